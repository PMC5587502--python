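"""Readers, writers and run configuration.

The canonical data dialect is a plain CSV with header
``winters,survey_frac,length_mm[,true_spawn,true_age]`` — one row per
fish.  Survey exports that record the quarter instead of the year
fraction are accommodated by a column map; quarter labels 1 and 4 map to
fractions 0 and 0.75.  Fitted runs are written as a draws CSV (one row
per retained draw) plus a JSON manifest carrying enough provenance
(model spec, priors, seed, config hash, versions, R-hat table) to re-run
deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .growth import GrowthParams
from .inference import ModelSpec, PosteriorDraws, PriorSpec
from .simulate import DATA_COLUMNS, LATENT_COLUMNS, SimConfig
from .spawning import SpawningDist

__all__ = [
    "RunConfig", "SpeciesConfig", "SamplerConfig", "load_config", "config_schema",
    "read_dataset", "write_dataset", "write_draws", "read_draws", "MalformedDataError",
]

QUARTER_TO_FRAC = {1: 0.0, 4: 0.75}


class MalformedDataError(ValueError):
    """Raised when more than the tolerated share of rows is malformed."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class SpeciesConfig(BaseModel):
    """Species block: spawning hyperparameters, length-weight constants,
    natural mortality schedule and the survey quarter mix."""

    model_config = ConfigDict(extra="forbid")

    name: str
    spawn_mu: float = Field(ge=0, lt=1)
    spawn_tau: float = Field(ge=0)
    alpha: float = Field(gt=0)
    beta: float = Field(gt=0)
    mortality_at_age: list[float]
    max_winters: int = Field(default=10, ge=1)
    quarter_counts: dict[float, float] = Field(default_factory=lambda: {0.0: 1.0})

    @field_validator("mortality_at_age")
    @classmethod
    def _positive_m(cls, v):
        if not v or any(m <= 0 for m in v):
            raise ValueError("mortality rates must be positive and non-empty")
        return v


class PriorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k_bounds: tuple[float, float] = (0.0, 3.0)
    l_inf_upper: float = 10_000.0
    t0_lower: float = -20.0
    sigma2_shape: float = 0.001
    sigma2_scale: float = 0.001
    c2_bounds: tuple[float, float] = (0.0, 1.0)

    def to_prior_spec(self) -> PriorSpec:
        return PriorSpec(**self.model_dump())


class SamplerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    chains: int = Field(default=4, ge=1)
    burn_in: int = Field(default=1000, ge=0)
    draws: int = Field(default=1000, ge=1)
    grid_size: int = Field(default=128, ge=8)


class RunConfig(BaseModel):
    """Validated run configuration (YAML on disk; unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    species: SpeciesConfig
    variant: str = "IV"
    priors: PriorConfig = Field(default_factory=PriorConfig)
    sampler: SamplerConfig = Field(default_factory=SamplerConfig)
    seed: int = 0
    data_path: str | None = None
    output_prefix: str | None = None

    @field_validator("variant")
    @classmethod
    def _known_variant(cls, v):
        if v not in ("I", "II", "III", "IV", "V"):
            raise ValueError(f"unknown model variant {v!r}")
        return v

    def model_spec(self) -> ModelSpec:
        spawn = None
        if self.variant in ("IV", "V"):
            spawn = SpawningDist(mu=self.species.spawn_mu, tau=self.species.spawn_tau)
        return ModelSpec(variant=self.variant, spawn=spawn)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def config_schema() -> dict:
    """JSON schema of the YAML run configuration."""
    return RunConfig.model_json_schema()


def species_run_config(species_name: str, **overrides) -> RunConfig:
    """RunConfig built from a bundled species preset (herring or cod)."""
    from .species import SPECIES

    preset = SPECIES[species_name]
    sp = SpeciesConfig(
        name=preset["name"], spawn_mu=preset["spawn_mu"], spawn_tau=preset["spawn_tau"],
        alpha=preset["alpha"], beta=preset["beta"],
        mortality_at_age=list(preset["mortality_at_age"]),
        max_winters=preset["max_winters"],
        quarter_counts={float(k): float(v) for k, v in preset["quarter_counts"].items()},
    )
    return RunConfig(species=sp, **overrides)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def write_dataset(df: pd.DataFrame, path, sim_config: SimConfig | None = None) -> None:
    """Write a dataset CSV (and a JSON sidecar when a SimConfig is given)."""
    path = Path(path)
    cols = [c for c in DATA_COLUMNS + LATENT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.10g")
    if sim_config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        payload = dataclasses.asdict(sim_config)
        payload["growth"] = dataclasses.asdict(sim_config.growth)
        payload["spawn"] = dataclasses.asdict(sim_config.spawn)
        payload["n_rejected"] = df.attrs.get("n_rejected")
        payload["package_version"] = __version__
        sidecar.write_text(json.dumps(payload, indent=2, default=str))


def read_dataset(path, col_map: dict | None = None, max_bad_fraction: float = 0.10):
    """Read and validate a survey dataset CSV.

    ``col_map`` maps canonical column names to the file's column names,
    e.g. ``{"winters": "Age", "quarter": "Quarter", "length_mm": "LngtCm"}``;
    a ``quarter`` entry converts quarter labels {1, 4} to survey fractions
    {0, 0.75}.  Rows violating the record invariants are dropped and
    reported (line-numbered) in ``df.attrs["rejected_rows"]``; if more
    than ``max_bad_fraction`` of rows are malformed a
    :class:`MalformedDataError` is raised.
    """
    raw = pd.read_csv(path)
    if col_map:
        if "quarter" in col_map:
            qcol = col_map["quarter"]
            raw["survey_frac"] = raw[qcol].map(QUARTER_TO_FRAC)
        rename = {v: k for k, v in col_map.items() if k != "quarter"}
        raw = raw.rename(columns=rename)
    missing = [c for c in DATA_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns {missing}")

    errors = []
    w = pd.to_numeric(raw["winters"], errors="coerce")
    q = pd.to_numeric(raw["survey_frac"], errors="coerce")
    length = pd.to_numeric(raw["length_mm"], errors="coerce")
    bad_numeric = w.isna() | q.isna() | length.isna()
    bad_winters = ~bad_numeric & ((w < 0) | (w != np.floor(w)))
    bad_frac = ~bad_numeric & ((q < 0) | (q >= 1))
    bad_length = ~bad_numeric & (length <= 0)
    bad_cell = ~bad_numeric & (w == 0) & (q == 0)
    reasons = {
        "non-numeric field": bad_numeric,
        "negative or non-integer winters": bad_winters,
        "survey fraction outside [0, 1)": bad_frac,
        "non-positive length": bad_length,
        "impossible cell winters=0, survey_frac=0": bad_cell,
    }
    bad = bad_numeric | bad_winters | bad_frac | bad_length | bad_cell
    for reason, mask in reasons.items():
        for idx in raw.index[mask]:
            errors.append(f"line {idx + 2}: {reason}")  # +2: header + 1-based
    if len(raw) and bad.sum() / len(raw) > max_bad_fraction:
        raise MalformedDataError(
            f"{bad.sum()} of {len(raw)} rows malformed (> {max_bad_fraction:.0%}):\n"
            + "\n".join(errors[:20])
        )
    df = pd.DataFrame({
        "winters": w[~bad].astype(int),
        "survey_frac": q[~bad].astype(float),
        "length_mm": length[~bad].astype(float),
    })
    for c in LATENT_COLUMNS:
        if c in raw.columns:
            df[c] = pd.to_numeric(raw[c], errors="coerce")[~bad]
    df = df.reset_index(drop=True)
    df.attrs["rejected_rows"] = errors
    return df


# ---------------------------------------------------------------------------
# posterior draws
# ---------------------------------------------------------------------------

def write_draws(pdraws: PosteriorDraws, prefix) -> tuple[Path, Path]:
    """Write draws CSV + JSON manifest; returns (draws path, manifest path)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    draws_path = prefix.with_suffix(".draws.csv")
    manifest_path = prefix.with_suffix(".manifest.json")
    pdraws.draws.to_csv(draws_path, index=False, float_format="%.12g")
    manifest = {
        "variant": pdraws.spec.variant,
        "seasonal_knot_x": pdraws.spec.seasonal_knot_x,
        "spawn": dataclasses.asdict(pdraws.spec.spawn) if pdraws.spec.spawn else None,
        "priors": dataclasses.asdict(pdraws.priors),
        "meta": {k: v for k, v in pdraws.meta.items()},
        "n_obs": len(pdraws.data),
        "package_version": __version__,
        "numpy_version": np.__version__,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return draws_path, manifest_path


def read_draws(prefix) -> tuple[pd.DataFrame, dict]:
    """Read back a draws CSV and its manifest."""
    prefix = Path(prefix)
    draws = pd.read_csv(prefix.with_suffix(".draws.csv"))
    manifest = json.loads(prefix.with_suffix(".manifest.json").read_text())
    return draws, manifest


def growth_params_from_draws(draws: pd.DataFrame) -> GrowthParams:
    """Posterior-mean GrowthParams from a draws table."""
    return GrowthParams(
        k=float(draws["k"].mean()), l_inf=float(draws["l_inf"].mean()),
        t0=min(float(draws["t0"].mean()), 0.0), sigma2=float(draws["sigma2"].mean()),
    )
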