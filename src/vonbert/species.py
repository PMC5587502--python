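"""Bundled species presets for Atlantic herring and Atlantic cod.

Each preset carries the survey composition (quarter counts), the spawning
distribution hyperparameters (held fixed, never estimated), length-weight
conversion constants (w = alpha * l^beta, l in mm), natural mortality at
age, and the generative growth truths used by the simulation study.

Herring (Clupea harengus) is the long-spawning-season species (small tau);
cod (Gadus morhua) the short-season one (large tau).
"""

from __future__ import annotations

from .growth import GrowthParams
from .spawning import SpawningDist

__all__ = ["SPECIES", "herring", "cod"]

herring = {
    "name": "herring",
    "n_surveyed": 22_790,
    "quarter_counts": {0.0: 18_933, 0.75: 3_857},
    # spawning hyperparameters used by the generative/simulation configuration
    "spawn_mu": 0.868,
    "spawn_tau": 0.404,
    # values listed with the survey input table (kept for reference; they
    # differ from the simulation configuration in the third decimal)
    "spawn_mu_survey_table": 0.858,
    "spawn_tau_survey_table": 0.405,
    "alpha": 0.006,
    "beta": 3.05,
    "mortality_at_age": [0.767, 0.385, 0.356, 0.339, 0.319, 0.314, 0.307],
    "max_winters": 10,
    # simulation-study growth truths
    "sim_growth": {"k": 0.60, "l_inf": 293.3, "t0": -0.713, "sigma": 0.057},
}

cod = {
    "name": "cod",
    "n_surveyed": 2_815,
    "quarter_counts": {0.0: 1_910, 0.75: 905},
    "spawn_mu": 0.312,
    "spawn_tau": 5.473,
    "alpha": 0.008,
    "beta": 3.06,
    "mortality_at_age": [0.537, 0.386, 0.306, 0.262, 0.237, 0.223, 0.211],
    "max_winters": 15,
    "sim_growth": {"k": 0.24, "l_inf": 1143.0, "t0": -0.179, "sigma": 0.139},
}

SPECIES = {"herring": herring, "cod": cod}


def sim_growth_params(preset: dict) -> GrowthParams:
    """Generative GrowthParams (sigma2 = sigma^2) for a species preset."""
    g = preset["sim_growth"]
    return GrowthParams(k=g["k"], l_inf=g["l_inf"], t0=g["t0"], sigma2=g["sigma"] ** 2)


def spawning_dist(preset: dict) -> SpawningDist:
    """Spawning distribution for a species preset."""
    return SpawningDist(mu=preset["spawn_mu"], tau=preset["spawn_tau"])
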