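"""WAIC computation and model ranking.

The Watanabe-Akaike information criterion on the deviance scale,

    waic = -2 * (lppd - p_waic),
    lppd = sum_i log E_post[ p(l_i | theta) ],
    p_waic = 2 * sum_i ( log E_post[ p(l_i | theta) ] - E_post[ log p(l_i | theta) ] ),

with expectations over posterior draws, estimated from a (draws x
observations) log-likelihood matrix.  Lower WAIC is the better fit; with
the density-over-log-length convention survey-scale fits give large
negative values.  For latent-spawning variants the matrix conditions on
the per-draw latents by default (matching what the sampler produces); a
marginal matrix may be supplied instead, but models are only comparable
when computed on the identical dataset under one convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["WAICResult", "waic", "rank_models"]


@dataclass(frozen=True)
class WAICResult:
    """WAIC on the deviance scale with its decomposition."""

    waic: float
    lppd: float
    p_waic: float
    pointwise: pd.DataFrame  # per-observation lppd, p_waic, waic contributions

    @property
    def n_obs(self) -> int:
        return len(self.pointwise)


def waic(loglik_matrix: np.ndarray) -> WAICResult:
    """WAIC from a (draws x observations) log-likelihood matrix.

    log E[p] is computed via log-sum-exp for stability.  An observation
    whose likelihood is zero under every draw makes the criterion
    undefined and raises, naming the observation.
    """
    ll = np.asarray(loglik_matrix, dtype=float)
    if ll.ndim != 2:
        raise ValueError("log-likelihood matrix must be 2-D (draws x observations)")
    m, n = ll.shape
    if m < 1:
        raise ValueError("need at least one draw")
    if np.any(np.isnan(ll)) or np.any(ll == np.inf):
        raise ValueError("log-likelihood matrix must be finite (or -inf)")
    all_dead = np.all(ll == -np.inf, axis=0)
    if all_dead.any():
        raise ValueError(
            f"observation(s) {np.flatnonzero(all_dead).tolist()} have zero "
            "likelihood under every draw"
        )
    lppd_i = logsumexp(ll, axis=0) - np.log(m)
    # E[log p]: -inf entries (zero likelihood under some draw) propagate;
    # treat them as they are -- the mean is then -inf and waic infinite,
    # which faithfully reports the incompatibility.
    mean_ll_i = ll.mean(axis=0)
    p_i = 2.0 * (lppd_i - mean_ll_i)
    waic_i = -2.0 * (lppd_i - p_i)
    pw = pd.DataFrame({"lppd": lppd_i, "p_waic": p_i, "waic": waic_i})
    return WAICResult(
        waic=float(waic_i.sum()), lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()), pointwise=pw,
    )


def rank_models(results) -> pd.DataFrame:
    """Rank (label, WAICResult) pairs by ascending WAIC.

    ``results`` is an iterable of (model label or ModelSpec, WAICResult)
    computed on the identical dataset; mismatched observation counts are
    rejected as non-comparable.  Returns a table with waic, lppd, p_waic
    and delta_waic relative to the best model.
    """
    items = list(results)
    if not items:
        raise ValueError("no models to rank")
    labels = [getattr(spec, "variant", spec) for spec, _ in items]
    ns = {r.n_obs for _, r in items}
    if len(ns) != 1:
        raise ValueError(f"models computed on different observation counts: {sorted(ns)}")
    df = pd.DataFrame(
        {
            "model": labels,
            "waic": [r.waic for _, r in items],
            "lppd": [r.lppd for _, r in items],
            "p_waic": [r.p_waic for _, r in items],
        }
    ).sort_values("waic", kind="stable", ignore_index=True)
    df["delta_waic"] = df["waic"] - df["waic"].iloc[0]
    return df
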