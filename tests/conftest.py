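import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from vonbert import (  # noqa: E402
    GrowthParams,
    ModelSpec,
    SpawningDist,
    cod_config,
    fit,
    herring_config,
    simulate_dataset,
)

HERRING_TRUTH = {"k": 0.60, "l_inf": 293.3, "t0": -0.713, "sigma2": 0.057**2}
COD_TRUTH = {"k": 0.24, "l_inf": 1143.0, "t0": -0.179, "sigma2": 0.139**2}


@pytest.fixture(scope="session")
def herring_params() -> GrowthParams:
    return GrowthParams(**HERRING_TRUTH)


@pytest.fixture(scope="session")
def cod_params() -> GrowthParams:
    return GrowthParams(**COD_TRUTH)


@pytest.fixture(scope="session")
def herring_spawn() -> SpawningDist:
    return SpawningDist(mu=0.868, tau=0.404)


@pytest.fixture(scope="session")
def cod_spawn() -> SpawningDist:
    return SpawningDist(mu=0.312, tau=5.473)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20171)


# --- shared heavy fits (full analysis protocol; reused across tests) -------

@pytest.fixture(scope="session")
def herring_recovery():
    """Herring generative config, simulated survey (n=2,000), model-IV fit."""
    cfg = herring_config(n=2000, seed=42)
    data = simulate_dataset(cfg)
    draws = fit(data, ModelSpec("IV", spawn=cfg.spawn),
                chains=4, burn_in=1000, draws=1000, seed=7)
    return cfg, data, draws


@pytest.fixture(scope="session")
def cod_recovery():
    """Cod generative config, simulated survey (n=2,000), model-IV fit."""
    cfg = cod_config(n=2000, seed=43)
    data = simulate_dataset(cfg)
    draws = fit(data, ModelSpec("IV", spawn=cfg.spawn),
                chains=4, burn_in=1000, draws=1000, seed=8)
    return cfg, data, draws
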