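import warnings

import numpy as np
import pandas as pd
import pytest

from coralherit import (DesignConfig, EffectConfig, VarianceComponents,
                        generate_experiment)
from coralherit.calcify import add_rates

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def default_experiment() -> pd.DataFrame:
    """One full 8-species experiment at the default design, fixed seed."""
    return generate_experiment(seed=42)


@pytest.fixture(scope="session")
def experiment_with_rates(default_experiment) -> pd.DataFrame:
    return add_rates(default_experiment)


@pytest.fixture(scope="session")
def noise_free_experiment() -> pd.DataFrame:
    """Degenerate experiment: zero variances, zero effects, no mortality."""
    vc = VarianceComponents(v_genet=0, v_site=0, v_tank=0, v_mesocosm=0,
                            v_residual=0)
    eff = EffectConfig(grand_mean=1.0, temp_effect=0, ph_effect=0,
                       interaction_effect=0)
    design = DesignConfig(mortality_rate=0.0)
    return generate_experiment(design, vc, eff, seed=0)


@pytest.fixture
def two_group_table() -> pd.DataFrame:
    """Control vs warming only, no nesting structure: the t-test oracle case."""
    rng = np.random.default_rng(11)
    n = 12
    return pd.DataFrame({
        "treatment": ["control"] * n + ["warming"] * n,
        "temp_level": ["ambient"] * n + ["+2C"] * n,
        "ph_level": ["ambient"] * (2 * n),
        "rate": np.r_[rng.normal(0.0, 1.0, n), rng.normal(0.8, 1.0, n)],
    })
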