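import numpy as np
import pandas as pd
import pytest

from obesim.polygenic import GeneticArchitecture
from obesim.selection import MortalitySchedule
from obesim.simulate import SimulationConfig


@pytest.fixture
def arch():
    return GeneticArchitecture()


@pytest.fixture
def harsh_schedule():
    """Pre-obstetrics regime: LMDR 15%, neonatal 14%, relative risks 4."""
    return MortalitySchedule(
        lmdr=0.15, neonatal_rate=0.14, rr_maternal=4.0, rr_perinatal=4.0, fertility=6.0
    )


@pytest.fixture
def modern_schedule():
    return MortalitySchedule(
        lmdr=0.0001, neonatal_rate=0.003, rr_maternal=4.0, rr_perinatal=4.0, fertility=2.0
    )


@pytest.fixture
def relaxation_config():
    """The 10% -> 15% worked setup: gain calibrates to exactly 0.5, post loss 0.

    Pre schedule: maternal-only deficit 1 - 0.4/0.8 = 0.5; post schedule has
    unit relative risks so the mortality loss vanishes exactly.
    """
    pre = MortalitySchedule(lmdr=0.2, neonatal_rate=0.0, rr_maternal=3.0, rr_perinatal=1.0)
    post = MortalitySchedule(lmdr=0.001, neonatal_rate=0.003, rr_maternal=1.0, rr_perinatal=1.0)
    return SimulationConfig(
        pre_schedule=pre,
        post_schedule=post,
        transition_generation=0,
        n_generations=3,
        initial_freq=0.10,
    )


@pytest.fixture
def small_table():
    """12-row complete country-style table with correlated columns."""
    rng = np.random.default_rng(42)
    n = 12
    x = rng.normal(0.0, 1.0, n)
    z1 = 0.6 * x + rng.normal(0.0, 0.8, n)
    z2 = rng.normal(0.0, 1.0, n)
    y = -0.7 * x + 0.4 * z1 + rng.normal(0.0, 0.5, n)
    return pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
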