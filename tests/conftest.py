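import numpy as np
import pandas as pd
import pytest

from cryoextender.components import COMPONENT_ORDER
from cryoextender.simulate import generate_experiment_table

X_COLS = list(COMPONENT_ORDER)
Y_COLS = ["tm", "pm"]


@pytest.fixture(scope="session")
def default_table() -> pd.DataFrame:
    """488-row study-structured table: default noise and bull effects."""
    return generate_experiment_table(seed=20230317)


def drop_clipped(table: pd.DataFrame) -> pd.DataFrame:
    """Remove rows clipped at the physical 0/100 motility bounds; the
    linear ground truth holds exactly only on the interior."""
    interior = (
        (table["tm"] > 0) & (table["tm"] < 100)
        & (table["pm"] > 0) & (table["pm"] < 100)
    )
    return table[interior].reset_index(drop=True)


@pytest.fixture(scope="session")
def noisefree_table() -> pd.DataFrame:
    """488 rows from the reference equations, no noise, no bull effects;
    rows clipped at the motility bounds removed."""
    return drop_clipped(
        generate_experiment_table(seed=20230317, noise_sd=0.0, bull_effects=False)
    )


@pytest.fixture(scope="session")
def noise_only_table() -> pd.DataFrame:
    """Default residual noise but no bull effects."""
    return generate_experiment_table(seed=20230317, bull_effects=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
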