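import numpy as np
import pandas as pd
import pytest

from betel.simulation import gen_design_data, gen_ks_data


@pytest.fixture(scope="session")
def design_df_small():
    """20-record design-setting dataset."""
    return gen_design_data(20, seed=42)


@pytest.fixture(scope="session")
def design_df():
    """100-record design-setting dataset."""
    return gen_design_data(100, seed=7)


@pytest.fixture(scope="session")
def ks_df():
    """200-record observational dataset (both model specifications correct
    and misspecified covariates available)."""
    return gen_ks_data(200, seed=11)


@pytest.fixture
def design_toy():
    """The 4-record worked design example: Hajek mean 4/8 = 0.5."""
    return pd.DataFrame(
        {
            "R": [1, 1, 0, 1],
            "Y": [1.0, 0.0, np.nan, 1.0],
            "pi": [0.5, 0.25, np.nan, 0.5],
        }
    )


def feasible_random_instance(rng, n, m):
    """Random moment matrix guaranteed feasible: appending the negated
    row-sum puts the origin at the uniform convex combination."""
    G = rng.standard_normal((n - 1, m))
    return np.vstack([G, -G.sum(axis=0)])
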