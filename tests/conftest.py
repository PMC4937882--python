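import numpy as np
import pandas as pd
import pytest

import miomega as mo


@pytest.fixture(scope="session")
def worksheet_curve() -> mo.OmegaCurve:
    """The bundled 13-point practice-size m-omega worksheet."""
    return mo.load_practice_size_worksheet()


@pytest.fixture()
def tiny_survey() -> mo.SurveyDataset:
    """A hand-built 12-record survey: one 2-level stratifier, one target.

    Records 2 and 7 have missing targets; observed values by stratum are
    stratum 1 -> {10, 20, 30, 40, 50} and stratum 2 -> {7, 7, 9, 9, 11}.
    """
    df = pd.DataFrame(
        {
            "G": [1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2],
            "Y": pd.array(
                [10, 20, pd.NA, 30, 40, 50, 7, pd.NA, 7, 9, 9, 11], dtype="Int64"
            ),
        }
    )
    return mo.SurveyDataset(df, stratifiers=["G"], targets=["Y"])


@pytest.fixture(scope="session")
def small_synthetic_survey() -> mo.SurveyDataset:
    """A 400-record survey from the generator with a single 4-level stratifier."""
    strat = mo.StratifierSpec("G", (1, 2, 3, 4), (0.25, 0.25, 0.25, 0.25))
    target = mo.TargetSpec("Y", 1, 30, missing_fraction=0.1)
    spec = mo.SyntheticSpec(400, (strat,), (target,), seed=11)
    return mo.generate_survey(spec)


@pytest.fixture(scope="session")
def small_pool(small_synthetic_survey) -> mo.ImputationPool:
    index = mo.build_donor_groups(small_synthetic_survey, "Y", ["G"])
    return mo.hotdeck_impute_pool(small_synthetic_survey, "Y", index, M=200, seed=5)


def normal_pool(seed: int, n_records: int = 4, M: int = 500) -> mo.ImputationPool:
    """Synthetic diagnostic pool: i.i.d. N(0,1) cells, so per-imputation
    means are i.i.d. normal across the M columns."""
    rng = np.random.default_rng(seed)
    return mo.ImputationPool.from_columns(
        rng.standard_normal((n_records, M)), variable_name="normal", seed=seed
    )
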