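"""Hot-deck donor groups and imputation pools."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import miomega as mo


def test_donor_groups_partition_observed_records(small_synthetic_survey):
    data = small_synthetic_survey
    index = mo.build_donor_groups(data, "Y", ["G"])
    all_members = np.concatenate(list(index.groups.values()))
    observed = np.flatnonzero(~data.missing_mask("Y"))
    assert sorted(all_members) == sorted(observed)
    assert len(all_members) == len(set(all_members))  # exactly one group each
    # every recipient maps onto an existing group
    for rec, combo in index.recipients.items():
        assert data.missing_mask("Y")[rec]
        assert combo in index.groups


def test_single_level_key_gives_one_group(tiny_survey):
    df = tiny_survey.data.copy()
    df["ONE"] = 1
    data = mo.SurveyDataset(df, stratifiers=["ONE"], targets=["Y"])
    index = mo.build_donor_groups(data, "Y", ["ONE"])
    assert len(index.groups) == 1
    assert len(index.groups[(1,)]) == 10  # the ten observed records


def test_empty_donor_group_raises_with_cell_named():
    df = pd.DataFrame(
        {"G": [1, 1, 2, 2], "Y": pd.array([1, 2, pd.NA, pd.NA], dtype="Int64")}
    )
    data = mo.SurveyDataset(df, stratifiers=["G"], targets=["Y"])
    with pytest.raises(mo.EmptyDonorGroupError, match="G=2"):
        mo.build_donor_groups(data, "Y", ["G"])


def test_collapse_fallback_matches_on_coarser_cell():
    df = pd.DataFrame(
        {
            "G": [1, 1, 1, 1, 2, 2],
            "H": [1, 1, 2, 2, 1, 2],
            "Y": pd.array([5, 6, 7, 8, pd.NA, 9], dtype="Int64"),
        }
    )
    data = mo.SurveyDataset(df, stratifiers=["G", "H"], targets=["Y"])
    # cell (2,1) has no observed donor; fallback drops H and matches G=2
    index = mo.build_donor_groups(data, "Y", ["G", "H"], collapse=True)
    assert index.recipients[4] == (2,)
    assert index.collapsed == {4: (2, 1)}
    assert list(index.groups[(2,)]) == [5]


def test_pool_observed_cells_constant_and_closure(tiny_survey):
    index = mo.build_donor_groups(tiny_survey, "Y", ["G"])
    pool = mo.hotdeck_impute_pool(tiny_survey, "Y", index, M=500, seed=1)
    assert pool.M == 500 and pool.n_records == 12
    observed = ~tiny_survey.missing_mask("Y")
    base = tiny_survey.data["Y"].to_numpy(dtype=float, na_value=np.nan)
    # observed cells identical across all 500 copies
    assert (pool.completed[observed] == base[observed, None]).all()
    # hot-deck closure, checked exhaustively: record 2 is in stratum 1,
    # record 7 in stratum 2
    assert set(pool.completed[2]) <= {10, 20, 30, 40, 50}
    assert set(pool.completed[7]) <= {7, 9, 11}
    # donor log points at real donors carrying the imputed value
    for row, rec in enumerate(pool.missing_indices):
        donors = pool.donor_log[row]
        assert np.array_equal(pool.completed[rec], base[donors])


def test_pool_with_no_missing_cells_is_constant():
    df = pd.DataFrame({"G": [1, 1, 1], "Y": pd.array([4, 5, 6], dtype="Int64")})
    data = mo.SurveyDataset(df, stratifiers=["G"], targets=["Y"])
    index = mo.build_donor_groups(data, "Y", ["G"])
    pool = mo.hotdeck_impute_pool(data, "Y", index, M=20, seed=0)
    assert (pool.completed == np.array([4, 5, 6])[:, None]).all()


def test_singleton_donor_group_forces_the_value():
    df = pd.DataFrame(
        {"G": [1, 1, 2, 2], "Y": pd.array([3, 3, 8, pd.NA], dtype="Int64")}
    )
    data = mo.SurveyDataset(df, stratifiers=["G"], targets=["Y"])
    index = mo.build_donor_groups(data, "Y", ["G"])
    pool = mo.hotdeck_impute_pool(data, "Y", index, M=50, seed=2)
    assert (pool.completed[3] == 8).all()  # lone donor, zero B contribution


def test_pool_is_seed_reproducible(tiny_survey):
    index = mo.build_donor_groups(tiny_survey, "Y", ["G"])
    a = mo.hotdeck_impute_pool(tiny_survey, "Y", index, M=100, seed=9)
    b = mo.hotdeck_impute_pool(tiny_survey, "Y", index, M=100, seed=9)
    assert np.array_equal(a.completed, b.completed)
    c = mo.hotdeck_impute_pool(tiny_survey, "Y", index, M=100, seed=10)
    assert not np.array_equal(a.completed, c.completed)


def test_imputed_cell_distribution_matches_donor_group(tiny_survey):
    """Uniform-with-replacement draws: at large M the imputed values in a
    cell follow the donor group's empirical distribution (chi-square GOF)."""
    index = mo.build_donor_groups(tiny_survey, "Y", ["G"])
    pool = mo.hotdeck_impute_pool(tiny_survey, "Y", index, M=6000, seed=7)
    imputed = pool.completed[7]  # stratum 2 donors: 7, 7, 9, 9, 11
    counts = np.array([(imputed == v).sum() for v in (7, 9, 11)])
    expected = 6000 * np.array([2 / 5, 2 / 5, 1 / 5])
    assert stats.chisquare(counts, expected).pvalue > 1e-3


def test_pool_closure_on_generated_survey(small_pool, small_synthetic_survey):
    """Every imputed value appears among the recipient's donor group values."""
    data = small_synthetic_survey
    index = mo.build_donor_groups(data, "Y", ["G"])
    base = data.data["Y"].to_numpy(dtype=float, na_value=np.nan)
    for rec in small_pool.missing_indices:
        allowed = set(base[index.donor_indices(int(rec))])
        assert set(small_pool.completed[rec]) <= allowed


def test_pool_csv_roundtrip(tmp_path, tiny_survey):
    index = mo.build_donor_groups(tiny_survey, "Y", ["G"])
    pool = mo.hotdeck_impute_pool(tiny_survey, "Y", index, M=30, seed=4)
    pool.to_csv(tmp_path / "pool.csv", sidecar=tmp_path / "pool.json")
    back = mo.ImputationPool.from_csv(tmp_path / "pool.csv", tmp_path / "pool.json")
    assert np.array_equal(back.completed, pool.completed)
    assert back.seed == 4 and back.M == 30


def test_invalid_m_rejected(tiny_survey):
    index = mo.build_donor_groups(tiny_survey, "Y", ["G"])
    with pytest.raises(ValueError):
        mo.hotdeck_impute_pool(tiny_survey, "Y", index, M=0, seed=1)
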