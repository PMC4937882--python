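"""Bundled reference worksheets.

Small published summary tables from a hot-deck MI study of a 2567-record
physician workflow mail survey, shipped as package data.  They let the eta
decision procedures be exercised and regression-tested against hand-checkable
numbers without access to any survey microdata (the underlying records are
restricted; only these worksheet summaries are public).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .replication import OmegaCurve

__all__ = ["load_practice_size_worksheet", "load_mean_b_by_m"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("miomega.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_practice_size_worksheet() -> OmegaCurve:
    """The m-omega worksheet for the 5-category practice-size variable.

    Thirteen grid points m = 2 ... 100, each summarising n = 10 replicate MI
    samples from a pool of 500 hot-deck imputations: B_bar (mean of the 10
    between-imputation variances, 3 decimals) and omega (their standard
    error, 4 decimals).
    """
    df = _read("practice_size5_worksheet.csv")
    return OmegaCurve.from_table(
        df["m"], df["omega"], B_bar=df["B_bar"], n=int(df["n"].iloc[0]),
        variable_name="PRACSIZE5",
    )


def load_mean_b_by_m() -> pd.DataFrame:
    """Mean between-imputation variance by variable and m (long format).

    Five survey variables of widely different scales (2-category practice
    size up to a 0-99 staff count) at eight m values.  Within a variable the
    means fluctuate around the population value with no trend in m, which is
    what makes omega -- not B_bar itself -- the informative function of m.
    """
    return _read("mean_b_by_m.csv")
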