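"""Survey dataset container: stratifier columns plus targets with missing values."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SurveyDataset:
    """A rectangular survey-style dataset.

    Parameters
    ----------
    data
        One row per respondent.  Target columns use pandas missing values
        (``pd.NA`` / ``NaN``) for item nonresponse; stratifier columns must be
        complete because they define hot-deck donor groups.
    stratifiers
        Names of the (categorical, fully observed) stratifier columns.
    targets
        Names of the columns eligible for imputation.
    """

    data: pd.DataFrame
    stratifiers: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in list(self.stratifiers) + list(self.targets):
            if col not in self.data.columns:
                raise KeyError(f"column {col!r} not present in data")
        for col in self.stratifiers:
            if self.data[col].isna().any():
                raise ValueError(f"stratifier column {col!r} has missing values")

    @property
    def n_records(self) -> int:
        return len(self.data)

    def missing_mask(self, column: str) -> np.ndarray:
        """Boolean vector marking the missing cells of ``column``."""
        return self.data[column].isna().to_numpy()

    def n_missing(self, column: str) -> int:
        return int(self.missing_mask(column).sum())

    def observed_values(self, column: str) -> np.ndarray:
        mask = self.missing_mask(column)
        return self.data[column].to_numpy()[~mask]

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path: str | Path, na_rep: str = "") -> None:
        """Write as CSV with a header row; missing cells as ``na_rep``."""
        self.data.to_csv(path, index=False, na_rep=na_rep)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        stratifiers: Sequence[str],
        targets: Sequence[str],
        na_values: Sequence[str] = ("",),
    ) -> "SurveyDataset":
        df = pd.read_csv(path, na_values=list(na_values), keep_default_na=True)
        # integer-valued target columns come back as float when they hold NaN;
        # nullable Int64 keeps the codes intact
        for col in targets:
            if col in df.columns and pd.api.types.is_float_dtype(df[col]):
                as_int = df[col].round()
                if ((df[col].dropna() - as_int.dropna()).abs() < 1e-9).all():
                    df[col] = as_int.astype("Int64")
        return cls(df, list(stratifiers), list(targets))
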