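"""Synthetic survey generator.

Emulates the structure of a physician workflow mail survey: a few thousand
respondents, complete categorical stratifiers (region, specialty, employment
code) that define hot-deck donor groups, and integer-valued practice-size /
staffing target variables carrying a few percent of MCAR item nonresponse.
Derived variables (a 2-group, a 5-group and a top-coded-at-20 version of a
1-100 master variable) are deterministic recodes of the master wherever the
master is observed, and share its missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import SurveyDataset

__all__ = [
    "StratifierSpec",
    "TargetSpec",
    "SyntheticSpec",
    "generate_survey",
    "workflow_survey_spec",
]


def _round_half_away(x: float) -> int:
    """round() with halves away from zero (Python's round is banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class StratifierSpec:
    """A complete categorical column: level codes and their probabilities."""

    name: str
    levels: tuple
    probabilities: tuple

    def validate(self) -> None:
        if len(self.levels) != len(self.probabilities):
            raise ValueError(f"{self.name}: levels/probabilities length mismatch")
        if len(self.levels) < 1:
            raise ValueError(f"{self.name}: needs at least one level")
        total = float(np.sum(self.probabilities))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.probabilities):
            raise ValueError(f"{self.name}: negative probability")


@dataclass(frozen=True)
class TargetSpec:
    """An integer-valued target variable on ``[low, high]``.

    ``distribution`` is ``"skewed"`` (truncated geometric, right-skewed counts
    typical of practice-size questions) or ``"uniform"``.  A derived variable
    sets ``derive_from`` plus exactly one of

    * ``breaks`` -- strictly increasing upper bin edges; the recode maps the
      master into groups ``1..len(breaks)+1`` (value <= breaks[0] -> 1, ...),
    * ``top_code`` -- values above this threshold are collapsed onto it.

    Derived variables inherit the master's missingness mask, mirroring how
    recodes of a single survey question are all missing together.
    """

    name: str
    low: int
    high: int
    missing_fraction: float = 0.0
    distribution: str = "skewed"
    geometric_p: float = 0.12
    derive_from: str | None = None
    breaks: tuple | None = None
    top_code: int | None = None

    def validate(self) -> None:
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError(f"{self.name}: missing_fraction must be in [0, 1)")
        if self.derive_from is None:
            if self.low > self.high:
                raise ValueError(f"{self.name}: empty value range")
            if self.distribution not in ("skewed", "uniform"):
                raise ValueError(f"{self.name}: unknown distribution")
            if not (0.0 < self.geometric_p < 1.0):
                raise ValueError(f"{self.name}: geometric_p must be in (0, 1)")
        else:
            if (self.breaks is None) == (self.top_code is None):
                raise ValueError(
                    f"{self.name}: derived target needs exactly one of breaks/top_code"
                )
            if self.breaks is not None and list(self.breaks) != sorted(set(self.breaks)):
                raise ValueError(f"{self.name}: breaks must be strictly increasing")

    def recode(self, master: np.ndarray) -> np.ndarray:
        """Apply the deterministic derivation to observed master values."""
        if self.breaks is not None:
            return np.digitize(master, list(self.breaks), right=True) + 1
        if self.top_code is not None:
            return np.minimum(master, self.top_code)
        raise ValueError(f"{self.name}: not a derived target")


@dataclass(frozen=True)
class SyntheticSpec:
    n_records: int
    stratifiers: tuple = ()
    targets: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        names: set[str] = set()
        for s in self.stratifiers:
            s.validate()
            names.add(s.name)
        n_cells = int(np.prod([len(s.levels) for s in self.stratifiers])) if self.stratifiers else 1
        if self.n_records <= n_cells:
            raise ValueError(
                f"n_records={self.n_records} <= {n_cells} stratifier cells: "
                "donor groups would be empty"
            )
        for t in self.targets:
            t.validate()
            if t.derive_from is not None and t.derive_from not in names:
                raise ValueError(f"{t.name}: derive_from {t.derive_from!r} not defined before it")
            names.add(t.name)


def _sample_integers(rng: np.random.Generator, t: TargetSpec, n: int) -> np.ndarray:
    support = np.arange(t.low, t.high + 1)
    if t.distribution == "uniform":
        return rng.choice(support, size=n)
    # truncated geometric over the support, renormalised
    weights = (1.0 - t.geometric_p) ** (support - t.low)
    return rng.choice(support, size=n, p=weights / weights.sum())


def generate_survey(spec: SyntheticSpec) -> SurveyDataset:
    """Generate a survey dataset per ``spec`` (seeded, bit-reproducible).

    Missingness is MCAR: for each non-derived target, exactly
    ``round(missing_fraction * n_records)`` cells (half-away-from-zero
    rounding) are blanked uniformly at random, independently of every other
    column.  Derived targets are recoded from their observed master values and
    blanked wherever the master is.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    frames: dict[str, pd.Series] = {}

    for s in spec.stratifiers:
        codes = rng.choice(np.asarray(s.levels), size=n, p=np.asarray(s.probabilities, float))
        frames[s.name] = pd.Series(codes, dtype="int64")

    masters: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for t in spec.targets:
        if t.derive_from is None:
            values = _sample_integers(rng, t, n)
            n_miss = _round_half_away(t.missing_fraction * n)
            mask = np.zeros(n, dtype=bool)
            if n_miss:
                mask[rng.choice(n, size=n_miss, replace=False)] = True
        else:
            values = t.recode(masters[t.derive_from])
            mask = masks[t.derive_from].copy()
        masters[t.name] = values
        masks[t.name] = mask
        col = pd.Series(values, dtype="Int64")
        col[mask] = pd.NA
        frames[t.name] = col

    df = pd.DataFrame(frames)
    return SurveyDataset(
        df,
        stratifiers=[s.name for s in spec.stratifiers],
        targets=[t.name for t in spec.targets],
    )


def workflow_survey_spec(
    seed: int = 0,
    n_records: int = 2567,
    practice_missing: float = 0.0362,
    staff_missing: float = 0.0888,
) -> SyntheticSpec:
    """The default stated world: a 2567-record physician workflow mail survey.

    Three complete stratifiers (4-level region, 14-level specialty, 8-level
    primary employment code) define the hot-deck donor groups.  Five targets:
    a 1-100 practice-size master (PRACSIZE100) with 3.62% missing; its
    2-group, 5-group and top-coded-at-20 recodes; and a 0-99 clinical-staff
    count (CLSTAFF1) with 8.88% missing.  Marginal level probabilities and
    the right-skew of the count variables are plausible stand-ins, not
    calibrated to any microdata.
    """
    region = StratifierSpec("REGION", (1, 2, 3, 4), (0.17, 0.21, 0.36, 0.26))
    specr = StratifierSpec(
        "SPECR",
        (1, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15),
        (0.10, 0.06, 0.08, 0.07, 0.05, 0.09, 0.06, 0.07, 0.08, 0.06, 0.07, 0.09, 0.05, 0.07),
    )
    primemp = StratifierSpec(
        "PRIMEMP",
        (11, 13, 20, 21, 22, 23, 30, 31),
        (0.30, 0.05, 0.18, 0.12, 0.08, 0.07, 0.14, 0.06),
    )
    targets = (
        TargetSpec("PRACSIZE100", 1, 100, practice_missing, "skewed", geometric_p=0.12),
        TargetSpec("PRACSIZE2", 1, 2, practice_missing, derive_from="PRACSIZE100", breaks=(1,)),
        TargetSpec("PRACSIZE5", 1, 5, practice_missing, derive_from="PRACSIZE100", breaks=(1, 3, 8, 20)),
        TargetSpec("PRACSIZE20", 1, 20, practice_missing, derive_from="PRACSIZE100", top_code=20),
        TargetSpec("CLSTAFF1", 0, 99, staff_missing, "skewed", geometric_p=0.10),
    )
    return SyntheticSpec(n_records, (region, specr, primemp), targets, seed)
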