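"""Hot-deck multiple imputation with categorical donor groups.

Each missing cell of a target variable is filled with the observed value of a
donor record drawn uniformly with replacement from the donor group matching
the recipient's stratifier-level combination.  Repeating the fill M times
(independently per cell and per repetition) yields an imputation pool: M
completed copies of the variable that downstream replication code treats as
the population of imputations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import SurveyDataset

__all__ = [
    "EmptyDonorGroupError",
    "DonorGroupIndex",
    "ImputationPool",
    "build_donor_groups",
    "hotdeck_impute_pool",
]


class EmptyDonorGroupError(ValueError):
    """A recipient's stratifier cell contains no observed donor."""


@dataclass
class DonorGroupIndex:
    """Partition of the observed records of one target by stratifier cell.

    ``groups`` maps each stratifier-level combination (a tuple) to the record
    indices whose target value is observed; ``recipients`` maps each record
    index with a missing target to its combination.  By default no collapsing
    hierarchy is applied to sparse cells: an empty cell raises at build time.
    With ``collapse=True`` a recipient in an empty cell falls back to
    progressively coarser cells (keys dropped from the right), recorded in
    ``collapsed``; its ``recipients`` entry is then a shorter tuple keying a
    coarser group.
    """

    target: str
    key_columns: list[str]
    groups: dict = field(default_factory=dict)
    recipients: dict = field(default_factory=dict)
    collapsed: dict = field(default_factory=dict)

    def donor_indices(self, record: int) -> np.ndarray:
        return self.groups[self.recipients[record]]


def build_donor_groups(
    data: SurveyDataset, target: str, keys: Sequence[str], collapse: bool = False
) -> DonorGroupIndex:
    """Index observed records by stratifier cell and map every recipient to one.

    Raises :class:`EmptyDonorGroupError` naming the offending cell if any
    record with a missing target falls in a cell with zero observed donors,
    unless ``collapse`` is set, in which case the recipient is matched on
    progressively fewer key columns (dropped from the right) until a donor
    exists; collapses are recorded on the returned index.
    """
    keys = list(keys)
    for k in keys:
        if data.data[k].isna().any():
            raise ValueError(f"key column {k!r} has missing values")
    if target not in data.data.columns:
        raise KeyError(f"target column {target!r} not present")

    mask = data.missing_mask(target)
    key_array = data.data[keys].to_numpy()
    observed_idx = np.flatnonzero(~mask)

    raw: dict = {}
    for i in observed_idx:
        raw.setdefault(tuple(key_array[i]), []).append(int(i))
    groups = {k: np.asarray(v, dtype=np.intp) for k, v in raw.items()}

    recipients: dict = {}
    collapsed: dict = {}
    for i in np.flatnonzero(mask):
        combo = tuple(key_array[i])
        if combo in groups:
            recipients[int(i)] = combo
            continue
        if not collapse:
            cell = ", ".join(f"{k}={v}" for k, v in zip(keys, combo))
            raise EmptyDonorGroupError(
                f"empty donor group for {target!r} recipient at record {int(i)} "
                f"(cell {cell})"
            )
        # fall back on coarser cells: drop PRIMEMP-style keys from the right
        for depth in range(len(combo) - 1, -1, -1):
            sub = combo[:depth]
            if sub not in groups:
                members = [int(j) for j in observed_idx
                           if tuple(key_array[j])[:depth] == sub]
                if not members:
                    continue
                groups[sub] = np.asarray(members, dtype=np.intp)
            recipients[int(i)] = sub
            collapsed[int(i)] = combo
            break
        else:
            raise EmptyDonorGroupError(
                f"no observed donors at all for target {target!r}"
            )

    return DonorGroupIndex(target=target, key_columns=keys, groups=groups,
                           recipients=recipients, collapsed=collapsed)


@dataclass
class ImputationPool:
    """M completed copies of one target variable.

    ``completed`` is an ``(n_records, M)`` array with no missing entries;
    originally observed cells are identical across all M columns, only the
    ``missing_indices`` rows vary.  ``donor_log`` (optional, hot-deck pools
    only) records the donating record index for each (missing cell, copy).
    """

    variable_name: str
    completed: np.ndarray
    missing_indices: np.ndarray
    seed: int | None = None
    key_columns: list[str] = field(default_factory=list)
    donor_log: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.completed = np.asarray(self.completed)
        if self.completed.ndim != 2:
            raise ValueError("completed must be 2-D (n_records, M)")
        self.missing_indices = np.asarray(self.missing_indices, dtype=np.intp)

    @property
    def n_records(self) -> int:
        return self.completed.shape[0]

    @property
    def M(self) -> int:
        return self.completed.shape[1]

    @classmethod
    def from_columns(cls, columns: np.ndarray, variable_name: str = "synthetic",
                     seed: int | None = None) -> "ImputationPool":
        """Wrap an arbitrary ``(n_records, M)`` array as a pool.

        Intended for synthetic diagnostic pools (e.g. i.i.d. normal columns
        used to check the chi-square scaling of omega); such a pool treats
        every cell as originally missing.
        """
        columns = np.asarray(columns)
        return cls(variable_name, columns, np.arange(columns.shape[0]), seed=seed)

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """One column per imputation (``imputation_001`` ...), one row per record."""
        width = len(str(self.M))
        cols = {f"imputation_{i + 1:0{max(width, 3)}d}": self.completed[:, i]
                for i in range(self.M)}
        pd.DataFrame(cols).to_csv(path, index=False)
        if sidecar is not None:
            meta = {
                "variable_name": self.variable_name,
                "M": self.M,
                "n_records": self.n_records,
                "seed": self.seed,
                "key_columns": self.key_columns,
                "missing_indices": [int(i) for i in self.missing_indices],
            }
            Path(sidecar).write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path) -> "ImputationPool":
        df = pd.read_csv(path)
        meta = json.loads(Path(sidecar).read_text())
        return cls(
            meta["variable_name"],
            df.to_numpy(),
            np.asarray(meta["missing_indices"], dtype=np.intp),
            seed=meta.get("seed"),
            key_columns=list(meta.get("key_columns", [])),
        )


def hotdeck_impute_pool(
    data: SurveyDataset,
    target: str,
    index: DonorGroupIndex,
    M: int,
    seed: int,
) -> ImputationPool:
    """Build a pool of ``M`` hot-deck completions of ``target``.

    Donors are drawn uniformly with replacement from the recipient's donor
    group, independently across missing cells and across the M copies, so the
    pool realises the full donor-sampling variability that the replication
    stage measures.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    if index.target != target:
        raise ValueError("index was built for a different target")

    # nullable Int64 and float columns both come out as float with NaN holes
    values = data.data[target].to_numpy(dtype="float64", na_value=np.nan)
    mask = data.missing_mask(target)
    missing_idx = np.flatnonzero(mask)
    for i in missing_idx:
        if int(i) not in index.recipients:
            raise EmptyDonorGroupError(
                f"recipient record {int(i)} not covered by donor index"
            )

    rng = np.random.default_rng(seed)
    completed = np.repeat(np.where(mask, 0.0, values)[:, None], M, axis=1)
    donor_log = np.empty((len(missing_idx), M), dtype=np.intp)
    for row, i in enumerate(missing_idx):
        donors = index.donor_indices(int(i))
        picks = donors[rng.integers(0, len(donors), size=M)]
        donor_log[row] = picks
        completed[i, :] = values[picks]
    if np.array_equal(completed, np.round(completed)):
        completed = completed.astype(np.int64)

    return ImputationPool(
        variable_name=target,
        completed=completed,
        missing_indices=missing_idx,
        seed=seed,
        key_columns=list(index.key_columns),
        donor_log=donor_log,
    )
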