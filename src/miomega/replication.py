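"""The replication experiment: measure the sampling spread of B against m.

For each m on a grid, draw n independent MI samples of m distinct imputations
from the pool (without replacement within a sample; separate samples may
overlap), compute B for each, and summarise:

    V_B   = sum((B - B_bar)^2) / (n - 1)   variance of B over the n samples
    SD_B  = sqrt(V_B)
    omega = SD_B / sqrt(n)                 standard error of B

The resulting m-omega curve is the object both eta decision rules consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hotdeck import ImputationPool
from .rubin import MISample, PointEstimator, combine, mean_point_estimator

__all__ = ["ReplicationPlan", "OmegaCurve", "draw_mi_sample", "build_omega_curve"]

#: m values exercised in the original workflow-survey experiment
DEFAULT_M_GRID = (2, 3, 5, 10, 15, 20, 25, 30, 35, 40, 60, 80, 100)


@dataclass(frozen=True)
class ReplicationPlan:
    """Grid of m values, number of replicate samples per m, and master seed."""

    m_grid: tuple = DEFAULT_M_GRID
    n: int = 10
    seed: int = 0

    def validate(self, M: int | None = None) -> None:
        grid = list(self.m_grid)
        if grid != sorted(set(grid)):
            raise ValueError("m_grid must be strictly increasing")
        if not grid or grid[0] < 2:
            raise ValueError("every m must be at least 2")
        if self.n < 2:
            raise ValueError("need n >= 2 replicate samples per m")
        if M is not None and grid[-1] > M:
            raise ValueError(f"largest m ({grid[-1]}) exceeds pool size M={M}")


@dataclass
class OmegaCurve:
    """Per-m summary of the spread of B: B_bar, V_B, SD_B and omega.

    ``B_values`` holds the raw n replicate B values per m (None when the
    curve was loaded from a published worksheet that prints only summaries).
    """

    m: np.ndarray
    B_bar: np.ndarray
    V_B: np.ndarray
    SD_B: np.ndarray
    omega: np.ndarray
    n: int | None = None
    B_values: np.ndarray | None = None
    variable_name: str = ""

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=int)
        for name in ("B_bar", "V_B", "SD_B", "omega"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.B_values is not None:
            self.B_values = np.asarray(self.B_values, dtype=float)
            self._check_consistency()

    def _check_consistency(self) -> None:
        vb = np.var(self.B_values, axis=1, ddof=1)
        if not np.allclose(vb, self.V_B, rtol=1e-12, atol=1e-300):
            raise ValueError("V_B inconsistent with raw B values")
        if not np.allclose(np.sqrt(self.V_B), self.SD_B, rtol=1e-12):
            raise ValueError("SD_B must equal sqrt(V_B)")
        if not np.allclose(self.SD_B / np.sqrt(self.n), self.omega, rtol=1e-12):
            raise ValueError("omega must equal SD_B / sqrt(n)")

    def __len__(self) -> int:
        return len(self.m)

    @classmethod
    def from_table(
        cls,
        m: Sequence[int],
        omega: Sequence[float],
        B_bar: Sequence[float] | None = None,
        n: int | None = None,
        variable_name: str = "",
    ) -> "OmegaCurve":
        """Build a curve from worksheet numbers (m and omega at minimum)."""
        m = np.asarray(m, dtype=int)
        omega = np.asarray(omega, dtype=float)
        if B_bar is None:
            B_bar = np.full_like(omega, np.nan)
        if n is not None:
            V_B = n * omega**2
        else:
            V_B = np.full_like(omega, np.nan)
        return cls(m=m, B_bar=np.asarray(B_bar, float), V_B=V_B,
                   SD_B=np.sqrt(V_B), omega=omega, n=n,
                   variable_name=variable_name)

    # -- I/O -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"m": self.m, "B_bar": self.B_bar, "V_B": self.V_B,
             "SD_B": self.SD_B, "omega": self.omega}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        """Audit dump including the raw replicate B values."""
        payload = {
            "variable_name": self.variable_name,
            "n": self.n,
            "m": self.m.tolist(),
            "B_bar": self.B_bar.tolist(),
            "V_B": self.V_B.tolist(),
            "SD_B": self.SD_B.tolist(),
            "omega": self.omega.tolist(),
            "B_values": None if self.B_values is None else self.B_values.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, n: int | None = None,
                 variable_name: str = "") -> "OmegaCurve":
        df = pd.read_csv(path)
        if "m" not in df or "omega" not in df:
            raise ValueError("curve CSV needs at least columns 'm' and 'omega'")
        return cls.from_table(
            df["m"], df["omega"],
            B_bar=df["B_bar"] if "B_bar" in df else None,
            n=n if n is not None else (int(df["n"].iloc[0]) if "n" in df else None),
            variable_name=variable_name,
        )


def draw_mi_sample(
    pool: ImputationPool,
    m: int,
    rng: np.random.Generator,
    estimator: PointEstimator = mean_point_estimator,
) -> MISample:
    """Draw m distinct imputations from the pool and combine them.

    Selection is uniform without replacement (an MI of size m means m
    distinct completed datasets).  With m = M the sample is the whole pool.
    """
    if not 2 <= m <= pool.M:
        raise ValueError(f"m must be in [2, M={pool.M}]")
    cols = rng.choice(pool.M, size=m, replace=False)
    Q, U = zip(*(estimator(pool.completed[:, c]) for c in cols))
    return combine(Q, U)


def _precompute_estimates(pool: ImputationPool, estimator: PointEstimator):
    """Q_i and U_i depend only on the pool column; compute each once."""
    QU = [estimator(pool.completed[:, c]) for c in range(pool.M)]
    Q = np.array([q for q, _ in QU])
    U = np.array([u for _, u in QU])
    return Q, U


def build_omega_curve(
    pool: ImputationPool,
    plan: ReplicationPlan,
    estimator: PointEstimator = mean_point_estimator,
) -> OmegaCurve:
    """Run the full replication experiment over the plan's m grid.

    Each (m, replicate) pair uses an independently derived substream of the
    master seed, so per-m results do not depend on grid order and the whole
    curve is reproducible.
    """
    plan.validate(M=pool.M)
    Q_all, U_all = _precompute_estimates(pool, estimator)

    n = plan.n
    B_values = np.empty((len(plan.m_grid), n))
    for mi, m in enumerate(plan.m_grid):
        for rep in range(n):
            # keyed by the m value itself, not its grid position: the B values
            # at a given m are unchanged by adding or removing other grid points
            ss = np.random.SeedSequence(plan.seed, spawn_key=(m, rep))
            rng = np.random.default_rng(ss)
            cols = rng.choice(pool.M, size=m, replace=False)
            B_values[mi, rep] = combine(Q_all[cols], U_all[cols]).B

    B_bar = B_values.mean(axis=1)
    V_B = B_values.var(axis=1, ddof=1)
    SD_B = np.sqrt(V_B)
    omega = SD_B / np.sqrt(n)
    return OmegaCurve(
        m=np.asarray(plan.m_grid), B_bar=B_bar, V_B=V_B, SD_B=SD_B,
        omega=omega, n=n, B_values=B_values, variable_name=pool.variable_name,
    )
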