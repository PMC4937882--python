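"""Rubin's combining rules for a scalar estimator, and relative efficiency.

For m completed datasets with per-imputation point estimates Q_i and variance
estimates U_i:

    Q_bar = mean(Q_i)
    U_bar = mean(U_i)                      (within-imputation variance)
    B     = sum((Q_i - Q_bar)^2) / (m - 1) (between-imputation variance)
    T     = U_bar + (1 + 1/m) * B          (total variance)

and the relative efficiency of using m rather than infinitely many
imputations, measured in standard-error units, is RE = (1 + gamma0/m)^(-1/2)
with gamma0 the population fraction of missing information.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["MISample", "combine", "mean_point_estimator", "relative_efficiency"]

#: signature of a pluggable scalar point estimator: completed values -> (Q, U)
PointEstimator = Callable[[np.ndarray], tuple[float, float]]


@dataclass(frozen=True)
class MISample:
    """One multiple-imputation sample of size m with its combined quantities."""

    m: int
    Q: tuple
    U: tuple
    Q_bar: float
    U_bar: float
    B: float
    T: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def combine(estimates: Sequence[float], variances: Sequence[float]) -> MISample:
    """Combine per-imputation estimates into an :class:`MISample`.

    Requires m >= 2 (B has divisor m - 1) and nonnegative variances.
    """
    Q = np.asarray(estimates, dtype=float)
    U = np.asarray(variances, dtype=float)
    if Q.shape != U.shape or Q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-D sequences")
    m = Q.size
    if m < 2:
        raise ValueError("B undefined: need at least m=2 imputations")
    if np.any(U < 0):
        raise ValueError("variance estimates must be nonnegative")
    Q_bar = float(Q.mean())
    U_bar = float(U.mean())
    B = float(np.sum((Q - Q_bar) ** 2) / (m - 1))
    T = U_bar + (1.0 + 1.0 / m) * B
    return MISample(m=m, Q=tuple(Q), U=tuple(U), Q_bar=Q_bar, U_bar=U_bar, B=B, T=T)


def mean_point_estimator(values: np.ndarray) -> tuple[float, float]:
    """Default scalar estimator: the unweighted mean.

    Returns ``(Q, U)`` with Q the mean of the completed variable and U its
    estimated sampling variance, sample variance (divisor n-1) over n.  Any
    callable with this signature can replace it in the replication stage.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot estimate from an empty vector")
    Q = float(v.mean())
    U = float(v.var(ddof=1) / v.size) if v.size > 1 else 0.0
    return Q, U


def relative_efficiency(gamma0: float, m: int) -> float:
    """Rubin's RE = (1 + gamma0/m)^(-1/2), in (0, 1].

    With gamma0 <= 0.2 even m=2 gives RE above 0.95, the observation behind
    the classical 2-to-5-imputations advice that the omega-based procedures
    in this package revisit.
    """
    if not 0.0 <= gamma0 <= 1.0:
        raise ValueError("gamma0 must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be a positive count")
    return float((1.0 + gamma0 / m) ** -0.5)
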