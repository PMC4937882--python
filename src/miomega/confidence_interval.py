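"""The confidence interval method for eta.

B_bar at each m is a mean of n replicate B values; since B is (under
normality of the per-imputation estimates) a scaled chi-square with m - 1
degrees of freedom, B_bar is close to normal already at small m, and a
Student t interval applies.  The decision statistic is the half-width of the
95% interval as a percentage of B_bar:

    P = 100 * t * omega / B_bar

with t the two-sided 0.05 t quantile at n - 1 degrees of freedom (2.2622 for
the default n = 10).  Eta is the smallest grid m whose P falls strictly
below a user-chosen cutoff; P is scale-free, so the rule is invariant to
rescaling the target variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decision import EtaDecision
from .replication import OmegaCurve

__all__ = ["CIRecord", "ci_table", "decide_eta_ci"]


@dataclass(frozen=True)
class CIRecord:
    """Worksheet row: CI half-width for B_bar at one m, and P."""

    m: int
    B_bar: float
    omega: float
    t_crit: float
    half_width: float
    P: float


def ci_table(curve: OmegaCurve, conf_level: float = 0.95) -> list[CIRecord]:
    """One :class:`CIRecord` per grid m.

    Requires the curve to carry B_bar (> 0 everywhere, else P is undefined)
    and the replicate count n (>= 2, for the t degrees of freedom).
    """
    if curve.n is None or curve.n < 2:
        raise ValueError("curve must record the replicate count n >= 2")
    if np.any(~np.isfinite(curve.B_bar)) or np.any(curve.B_bar <= 0):
        raise ValueError("P undefined: curve must carry strictly positive B_bar")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must be in (0, 1)")
    t_crit = float(stats.t.ppf(0.5 + conf_level / 2.0, df=curve.n - 1))
    records = []
    for m, b_bar, omega in zip(curve.m, curve.B_bar, curve.omega):
        half = t_crit * float(omega)
        records.append(
            CIRecord(m=int(m), B_bar=float(b_bar), omega=float(omega),
                     t_crit=t_crit, half_width=half, P=100.0 * half / float(b_bar))
        )
    return records


def _worksheet(records: list[CIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "m": [r.m for r in records],
            "B_bar": [r.B_bar for r in records],
            "omega": [r.omega for r in records],
            "half_width": [r.half_width for r in records],
            "P": [r.P for r in records],
        }
    )


def decide_eta_ci(
    curve: OmegaCurve, cutoff: float = 15.0, conf_level: float = 0.95
) -> EtaDecision:
    """Eta = the smallest grid m with P strictly below ``cutoff``.

    No monotonicity is enforced: if P rebounds above the cutoff at a larger
    m through sampling noise, the first crossing still decides.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    records = ci_table(curve, conf_level=conf_level)
    eta = next((r.m for r in records if r.P < cutoff), None)
    return EtaDecision(
        method="confidence_interval",
        cutoff=cutoff,
        eta=eta,
        worksheet=_worksheet(records),
        details={
            "conf_level": conf_level,
            "t_crit": records[0].t_crit,
            "n": curve.n,
            "grid_exhausted": eta is None,
        },
    )
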