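"""The moving regression method for eta.

Slide a window of h consecutive grid points along the m-omega curve and fit
ordinary least squares of omega on m in each window.  Report per window

    S5  = 5 * slope        (omega change per 5-imputation increase)
    RS5 = 100 * S5 / mean(omega in window)   (the same, as a percent)

Scanning from low to high m, eta is the middle m of the first window with
|RS5| below the cutoff (default 10) -- unless that window is an outlier
artefact: a single aberrant omega can push one window's |RS5| under the
cutoff while neighbouring windows rebound above it.  Such windows are
detected, attributed to their outlier grid point o_m, and resolved by
averaging the RS5 of the two windows having o_m as their largest and
smallest m: if the |average| clears the cutoff o_m itself is eta, otherwise
every window containing o_m is treated as still above the cutoff and the
scan continues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision import EtaDecision
from .replication import OmegaCurve

__all__ = [
    "RegressionWindow",
    "OutlierResolution",
    "moving_windows",
    "detect_outliers",
    "resolve_outlier",
    "decide_eta_moving_regression",
]


@dataclass(frozen=True)
class RegressionWindow:
    """One h-point window with its OLS slope and derived statistics."""

    m_values: tuple
    omega_values: tuple
    slope: float
    S5: float
    omega_bar: float
    RS5: float

    @property
    def middle_m(self) -> int:
        k = len(self.m_values)
        if k % 2 == 0:
            raise ValueError("middle point undefined for an even-width window")
        return self.m_values[k // 2]


@dataclass(frozen=True)
class OutlierResolution:
    """Audit record of one application of the outlier-averaging rule."""

    o_m: int
    rs5_ending_at_o_m: float
    rs5_starting_at_o_m: float
    average: float
    accepted: bool


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / np.dot(xc, xc))


def moving_windows(curve: OmegaCurve, h: int = 3) -> list[RegressionWindow]:
    """All J-h+1 consecutive h-point windows of the curve, in grid order.

    S5, omega_bar and RS5 are computed from unrounded inputs throughout;
    rounding is a display concern only.
    """
    if h < 2:
        raise ValueError("window width h must be at least 2")
    m = np.asarray(curve.m, dtype=float)
    omega = np.asarray(curve.omega, dtype=float)
    if len(m) < h:
        raise ValueError(f"curve has {len(m)} grid points, fewer than h={h}")
    windows = []
    for j in range(len(m) - h + 1):
        x, y = m[j:j + h], omega[j:j + h]
        slope = _ols_slope(x, y)
        s5 = 5.0 * slope
        obar = float(y.mean())
        windows.append(
            RegressionWindow(
                m_values=tuple(int(v) for v in x),
                omega_values=tuple(float(v) for v in y),
                slope=slope,
                S5=s5,
                omega_bar=obar,
                RS5=100.0 * s5 / obar,
            )
        )
    return windows


def detect_outliers(windows: list[RegressionWindow], cutoff: float = 10.0) -> list[bool]:
    """Flag windows whose small |RS5| is an artefact of one aberrant omega.

    A window is an outlier iff (1) its |RS5| is below the cutoff and (2) at
    least one of the next three windows toward higher m has |RS5| above the
    cutoff.  The comparisons are strict, so |RS5| equal to the cutoff neither
    qualifies nor triggers condition (2).
    """
    abs_rs5 = [abs(w.RS5) for w in windows]
    flags = []
    for i in range(len(windows)):
        below = abs_rs5[i] < cutoff
        rebound = any(v > cutoff for v in abs_rs5[i + 1:i + 4])
        flags.append(below and rebound)
    return flags


def _outlier_grid_point(
    curve: OmegaCurve, windows: list[RegressionWindow], cluster: list[int]
) -> int:
    """Attribute a cluster of flagged windows to a single outlier omega.

    Candidates are the grid points shared by every window in the cluster.
    Among them, the outlier omega is the one deviating most from the linear
    interpolation of its two grid neighbours (grid endpoints cannot win:
    they have no two-sided neighbourhood, and the averaging rule could not
    resolve them anyway).
    """
    shared = set(windows[cluster[0]].m_values)
    for j in cluster[1:]:
        shared &= set(windows[j].m_values)
    if not shared:
        raise ValueError("flagged windows share no grid point")
    candidates = sorted(shared)
    if len(candidates) == 1:
        return candidates[0]
    m_list = [int(v) for v in curve.m]
    omega = list(curve.omega)
    deviations = []
    for cand in candidates:
        k = m_list.index(cand)
        if 0 < k < len(m_list) - 1:
            frac = (m_list[k] - m_list[k - 1]) / (m_list[k + 1] - m_list[k - 1])
            interp = omega[k - 1] + frac * (omega[k + 1] - omega[k - 1])
            deviations.append(abs(omega[k] - interp))
        else:
            deviations.append(-np.inf)
    return candidates[int(np.argmax(deviations))]


def resolve_outlier(
    windows: list[RegressionWindow], o_m: int, cutoff: float = 10.0
) -> OutlierResolution:
    """Apply the averaging rule at outlier grid point ``o_m``.

    Averages the RS5 of the window whose largest m is o_m with that of the
    window whose smallest m is o_m.  ``accepted`` means the |average| is
    below the cutoff, in which case o_m itself is eta; otherwise every RS5
    from a window containing o_m is treated as exceeding the cutoff.
    """
    ending = [w for w in windows if w.m_values[-1] == o_m]
    starting = [w for w in windows if w.m_values[0] == o_m]
    if not ending or not starting:
        raise ValueError(
            f"outlier at grid edge: no window has m={o_m} as both a largest "
            "and a smallest member"
        )
    rs5_end = ending[0].RS5
    rs5_start = starting[0].RS5
    avg = 0.5 * (rs5_end + rs5_start)
    return OutlierResolution(
        o_m=int(o_m),
        rs5_ending_at_o_m=rs5_end,
        rs5_starting_at_o_m=rs5_start,
        average=avg,
        accepted=abs(avg) < cutoff,
    )


def _worksheet(windows: list[RegressionWindow], flags: list[bool]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "m_window": [", ".join(str(m) for m in w.m_values) for w in windows],
            "omega_window": [", ".join(f"{o:.4f}" for o in w.omega_values) for w in windows],
            "S5": [w.S5 for w in windows],
            "omega_bar": [w.omega_bar for w in windows],
            "RS5": [w.RS5 for w in windows],
            "outlier": flags,
        }
    )


def decide_eta_moving_regression(
    curve: OmegaCurve, h: int = 3, cutoff: float = 10.0
) -> EtaDecision:
    """Scan the moving-regression worksheet for the first sufficient window.

    Returns an :class:`EtaDecision` whose worksheet mirrors the hand
    worksheet (m window, omega window, S5, omega_bar, RS5, outlier flag) and
    whose ``outlier_events`` record each application of the averaging rule.
    """
    if h % 2 == 0:
        raise ValueError("h must be odd so each window has a middle point")
    windows = moving_windows(curve, h=h)
    flags = detect_outliers(windows, cutoff=cutoff)

    # group flagged windows into overlapping clusters, one outlier omega each
    clusters: list[list[int]] = []
    for i, fl in enumerate(flags):
        if not fl:
            continue
        if clusters and i - clusters[-1][-1] < h:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    cluster_of = {i: c for c in clusters for i in c}

    events: list[dict] = []
    treated_exceeding: set[int] = set()
    resolved: set[int] = set()
    eta: int | None = None

    for i, w in enumerate(windows):
        if flags[i] and i not in resolved:
            o_m = _outlier_grid_point(curve, windows, cluster_of[i])
            affected = [j for j, wj in enumerate(windows) if o_m in wj.m_values]
            resolved.update(affected)
            try:
                res = resolve_outlier(windows, o_m, cutoff=cutoff)
            except ValueError:
                # o_m too close to a grid edge for the averaging rule: the
                # small |RS5| is suspect but unresolvable, so treat the whole
                # cluster as exceeding the cutoff and keep scanning
                events.append({"o_m": int(o_m), "average": None,
                               "accepted": False,
                               "note": "unresolvable at grid edge"})
                treated_exceeding.update(affected)
                continue
            events.append(vars(res).copy())
            if res.accepted:
                eta = res.o_m
                break
            treated_exceeding.update(affected)
            continue
        if i in treated_exceeding or flags[i]:
            continue
        if abs(w.RS5) < cutoff:
            eta = w.middle_m
            break

    details = {"h": h, "grid_exhausted": eta is None}
    return EtaDecision(
        method="moving_regression",
        cutoff=cutoff,
        eta=eta,
        worksheet=_worksheet(windows, flags),
        outlier_events=events,
        details=details,
    )
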