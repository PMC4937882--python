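"""Moving regression method: windows, outlier rule, eta decision."""

import numpy as np
import pytest

import miomega as mo
from miomega.replication import OmegaCurve


def test_published_worksheet_windows(worksheet_curve):
    """First and third windows of the practice-size worksheet reproduce the
    printed S5, omega_bar and RS5 to their printed precision."""
    ws = mo.moving_windows(worksheet_curve, h=3)
    assert len(ws) == 11  # 13 grid points -> J - h + 1 windows
    w0 = ws[0]
    assert w0.m_values == (2, 3, 5)
    assert round(w0.S5, 4) == -0.5585
    assert round(w0.omega_bar, 4) == 0.4169
    w2 = ws[2]
    assert w2.m_values == (5, 10, 15)
    assert round(w2.S5, 4) == -0.0721
    assert round(w2.RS5, 2) == -40.80


def test_flat_window_has_zero_slope():
    curve = OmegaCurve.from_table([2, 3, 5, 10], [0.2, 0.2, 0.2, 0.2])
    for w in mo.moving_windows(curve, h=3):
        assert w.slope == pytest.approx(0.0, abs=1e-15)
        assert w.RS5 == pytest.approx(0.0, abs=1e-12)


def test_windows_match_normal_equations_oracle():
    """OLS slope agrees with brute-force normal equations to 1e-10 relative."""
    rng = np.random.default_rng(77)
    for _ in range(300):
        m = np.sort(rng.choice(np.arange(2, 200), size=3, replace=False))
        omega = rng.uniform(0.01, 1.0, size=3)
        w = mo.moving_windows(OmegaCurve.from_table(m, omega), h=3)[0]
        X = np.column_stack([np.ones(3), m.astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ omega)
        assert w.slope == pytest.approx(beta[1], rel=1e-10)


def test_too_few_points_and_even_h_rejected(worksheet_curve):
    with pytest.raises(ValueError):
        mo.moving_windows(OmegaCurve.from_table([2, 3], [0.5, 0.4]), h=3)
    with pytest.raises(ValueError, match="odd"):
        mo.decide_eta_moving_regression(worksheet_curve, h=4)


def test_outlier_detection_on_published_worksheet(worksheet_curve):
    """Exactly the two windows straddling the aberrant omega at m=25 (the
    printed RS5 ~ -1.03 and -9.03 rows) are flagged."""
    ws = mo.moving_windows(worksheet_curve, h=3)
    flags = mo.detect_outliers(ws, cutoff=10.0)
    flagged = [w.m_values for w, f in zip(ws, flags) if f]
    assert flagged == [(15, 20, 25), (20, 25, 30)]


def test_monotone_curve_has_no_outliers():
    curve = OmegaCurve.from_table(
        [2, 3, 5, 10, 15, 20], [0.60, 0.40, 0.25, 0.20, 0.19, 0.185]
    )
    ws = mo.moving_windows(curve, h=3)
    assert not any(mo.detect_outliers(ws, cutoff=10.0))


def test_last_window_cannot_be_outlier(worksheet_curve):
    ws = mo.moving_windows(worksheet_curve, h=3)
    flags = mo.detect_outliers(ws, cutoff=10.0)
    assert flags[-1] is False  # no upstream windows: condition 2 vacuous


def test_resolve_outlier_at_m25_rejects(worksheet_curve):
    ws = mo.moving_windows(worksheet_curve, h=3)
    res = mo.resolve_outlier(ws, o_m=25, cutoff=10.0)
    # averages the (15,20,25) and (25,30,35) RS5 values; the printed
    # worksheet shows -1.03 and -27.79 averaging to -14.41 (its first value
    # carries table rounding; unrounded arithmetic gives -0.99 and -27.73)
    assert res.average == pytest.approx(-14.41, abs=0.1)
    assert abs(res.average) > 10.0
    assert not res.accepted


def dip_curve() -> OmegaCurve:
    """Steep early decline, then a plateau near 0.23 with a dip at m=20.

    The window ending at the dip slopes steeply down, the window starting at
    it rebounds steeply up; the two slopes nearly cancel, so the averaging
    rule accepts m=20.
    """
    return OmegaCurve.from_table(
        [2, 5, 10, 15, 20, 25, 30, 35],
        [1.0, 0.5, 0.25, 0.24, 0.15, 0.235, 0.23, 0.228],
    )


def test_resolve_outlier_accepts_below_cutoff():
    ws = mo.moving_windows(dip_curve(), h=3)
    res = mo.resolve_outlier(ws, o_m=20, cutoff=10.0)
    # downslope into the dip and rebound out of it nearly cancel
    assert res.rs5_ending_at_o_m < -10.0
    assert res.rs5_starting_at_o_m > 10.0
    assert res.accepted and abs(res.average) < 10.0


def test_resolve_outlier_at_grid_edge_errors(worksheet_curve):
    ws = mo.moving_windows(worksheet_curve, h=3)
    with pytest.raises(ValueError, match="grid edge"):
        mo.resolve_outlier(ws, o_m=2, cutoff=10.0)
    with pytest.raises(ValueError, match="grid edge"):
        mo.resolve_outlier(ws, o_m=100, cutoff=10.0)


def test_decision_on_published_worksheet(worksheet_curve):
    """Full scan: the outlier at m=25 is rejected by the averaging rule and
    the first qualifying window is (40, 60, 80), so eta = 60."""
    dec = mo.decide_eta_moving_regression(worksheet_curve, h=3, cutoff=10.0)
    assert dec.eta == 60
    assert len(dec.outlier_events) == 1
    ev = dec.outlier_events[0]
    assert ev["o_m"] == 25 and not ev["accepted"]
    assert dec.worksheet.shape[0] == 11
    assert list(dec.worksheet["outlier"]) == [False] * 4 + [True, True] + [False] * 5


def test_unresolvable_edge_outlier_treated_as_exceeding():
    """An outlier attributed to a near-edge grid point cannot be averaged
    (one flanking window is missing); the scan treats its windows as above
    the cutoff instead of crashing or accepting them."""
    curve = OmegaCurve.from_table(
        [2, 3, 5, 10, 15, 20], [0.30, 0.36, 0.295, 0.18, 0.12, 0.10]
    )
    ws = mo.moving_windows(curve, h=3)
    flags = mo.detect_outliers(ws, cutoff=10.0)
    assert flags[0]  # bump at m=3 makes the first window spuriously flat
    dec = mo.decide_eta_moving_regression(curve, h=3, cutoff=10.0)
    assert dec.eta is None and dec.details["grid_exhausted"]
    assert dec.outlier_events == [
        {"o_m": 3, "average": None, "accepted": False,
         "note": "unresolvable at grid edge"}
    ]


def test_decision_all_above_cutoff_yields_none():
    curve = OmegaCurve.from_table([2, 3, 5, 10, 15], [1.0, 0.5, 0.25, 0.12, 0.06])
    dec = mo.decide_eta_moving_regression(curve, cutoff=1.0)
    assert dec.eta is None
    assert dec.details["grid_exhausted"]


def test_decision_generous_cutoff_takes_first_window(worksheet_curve):
    dec = mo.decide_eta_moving_regression(worksheet_curve, cutoff=1e6)
    assert dec.eta == 3  # middle of the first window (2, 3, 5)


def test_decision_invariant_to_grid_points_above_eta(worksheet_curve):
    m = list(worksheet_curve.m) + [150, 200]
    omega = list(worksheet_curve.omega) + [0.030, 0.029]
    extended = OmegaCurve.from_table(m, omega)
    dec = mo.decide_eta_moving_regression(extended, h=3, cutoff=10.0)
    assert dec.eta == 60


def test_accepted_outlier_becomes_eta():
    """When the averaged |RS5| clears the cutoff, o_m itself is eta."""
    curve = dip_curve()
    ws = mo.moving_windows(curve, h=3)
    flags = mo.detect_outliers(ws, cutoff=10.0)
    # the window straddling the dip is flagged (small |RS5|, rebound above
    # the cutoff right after it) and attributed to the dip point m=20
    flagged = [w.m_values for w, f in zip(ws, flags) if f]
    assert (15, 20, 25) in flagged
    dec = mo.decide_eta_moving_regression(curve, h=3, cutoff=10.0)
    assert dec.eta == 20
    assert dec.outlier_events == [dec.outlier_events[0]]
    ev = dec.outlier_events[0]
    assert ev["o_m"] == 20 and ev["accepted"]
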