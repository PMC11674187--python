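"""Peak, exponential, Boltzmann and action-potential measurements."""

import numpy as np
import pytest

from cardioblock.trace_analysis import (
    ap_metrics,
    fit_biexp,
    fit_boltzmann,
    fit_monoexp,
    measure_peak,
)
from cardioblock.traces import SweepSet


def _sweepset(y, dt=0.01, kind="current", units="pA"):
    return SweepSet(sample_interval=dt, sweeps=np.atleast_2d(y),
                    signal_kind=kind, units=units)


# ---------------------------------------------------------------------------
# measure_peak
# ---------------------------------------------------------------------------

def test_flat_trace_peak_zero_at_window_start():
    ss = _sweepset(np.zeros(1000))
    pk = measure_peak(ss, (2.0, 8.0), "inward")[0]
    assert pk.peak_value == 0.0
    assert pk.peak_time == 2.0  # earliest-sample tie-break


def test_peak_matches_dense_grid_argmin():
    t = np.arange(0, 50, 0.01)
    y = -np.exp(-((t - 17.3) ** 2) / 4.0) * 120.0
    ss = _sweepset(y)
    pk = measure_peak(ss, (5.0, 45.0), "inward")[0]
    dense = t[np.argmin(y)]
    assert abs(pk.peak_time - dense) <= 0.01
    assert pk.peak_value == pytest.approx(y.min())


def test_peak_invariant_to_constant_offset_with_baseline_subtraction():
    t = np.arange(0, 50, 0.01)
    y = -np.exp(-((t - 20.0) ** 2) / 9.0) * 80.0
    a = measure_peak(_sweepset(y), (10.0, 40.0), "inward", baseline_window=(0.0, 5.0))[0]
    b = measure_peak(_sweepset(y + 37.5), (10.0, 40.0), "inward", baseline_window=(0.0, 5.0))[0]
    assert a.peak_value == pytest.approx(b.peak_value, abs=1e-9)


def test_known_peak_ratio_recovered():
    """Two sweeps scaled by a known inhibition factor report that exact ratio."""
    t = np.arange(0, 60, 0.01)
    base = -np.exp(-((t - 25.0) ** 2) / 6.0) * 500.0
    inhibited = (1.0 - 0.6953) * base
    ss = SweepSet(sample_interval=0.01, sweeps=np.vstack([base, inhibited]))
    pks = measure_peak(ss, (10.0, 50.0), "inward")
    ratio = 1.0 - pks[1].peak_value / pks[0].peak_value
    assert ratio == pytest.approx(0.6953, abs=0.001)


def test_empty_window_raises():
    ss = _sweepset(np.zeros(100))
    with pytest.raises(ValueError):
        measure_peak(ss, (5.0, 5.0), "inward")


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------

def test_monoexp_noiseless_self_consistency():
    t = np.arange(0, 20, 0.01)
    y = -800.0 * np.exp(-t / 2.36) + 5.0
    fit = fit_monoexp(_sweepset(y), (0.0, 20.0))
    assert fit.tau == pytest.approx(2.36, abs=0.01)
    assert fit.converged


def test_monoexp_bias_small_at_snr20():
    """Monte-Carlo over the noise generator: median tau bias < 2%."""
    rng = np.random.default_rng(42)
    t = np.arange(0, 15, 0.01)
    clean = -1000.0 * np.exp(-t / 2.0)
    taus = []
    for _ in range(100):
        y = clean + rng.normal(0, 50.0, size=t.size)  # SNR 20 at peak
        taus.append(fit_monoexp(_sweepset(y), (0.0, 15.0)).tau)
    assert abs(np.median(taus) / 2.0 - 1.0) < 0.02


def test_biexp_recovers_two_time_scales():
    t = np.arange(0, 40, 0.01)
    y = -600.0 * np.exp(-t / 1.5) - 150.0 * np.exp(-t / 9.0) + 2.0
    fast, slow = fit_biexp(_sweepset(y), (0.0, 40.0))
    assert fast.tau == pytest.approx(1.5, rel=0.02)
    assert slow.tau == pytest.approx(9.0, rel=0.02)


def test_monoexp_window_too_small_raises():
    ss = _sweepset(np.zeros(100))
    with pytest.raises(ValueError, match="at least 10"):
        fit_monoexp(ss, (0.0, 0.05))


# ---------------------------------------------------------------------------
# Boltzmann fits
# ---------------------------------------------------------------------------

def test_boltzmann_exact_recovery_and_midpoint():
    v = np.arange(-80.0, 21.0, 5.0)
    y = 1.0 / (1.0 + np.exp((-40.0 - v) / 5.0))
    fit = fit_boltzmann(v, y, kind="activation")
    assert fit.v_half == pytest.approx(-40.0, abs=1e-6)
    assert fit.k == pytest.approx(5.0, abs=1e-6)
    # the half-response voltage is bracketed by the grid point at -40
    assert abs(fit.v_half - v[np.argmin(np.abs(y - 0.5))]) <= 2.5


def test_boltzmann_paired_shift_recovered():
    """Control/drug curves generated 12 mV apart give ΔV_half = -12 ± 0.5."""
    v = np.arange(-120.0, -19.0, 5.0)
    ctrl = 1.0 / (1.0 + np.exp((v + 65.0) / 6.0))  # inactivation-type
    drug = 1.0 / (1.0 + np.exp((v + 77.0) / 6.0))
    f_c = fit_boltzmann(v, ctrl, kind="inactivation")
    f_d = fit_boltzmann(v, drug, kind="inactivation")
    assert f_d.v_half - f_c.v_half == pytest.approx(-12.0, abs=0.5)


def test_boltzmann_non_spanning_flagged():
    v = np.arange(-80.0, -49.0, 5.0)
    y = 1.0 / (1.0 + np.exp((-20.0 - v) / 5.0))  # all << 0.5
    with pytest.warns(UserWarning, match="low-confidence"):
        fit = fit_boltzmann(v, y)
    assert not fit.spanning


# ---------------------------------------------------------------------------
# AP metrics
# ---------------------------------------------------------------------------

def _trapezoid_ap(rp=-80.0, peak=30.0, plateau_ms=200.0, dt=0.1):
    """Idealized AP: fast upstroke at 50 ms, linear repolarization."""
    t = np.arange(0, 500, dt)
    v = np.full_like(t, rp)
    up = (t >= 50.0) & (t < 51.0)
    v[up] = rp + (peak - rp) * (t[up] - 50.0) / 1.0
    plateau = (t >= 51.0) & (t < 51.0 + plateau_ms)
    v[plateau] = peak
    down = (t >= 51.0 + plateau_ms) & (t < 101.0 + plateau_ms)
    v[down] = peak - (peak - rp) * (t[down] - 51.0 - plateau_ms) / 50.0
    return SweepSet(sample_interval=dt, sweeps=v[None, :], signal_kind="voltage",
                    units="mV")


def test_apd90_of_constructed_trapezoid():
    ss = _trapezoid_ap()
    m = ap_metrics(ss, [49.0])[0]
    assert m.captured
    assert m.resting_potential == pytest.approx(-80.0, abs=0.1)
    assert m.peak_overshoot == pytest.approx(30.0, abs=0.1)
    # take-off at ~50.5 (max dV/dt inside the 1 ms upstroke); 90% repolarization
    # occurs 45 ms into the 50 ms linear phase
    expected = (51.0 + 200.0 + 45.0) - m.takeoff_time
    assert m.apd90 == pytest.approx(expected, abs=0.5)


def test_apd90_monotone_under_faster_repolarization():
    slow = _trapezoid_ap(plateau_ms=220.0)
    fast = _trapezoid_ap(plateau_ms=150.0)
    m_slow = ap_metrics(slow, [49.0])[0]
    m_fast = ap_metrics(fast, [49.0])[0]
    assert m_fast.apd90 < m_slow.apd90


def test_no_capture_reported_explicitly():
    t = np.arange(0, 500, 0.1)
    v = np.full_like(t, -80.0)
    v[(t >= 50) & (t < 60)] = -70.0  # electrotonic bump only
    ss = SweepSet(sample_interval=0.1, sweeps=v[None, :], signal_kind="voltage",
                  units="mV")
    m = ap_metrics(ss, [49.0])[0]
    assert not m.captured
    assert np.isnan(m.apd90)


def test_apd90_grid_refinement_stable():
    coarse = _trapezoid_ap(dt=0.2)
    fine = _trapezoid_ap(dt=0.1)
    a = ap_metrics(coarse, [49.0])[0].apd90
    b = ap_metrics(fine, [49.0])[0].apd90
    assert abs(a - b) < 1.0
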