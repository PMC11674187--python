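"""Synthetic-trace generator: Markov scheme invariants, decay kinetics, noise."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import curve_fit

from cardioblock.protocols import build_protocol
from cardioblock.synth import (
    NavMarkovParams,
    NoiseSpec,
    add_noise,
    hh_presets,
    simulate_hh_trace,
    simulate_markov_trace,
    _rate_matrix,
)
from cardioblock.trace_analysis import measure_peak
from tests.conftest import markov_sweeps, udb_peak_seqs


def test_rate_matrix_is_a_generator_and_propagator_is_stochastic():
    """Columns of Q sum to zero, so exp(Q dt) conserves probability and
    keeps occupancies in [0, 1] at every voltage the library visits."""
    params = NavMarkovParams(k_ob=0.00215, k_ob_inv=0.189, k_ib=6.7e-4,
                             k_ib_inv=0.18, drug_conc=200.0)
    for v in (-120.0, -110.0, -90.0, -50.0, -10.0, 0.0, 40.0, 60.0):
        Q = _rate_matrix(params, v)
        assert np.allclose(Q.sum(axis=0), 0.0, atol=1e-12)
        T = expm(Q * 0.005)
        assert np.all(T >= -1e-12)
        assert np.allclose(T.sum(axis=0), 1.0, atol=1e-10)


def test_occupancy_normalization_along_every_library_protocol():
    params = NavMarkovParams(k_ob=0.00215, k_ob_inv=0.189, drug_conc=50.0)
    for name in ("nav_standard", "nav_udb", "nav_activation"):
        proto = build_protocol(name)
        p = np.array([1.0, 0, 0, 0, 0])
        for v0, v1, dur in proto.resolve_sweep(proto.n_sweeps - 1):
            T = expm(_rate_matrix(params, 0.5 * (v0 + v1)) * dur)
            p = T @ p
            assert np.all(p >= -1e-10) and np.all(p <= 1 + 1e-10)
            assert p.sum() == pytest.approx(1.0, abs=1e-8)


def test_zero_conductance_gives_zero_current():
    proto = build_protocol("nav_standard", n_sweeps=1)
    ss = simulate_markov_trace(NavMarkovParams(g_max=0.0), proto, dt=0.01)
    assert np.all(ss.sweeps == 0.0)


def test_zero_block_rates_make_drug_irrelevant():
    proto = build_protocol("nav_standard", n_sweeps=1)
    a = simulate_markov_trace(NavMarkovParams(drug_conc=0.0), proto, dt=0.01)
    b = simulate_markov_trace(NavMarkovParams(drug_conc=10.0), proto, dt=0.01)
    np.testing.assert_array_equal(a.sweeps, b.sweeps)


def test_peak_current_inward_and_linear_in_gmax():
    proto = build_protocol("nav_standard", n_sweeps=1)
    win = proto.segment_window(0, "activation")
    peaks = []
    for g in (50.0, 100.0, 200.0):
        ss = simulate_markov_trace(NavMarkovParams(g_max=g), proto, dt=0.01)
        pk = measure_peak(ss, win, "inward")[0]
        assert pk.peak_value < 0.0
        peaks.append(pk.peak_value)
    assert peaks[1] / peaks[0] == pytest.approx(2.0, rel=1e-9)
    assert peaks[2] / peaks[1] == pytest.approx(2.0, rel=1e-9)


def test_elicited_decay_matches_ground_truth_tau():
    """Independent nonlinear-least-squares fit of the generated decay
    recovers the inactivation constant within 2%."""
    tau_true = 2.36
    proto = build_protocol("nav_standard", n_sweeps=1)
    ss = simulate_markov_trace(NavMarkovParams(tau_i=tau_true), proto, dt=0.005)
    win = proto.segment_window(0, "activation")
    pk = measure_peak(ss, win, "inward")[0]
    t = ss.time
    sel = (t >= pk.peak_time + 0.5) & (t <= win[1] - 1.0)
    popt, _ = curve_fit(
        lambda x, a, tau, c: a * np.exp(-x / tau) + c,
        t[sel] - t[sel][0], ss.sweeps[0][sel], p0=(-1000.0, 1.0, 0.0),
    )
    assert popt[1] == pytest.approx(tau_true, rel=0.02)


def test_udb_first_interval_follows_two_state_recurrence():
    """With block rates zero, the first-pair availability ratio equals
    1 - (1 - e^{-t_d/tau_i}) e^{-t_r/tau_r} within 3% for every t_r."""
    tau_i, tau_r = 2.47, 3.81
    ss, proto, _ = markov_sweeps("nav_udb", 0.0)
    # block rates are irrelevant at zero concentration
    seqs = udb_peak_seqs(ss, proto, "control")
    for m in seqs:
        expected = 1.0 - (1.0 - np.exp(-m.t_d / tau_i)) * np.exp(-m.t_r[0] / tau_r)
        assert m.peak_sequence[1] == pytest.approx(expected, rel=0.03)


def test_stiffness_guard_rejects_coarse_dt():
    proto = build_protocol("nav_udb")
    with pytest.raises(ValueError, match="too coarse"):
        simulate_markov_trace(NavMarkovParams(), proto, dt=1.0)


def test_negative_rates_rejected():
    with pytest.raises(ValueError):
        NavMarkovParams(k_ob=-1.0)


def test_noise_identity_determinism_and_sd():
    proto = build_protocol("hold_only", level=-90.0, duration=1000.0)
    ss = simulate_markov_trace(NavMarkovParams(g_max=0.0), proto, dt=0.01)
    same = add_noise(ss, NoiseSpec(sd=0.0))
    np.testing.assert_array_equal(same.sweeps, ss.sweeps)
    a = add_noise(ss, NoiseSpec(sd=5.0, seed=7))
    b = add_noise(ss, NoiseSpec(sd=5.0, seed=7))
    np.testing.assert_array_equal(a.sweeps, b.sweeps)
    assert np.all(ss.sweeps == 0.0)  # input untouched
    assert a.sweeps.std() == pytest.approx(5.0, rel=0.03)


def test_noise_streams_stable_under_sweep_count_change():
    """Per-sweep seed splitting: adding sweeps never reshuffles earlier ones."""
    proto2 = build_protocol("nav_standard", n_sweeps=2)
    proto5 = build_protocol("nav_standard", n_sweeps=5)
    s2 = add_noise(simulate_markov_trace(NavMarkovParams(), proto2, dt=0.01),
                   NoiseSpec(sd=3.0, seed=11))
    s5 = add_noise(simulate_markov_trace(NavMarkovParams(), proto5, dt=0.01),
                   NoiseSpec(sd=3.0, seed=11))
    np.testing.assert_array_equal(s2.sweeps, s5.sweeps[:2])


def test_hh_surrogate_activates_and_scales_with_block():
    proto = build_protocol("cav_pharm", n_sweeps=1)
    pars = hh_presets()["cav"]
    ss = simulate_hh_trace(pars, proto, dt=0.05)
    win = proto.segment_window(0, "activation")
    pk = measure_peak(ss, win, "inward")[0]
    assert pk.peak_value < 0.0  # inward Ca-like current at 0 mV
    from dataclasses import replace

    half = simulate_hh_trace(replace(pars, block_fraction=0.5), proto, dt=0.05)
    np.testing.assert_allclose(half.sweeps, 0.5 * ss.sweeps, rtol=1e-12)
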