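"""Measurements derived from raw sweeps: peaks, exponential decay constants,
Boltzmann voltage-dependence curves and action-potential metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from cardioblock.protocols import VoltageProtocol
from cardioblock.traces import SweepSet

__all__ = [
    "PeakMeasurement",
    "ExpFit",
    "BoltzmannFit",
    "APMetrics",
    "measure_peak",
    "fit_monoexp",
    "fit_boltzmann",
    "ap_metrics",
    "udb_peak_sequences",
]


@dataclass(frozen=True)
class PeakMeasurement:
    sweep_index: int
    peak_value: float  # baseline-subtracted, trace units
    peak_time: float  # ms
    baseline: float  # trace units


@dataclass(frozen=True)
class ExpFit:
    """Monoexponential fit A*exp(-t/tau) + C over a window."""

    tau: float  # ms
    amplitude: float
    offset: float
    window: tuple[float, float]  # ms
    residual_rms: float
    converged: bool = True


@dataclass(frozen=True)
class BoltzmannFit:
    """Fit of floor + (ceiling-floor) / (1 + exp((v_half - V)/k))."""

    v_half: float  # mV
    k: float  # mV; negative slope = inactivation-type curve
    floor: float
    ceiling: float
    spanning: bool = True  # data bracket the transition


@dataclass(frozen=True)
class APMetrics:
    """Stimulus-aligned action-potential metrics.

    APD90 is measured from the maximum-dV/dt take-off to 90% repolarization
    from the AP peak toward the pre-stimulus resting level (not toward an
    absolute reference voltage), which remains meaningful for depolarized
    hiPSC-CM-like traces.
    """

    apd90: float  # ms; nan if no capture
    resting_potential: float  # mV
    peak_overshoot: float  # mV
    max_dvdt: float  # mV/ms
    takeoff_time: float  # ms
    captured: bool = True


def _window_slice(time: np.ndarray, window: tuple[float, float]) -> slice:
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window {window}")
    i0 = int(np.searchsorted(time, t0 - 1e-9))
    i1 = int(np.searchsorted(time, t1 + 1e-9))
    if i1 - i0 < 1:
        raise ValueError(f"window {window} contains no samples")
    return slice(i0, i1)


def measure_peak(
    sweeps: SweepSet,
    window: tuple[float, float],
    polarity: str = "inward",
    baseline_window: tuple[float, float] | None = None,
    sweep_index: int | None = None,
) -> list[PeakMeasurement]:
    """Baseline-subtracted extremum within a window, earliest sample on ties.

    ``polarity`` 'inward' takes the minimum (negative currents), 'outward'
    the maximum.  The baseline is the mean over ``baseline_window`` (0 if
    omitted).  Returns one measurement per sweep (or only ``sweep_index``).
    """
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    t = sweeps.time
    sl = _window_slice(t, window)
    indices = range(sweeps.n_sweeps) if sweep_index is None else [sweep_index]
    out = []
    for sw in indices:
        y = sweeps.sweeps[sw]
        base = 0.0
        if baseline_window is not None:
            base = float(np.mean(y[_window_slice(t, baseline_window)]))
        seg = y[sl] - base
        k = int(np.argmin(seg)) if polarity == "inward" else int(np.argmax(seg))
        out.append(
            PeakMeasurement(
                sweep_index=sw,
                peak_value=float(seg[k]),
                peak_time=float(t[sl][k]),
                baseline=base,
            )
        )
    return out


def fit_monoexp(
    sweeps: SweepSet,
    window: tuple[float, float],
    sweep_index: int = 0,
) -> ExpFit:
    """Least-squares monoexponential fit A*exp(-t/tau) + C within a window.

    Uses a Levenberg–Marquardt local fit with up to three restarts from
    perturbed initial guesses; a non-converged result is returned flagged,
    never silently.
    """
    import lmfit

    t = sweeps.time
    sl = _window_slice(t, window)
    tt = t[sl] - t[sl][0]
    yy = sweeps.sweeps[sweep_index][sl]
    if len(yy) < 10:
        raise ValueError("window must contain at least 10 samples")

    span = float(tt[-1])
    amp0 = float(yy[0] - yy[-1])
    tau0 = max(span / 3.0, 1e-3)

    def model(x, amplitude, tau, offset):
        return amplitude * np.exp(-x / tau) + offset

    m = lmfit.Model(model)
    best = None
    for mult in (1.0, 0.3, 3.0):
        params = m.make_params(
            amplitude=amp0 if amp0 != 0 else 1.0,
            tau=tau0 * mult,
            offset=float(yy[-1]),
        )
        params["tau"].set(min=1e-6)
        try:
            res = m.fit(yy, params, x=tt)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
        if res.success and res.params["tau"].stderr is not None:
            best = res if res.chisqr <= best.chisqr else best
            break
    if best is None:
        return ExpFit(
            tau=tau0, amplitude=amp0, offset=float(yy[-1]), window=window,
            residual_rms=float(np.std(yy)), converged=False,
        )
    rms = float(np.sqrt(np.mean(best.residual**2)))
    return ExpFit(
        tau=float(best.params["tau"].value),
        amplitude=float(best.params["amplitude"].value),
        offset=float(best.params["offset"].value),
        window=window,
        residual_rms=rms,
        converged=bool(best.success),
    )


def fit_biexp(
    sweeps: SweepSet,
    window: tuple[float, float],
    sweep_index: int = 0,
) -> tuple[ExpFit, ExpFit]:
    """Double-exponential fit A1*exp(-t/tau1) + A2*exp(-t/tau2) + C.

    Returns the two components as :class:`ExpFit` pairs (fast first).  Used
    where a current decay is governed by two coupled first-order processes
    (e.g. inactivation plus open-channel block/unblock): the sum of the two
    fitted rates then equals the sum of the underlying transition rates.
    """
    import lmfit

    t = sweeps.time
    sl = _window_slice(t, window)
    tt = t[sl] - t[sl][0]
    yy = sweeps.sweeps[sweep_index][sl]
    if len(yy) < 20:
        raise ValueError("window must contain at least 20 samples")
    amp0 = float(yy[0] - yy[-1])
    span = float(tt[-1])

    def model(x, a1, tau1, a2, tau2, offset):
        return a1 * np.exp(-x / tau1) + a2 * np.exp(-x / tau2) + offset

    m = lmfit.Model(model)
    params = m.make_params(
        a1=0.8 * amp0, tau1=max(span / 10.0, 1e-3),
        a2=0.2 * amp0, tau2=max(span / 2.0, 1e-2),
        offset=float(yy[-1]),
    )
    params["tau1"].set(min=1e-6)
    params["tau2"].set(min=1e-6)
    res = m.fit(yy, params, x=tt)
    rms = float(np.sqrt(np.mean(res.residual**2)))
    comps = sorted(
        [
            (float(res.params["tau1"].value), float(res.params["a1"].value)),
            (float(res.params["tau2"].value), float(res.params["a2"].value)),
        ]
    )
    return tuple(
        ExpFit(
            tau=tau, amplitude=a, offset=float(res.params["offset"].value),
            window=window, residual_rms=rms, converged=bool(res.success),
        )
        for tau, a in comps
    )


def fit_boltzmann(
    voltages,
    normalized_response,
    kind: str = "activation",
) -> BoltzmannFit:
    """Boltzmann fit of a normalized conductance/availability curve.

    ``kind`` 'activation' fits 1/(1 + exp((v_half - V)/k)) (rising with V);
    'inactivation' fits the mirrored, falling form.  Floor and ceiling are
    co-fitted.  Data that do not span the transition (no response below 0.3
    and above 0.7) yield a flagged low-confidence fit.
    """
    import lmfit

    v = np.asarray(voltages, dtype=float)
    y = np.asarray(normalized_response, dtype=float)
    if len(v) < 5:
        raise ValueError("need at least 5 points spanning the transition")
    if kind not in ("activation", "inactivation"):
        raise ValueError("kind must be 'activation' or 'inactivation'")
    sign = 1.0 if kind == "activation" else -1.0

    spanning = bool((y.min() < 0.3) and (y.max() > 0.7))
    if not spanning:
        warnings.warn("data do not span the transition: low-confidence fit", stacklevel=2)

    def model(x, v_half, k, floor, ceiling):
        return floor + (ceiling - floor) / (1.0 + np.exp(sign * (v_half - x) / k))

    m = lmfit.Model(model)
    v50_guess = float(np.interp(0.5, y, v)) if np.all(np.diff(y) >= 0) else float(
        v[np.argmin(np.abs(y - 0.5))]
    )
    params = m.make_params(v_half=v50_guess, k=6.0, floor=float(y.min()), ceiling=float(y.max()))
    params["k"].set(min=1e-3)
    res = m.fit(y, params, x=v)
    k_fit = float(res.params["k"].value)
    return BoltzmannFit(
        v_half=float(res.params["v_half"].value),
        k=sign * k_fit,
        floor=float(res.params["floor"].value),
        ceiling=float(res.params["ceiling"].value),
        spanning=spanning,
    )


def ap_metrics(
    voltage: SweepSet,
    stimulus_times,
    sweep_index: int = 0,
    rp_window_ms: float = 20.0,
    capture_threshold_mV: float = 0.0,
    repolarization_fraction: float = 0.9,
) -> list[APMetrics]:
    """Per-stimulus AP metrics from a current-clamp voltage trace.

    For each stimulus: RP = mean voltage over ``rp_window_ms`` immediately
    before the stimulus; take-off at the maximum dV/dt after the stimulus;
    APD90 = time from take-off until the voltage falls below
    peak - 0.9*(peak - RP).  A beat whose peak stays below
    ``capture_threshold_mV`` is reported as not captured (APD90 = nan).
    """
    if voltage.signal_kind != "voltage":
        raise ValueError("ap_metrics requires a voltage trace")
    t = voltage.time
    y = voltage.sweeps[sweep_index]
    dt = voltage.sample_interval
    dvdt = np.gradient(y, dt)
    stim = np.atleast_1d(np.asarray(stimulus_times, dtype=float))
    out = []
    for si, t_stim in enumerate(stim):
        i_stim = int(np.searchsorted(t, t_stim))
        i_rp0 = max(0, i_stim - int(round(rp_window_ms / dt)))
        rp = float(np.mean(y[i_rp0:i_stim])) if i_stim > i_rp0 else float(y[0])
        t_end = stim[si + 1] if si + 1 < len(stim) else t[-1]
        i_end = int(np.searchsorted(t, t_end))
        seg = slice(i_stim, i_end)
        if i_end - i_stim < 3:
            raise ValueError("stimulus window contains too few samples")
        peak_idx = i_stim + int(np.argmax(y[seg]))
        peak = float(y[peak_idx])
        if peak < capture_threshold_mV:
            out.append(APMetrics(np.nan, rp, peak, float(np.max(dvdt[seg])),
                                 np.nan, captured=False))
            continue
        up = slice(i_stim, peak_idx + 1)
        k_up = i_stim + int(np.argmax(dvdt[up]))
        takeoff = float(t[k_up])
        level = peak - repolarization_fraction * (peak - rp)
        below = np.nonzero(y[peak_idx:i_end] <= level)[0]
        if len(below) == 0:
            # repolarization incomplete within the record
            out.append(APMetrics(np.nan, rp, peak, float(dvdt[k_up]), takeoff, captured=True))
            continue
        j = peak_idx + below[0]
        # linear interpolation of the crossing for sub-sample precision
        if j > peak_idx and y[j - 1] != y[j]:
            frac = (y[j - 1] - level) / (y[j - 1] - y[j])
            t_cross = t[j - 1] + frac * dt
        else:
            t_cross = t[j]
        out.append(
            APMetrics(
                apd90=float(t_cross - takeoff),
                resting_potential=rp,
                peak_overshoot=peak,
                max_dvdt=float(dvdt[k_up]),
                takeoff_time=takeoff,
                captured=True,
            )
        )
    return out


def udb_peak_sequences(
    sweeps: SweepSet,
    protocol: VoltageProtocol,
    condition: str = "control",
):
    """Extract normalized per-pulse peak sequences from a use-dependent-block
    recording: one :class:`~cardioblock.block_kinetics.UDBMeasurement` per
    sweep, peaks normalized to the first pulse."""
    from cardioblock.block_kinetics import UDBMeasurement

    if protocol.variable_interpulse is None or protocol.pulse_duration is None:
        raise ValueError("protocol is not a use-dependent-block protocol")
    n_pulses = sum(1 for s in protocol.segments if s.role_tag == "activation")
    out = []
    for sw in range(sweeps.n_sweeps):
        peaks = []
        for p in range(n_pulses):
            win = protocol.segment_window(sw, "activation", occurrence=p)
            m = measure_peak(sweeps, win, polarity="inward", sweep_index=sw)[0]
            peaks.append(-m.peak_value)  # magnitude of inward peak
        t_r = protocol.variable_interpulse[sw]
        out.append(
            UDBMeasurement(
                t_d=protocol.pulse_duration,
                t_r=tuple([t_r] * (n_pulses - 1)),
                peak_sequence=tuple(np.array(peaks) / peaks[0]),
                condition=condition,
            )
        )
    return out
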