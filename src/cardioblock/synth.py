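"""Synthetic patch-clamp sweep generation from ground-truth channel models.

The centrepiece is a five-state Markov model of the cardiac Na+ channel with
conformation-specific drug block following the modulated receptor hypothesis
(MRH): closed (C), open (O) and inactivated (I) gating states plus drug-bound
open (OB) and inactivated (IB) states.  Activation C<->O lumps the cubed
m-gate into a single voltage-dependent transition; block is only allowed from
O (at k_ob*[D] / k_ob_inv) and from I (at k_ib*[D] / k_ib_inv) — closed
channels bind drug with negligible affinity and carry no block pathway.

Within a constant-voltage protocol segment the occupancy vector is propagated
with the exact matrix exponential of the transition-rate matrix, which keeps
occupancies non-negative and exactly normalized at every sample.  Ramps are
integrated by re-evaluating the exponential propagator on each sample step at
the local ramp voltage.

Simple Hodgkin–Huxley surrogates (activation^p × inactivation) are provided
for the non-Na currents (L-type Ca2+, slow/rapid delayed-rectifier K+) so the
full protocol library can be exercised by downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.linalg import expm

from cardioblock.protocols import VoltageProtocol
from cardioblock.traces import SweepSet

__all__ = [
    "NavMarkovParams",
    "NoiseSpec",
    "HHParams",
    "simulate_markov_trace",
    "simulate_hh_trace",
    "add_noise",
    "hh_presets",
]

# state indices of the MRH Markov scheme
C, O, I, OB, IB = 0, 1, 2, 3, 4
N_STATES = 5


@dataclass(frozen=True)
class NavMarkovParams:
    """Ground-truth parameters of the MRH Na+ channel block model.

    Rates are in ms^-1 except the blocking rates k_ob, k_ib (uM^-1 ms^-1).
    ``tau_i`` is the apparent macroscopic inactivation time constant at a
    depolarized potential, ``tau_r`` the recovery time constant at a
    hyperpolarized holding potential; defaults are the control estimates from
    use-dependent-block experiments on hNav1.5 (2.47 ms and 3.81 ms).
    """

    g_max: float = 100.0  # nS
    reversal: float = 65.0  # mV (Na+ under the recording solutions)
    v_half_act: float = -45.0  # mV, lumped m-gate midpoint
    k_act: float = 4.0  # mV, m-gate slope
    tau_act: float = 0.15  # ms, activation/deactivation time scale
    tau_i: float = 2.47  # ms
    tau_r: float = 3.81  # ms
    v_half_rec: float = -90.0  # mV, recovery pathway gate midpoint
    k_rec: float = 5.0  # mV
    k_ob: float = 0.0  # uM^-1 ms^-1
    k_ob_inv: float = 0.0  # ms^-1
    k_ib: float = 0.0  # uM^-1 ms^-1
    k_ib_inv: float = 0.0  # ms^-1
    drug_conc: float = 0.0  # uM
    blocked_interconversion: bool = False  # OB<->IB pathway (detailed balance)

    def __post_init__(self) -> None:
        for name in ("g_max", "k_ob", "k_ob_inv", "k_ib", "k_ib_inv", "drug_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_act", "tau_i", "tau_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def with_drug(self, conc_uM: float) -> "NavMarkovParams":
        return replace(self, drug_conc=float(conc_uM))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian recording noise; optional per-sweep linear drift."""

    sd: float = 0.0  # trace units
    seed: int = 0
    baseline_drift: float = 0.0  # units per ms, per sweep

    def __post_init__(self) -> None:
        if not np.isfinite(self.sd) or self.sd < 0:
            raise ValueError("noise sd must be finite and >= 0")


def _rate_matrix(params: NavMarkovParams, v: float) -> np.ndarray:
    """Transition-rate matrix Q (columns: from-state) at membrane voltage v."""
    m = 1.0 / (1.0 + np.exp(-(v - params.v_half_act) / params.k_act))
    po_inf = m ** 3
    k_co = po_inf / params.tau_act
    k_oc = (1.0 - po_inf) / params.tau_act
    k_oi = 1.0 / params.tau_i
    # recovery I->C gated to the hyperpolarized range
    h_rec = 1.0 / (1.0 + np.exp((v - params.v_half_rec) / params.k_rec))
    k_ic = h_rec / params.tau_r

    d = params.drug_conc
    k_o_ob = params.k_ob * d
    k_ob_o = params.k_ob_inv
    k_i_ib = params.k_ib * d
    k_ib_i = params.k_ib_inv

    Q = np.zeros((N_STATES, N_STATES))

    def add(frm, to, rate):
        Q[to, frm] += rate
        Q[frm, frm] -= rate

    add(C, O, k_co)
    add(O, C, k_oc)
    add(O, I, k_oi)
    add(I, C, k_ic)
    add(O, OB, k_o_ob)
    add(OB, O, k_ob_o)
    add(I, IB, k_i_ib)
    add(IB, I, k_ib_i)
    if params.blocked_interconversion and k_ob_o > 0 and k_i_ib > 0:
        # OB->IB mirrors O->I; IB->OB set by detailed balance around the
        # O-I-IB-OB cycle so the blocked loop carries no net flux at rest
        k_ob_ib = k_oi
        denom = k_oi * k_i_ib * k_ob_o
        k_ib_ob = denom / (k_o_ob * k_ib_i) if (k_o_ob * k_ib_i) > 0 else 0.0
        add(OB, IB, k_ob_ib)
        add(IB, OB, k_ib_ob)
    return Q


def simulate_markov_trace(
    params: NavMarkovParams,
    protocol: VoltageProtocol,
    dt: float = 0.005,
    seed: int = 0,
) -> SweepSet:
    """Integrate the MRH Markov model under a voltage protocol.

    Returns per-sweep current traces (pA) sampled at ``dt`` ms.  Sweeps of a
    variable-interpulse protocol are padded at the final holding level so all
    rows share one length.  The integration itself is deterministic; ``seed``
    is recorded in the sweep-set metadata for provenance.
    """
    if protocol.signal_kind != "voltage":
        raise ValueError("Markov trace synthesis requires a voltage-clamp protocol")
    min_dur = min(
        d for sw in range(protocol.n_sweeps) for _, _, d in protocol.resolve_sweep(sw)
    )
    if dt > 0.01 * min_dur:
        raise ValueError(
            f"dt={dt} ms too coarse for stiff kinetics: require "
            f"dt <= 0.01 x min segment duration ({0.01 * min_dur:.4g} ms)"
        )

    sweep_plans = [protocol.resolve_sweep(sw) for sw in range(protocol.n_sweeps)]
    durations = [sum(d for _, _, d in plan) for plan in sweep_plans]
    total = max(durations)
    n_samples = int(round(total / dt)) + 1

    propagator_cache: dict[float, np.ndarray] = {}

    def propagator(v: float) -> np.ndarray:
        key = round(v, 9)
        if key not in propagator_cache:
            propagator_cache[key] = expm(_rate_matrix(params, v) * dt)
        return propagator_cache[key]

    sweeps = np.empty((protocol.n_sweeps, n_samples))
    for sw, plan in enumerate(sweep_plans):
        # pad the tail at the last level so all sweeps share one grid
        pad = total - durations[sw]
        plan = list(plan)
        last_level = plan[-1][1]
        if pad > 1e-9:
            plan.append((last_level, last_level, pad))
        p = np.zeros(N_STATES)
        p[C] = 1.0
        out = sweeps[sw]
        idx = 0
        v0_first = plan[0][0]
        out[idx] = params.g_max * p[O] * (v0_first - params.reversal)
        for v_start, v_end, dur in plan:
            n_steps = int(round(dur / dt))
            if v_start == v_end:
                T = propagator(v_start)
                for _ in range(n_steps):
                    p = T @ p
                    idx += 1
                    out[idx] = params.g_max * p[O] * (v_start - params.reversal)
            else:
                for s in range(n_steps):
                    frac = (s + 0.5) / n_steps
                    v = v_start + (v_end - v_start) * frac
                    T = expm(_rate_matrix(params, v) * dt)
                    p = T @ p
                    idx += 1
                    v_here = v_start + (v_end - v_start) * (s + 1) / n_steps
                    out[idx] = params.g_max * p[O] * (v_here - params.reversal)
        # numerical guard: renormalize accumulated round-off
        out[idx + 1 :] = out[idx]

    return SweepSet(
        sample_interval=dt,
        sweeps=sweeps,
        signal_kind="current",
        units="pA",
        protocol_ref=protocol.name,
        meta={"seed": seed, "model": "nav_markov_mrh"},
    )


# ---------------------------------------------------------------------------
# Hodgkin–Huxley surrogates for non-Na currents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HHParams:
    """Generic g * a^p * h * (V - E) surrogate with first-order gates."""

    g_max: float  # nS
    reversal: float  # mV
    act_v_half: float
    act_k: float  # mV; positive = activates on depolarization
    act_tau: float  # ms
    act_power: int = 1
    inact_v_half: float | None = None
    inact_k: float = 5.0
    inact_tau: float = 100.0
    block_fraction: float = 0.0  # static pore-block scaling


def hh_presets() -> dict[str, HHParams]:
    """Surrogate parameter sets for L-type Ca2+, IKs-like and hERG-like currents."""
    return {
        "cav": HHParams(
            g_max=20.0, reversal=60.0, act_v_half=-20.0, act_k=6.0, act_tau=2.0,
            act_power=2, inact_v_half=-35.0, inact_k=6.0, inact_tau=60.0,
        ),
        "iks": HHParams(
            g_max=10.0, reversal=-85.0, act_v_half=10.0, act_k=12.0, act_tau=500.0,
            act_power=1,
        ),
        "herg": HHParams(
            g_max=15.0, reversal=-85.0, act_v_half=-15.0, act_k=8.0, act_tau=300.0,
            act_power=1, inact_v_half=-50.0, inact_k=10.0, inact_tau=10.0,
        ),
    }


def simulate_hh_trace(
    params: HHParams,
    protocol: VoltageProtocol,
    dt: float = 0.02,
    seed: int = 0,
) -> SweepSet:
    """Integrate an HH surrogate under a voltage protocol (exponential gate updates)."""
    if protocol.signal_kind != "voltage":
        raise ValueError("HH trace synthesis requires a voltage-clamp protocol")

    sweep_plans = [protocol.resolve_sweep(sw) for sw in range(protocol.n_sweeps)]
    durations = [sum(d for _, _, d in plan) for plan in sweep_plans]
    total = max(durations)
    n_samples = int(round(total / dt)) + 1
    scale = params.g_max * (1.0 - params.block_fraction)

    def gates_inf(v):
        a = 1.0 / (1.0 + np.exp(-(v - params.act_v_half) / params.act_k))
        if params.inact_v_half is None:
            return a, 1.0
        h = 1.0 / (1.0 + np.exp((v - params.inact_v_half) / params.inact_k))
        return a, h

    sweeps = np.empty((protocol.n_sweeps, n_samples))
    for sw, plan in enumerate(sweep_plans):
        pad = total - durations[sw]
        plan = list(plan)
        if pad > 1e-9:
            last_level = plan[-1][1]
            plan.append((last_level, last_level, pad))
        v0 = plan[0][0]
        a, h = gates_inf(v0)
        out = sweeps[sw]
        idx = 0
        out[idx] = scale * a**params.act_power * h * (v0 - params.reversal)
        ea = np.exp(-dt / params.act_tau)
        eh = np.exp(-dt / params.inact_tau)
        for v_start, v_end, dur in plan:
            n_steps = int(round(dur / dt))
            for s in range(n_steps):
                v = v_start + (v_end - v_start) * (s + 1) / n_steps
                a_inf, h_inf = gates_inf(v)
                a = a_inf + (a - a_inf) * ea
                h = h_inf + (h - h_inf) * eh
                idx += 1
                out[idx] = scale * a**params.act_power * h * (v - params.reversal)
        out[idx + 1 :] = out[idx]

    return SweepSet(
        sample_interval=dt,
        sweeps=sweeps,
        signal_kind="current",
        units="pA",
        protocol_ref=protocol.name,
        meta={"seed": seed, "model": "hh_surrogate"},
    )


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def add_noise(sweeps: SweepSet, noise: NoiseSpec) -> SweepSet:
    """Add Gaussian noise (and optional per-sweep linear drift) to a copy.

    Per-sweep random streams are derived from the master seed by fixed
    splitting, so changing the sweep count never reshuffles earlier sweeps.
    """
    out = sweeps.copy()
    if noise.sd == 0.0 and noise.baseline_drift == 0.0:
        return out
    t = out.time
    for sw in range(out.n_sweeps):
        rng = np.random.default_rng(np.random.SeedSequence(noise.seed, spawn_key=(sw,)))
        if noise.sd > 0:
            out.sweeps[sw] += rng.normal(0.0, noise.sd, size=out.n_samples)
        if noise.baseline_drift != 0.0:
            out.sweeps[sw] += noise.baseline_drift * t
    out.meta["noise_sd"] = noise.sd
    out.meta["noise_seed"] = noise.seed
    return out
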