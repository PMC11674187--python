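"""Voltage- and current-clamp protocol definitions and a named protocol library.

Protocols are ordered lists of step or ramp segments.  Segments may carry a
per-sweep voltage increment (activation / inactivation families) and a
protocol may declare per-sweep variable interpulse durations (use-dependent
block).  The same objects drive both synthetic trace generation and the
placement of analysis windows.
"""

from __future__ import annotations

import inspect
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

__all__ = [
    "ProtocolSegment",
    "VoltageProtocol",
    "build_protocol",
    "available_protocols",
    "ProtocolError",
]


class ProtocolError(ValueError):
    """Unknown protocol name or invalid override."""


@dataclass(frozen=True)
class ProtocolSegment:
    """One step or ramp of a clamp protocol.

    ``level`` is the command level in mV (voltage clamp) or pA (current
    clamp).  A ramp carries a distinct ``level_end``.  ``per_sweep_increment``
    shifts ``level`` by that many mV for each successive sweep.
    ``role_tag`` is free text used to locate analysis windows
    (``holding``/``seal-test``/``activation``/``recovery``/``stimulus``).
    """

    level: float
    duration: float  # ms
    level_end: float | None = None  # ramps only
    per_sweep_increment: float = 0.0
    role_tag: str = "holding"
    variable_duration: bool = False  # duration taken from per-sweep table

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError(f"segment duration must be > 0, got {self.duration}")
        import math

        if not math.isfinite(self.level):
            raise ValueError("segment level must be finite")
        if self.level_end is not None and not math.isfinite(self.level_end):
            raise ValueError("ramp end level must be finite")

    @property
    def is_ramp(self) -> bool:
        return self.level_end is not None

    def level_at(self, sweep: int, frac: float = 0.0) -> float:
        """Command level for a given sweep, at fractional position ``frac``."""
        v0 = self.level + self.per_sweep_increment * sweep
        if self.level_end is None:
            return v0
        return v0 + (self.level_end - self.level) * frac


@dataclass(frozen=True)
class VoltageProtocol:
    """A named multi-sweep clamp protocol.

    ``variable_interpulse`` lists, per sweep, the duration (ms) substituted
    into every segment flagged ``variable_duration`` — this encodes the
    use-dependent-block family where the recovery interval t_r grows from
    sweep to sweep while the depolarized dwell t_d stays fixed.
    """

    name: str
    segments: tuple[ProtocolSegment, ...]
    n_sweeps: int = 1
    inter_sweep_interval: float = 1.0  # s
    variable_interpulse: tuple[float, ...] | None = None  # ms, one per sweep
    pulse_duration: float | None = None  # t_d, ms (use-dependent family)
    signal_kind: str = "voltage"  # command signal: voltage | current

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.variable_interpulse is not None:
            if len(self.variable_interpulse) != self.n_sweeps:
                raise ValueError(
                    "variable_interpulse must have one entry per sweep "
                    f"({len(self.variable_interpulse)} != {self.n_sweeps})"
                )
            if any(t <= 0 for t in self.variable_interpulse):
                raise ValueError("interpulse intervals must be strictly positive")
        if self.pulse_duration is not None and self.pulse_duration <= 0:
            raise ValueError("pulse duration t_d must be strictly positive")
        if any(s.variable_duration for s in self.segments) and self.variable_interpulse is None:
            raise ValueError("variable-duration segments require variable_interpulse")

    # -- geometry ---------------------------------------------------------
    def resolve_sweep(self, sweep: int) -> list[tuple[float, float, float]]:
        """Piecewise command for one sweep: list of (v_start, v_end, duration ms)."""
        if not (0 <= sweep < self.n_sweeps):
            raise IndexError(f"sweep {sweep} out of range")
        out = []
        for seg in self.segments:
            dur = seg.duration
            if seg.variable_duration:
                dur = float(self.variable_interpulse[sweep])  # type: ignore[index]
            v0 = seg.level_at(sweep, 0.0)
            v1 = seg.level_at(sweep, 1.0)
            out.append((v0, v1, dur))
        return out

    def sweep_duration(self, sweep: int) -> float:
        return sum(d for _, _, d in self.resolve_sweep(sweep))

    def segment_window(self, sweep: int, role_tag: str, occurrence: int = 0) -> tuple[float, float]:
        """(start, end) ms of the n-th segment carrying ``role_tag`` in a sweep."""
        t = 0.0
        seen = 0
        for seg, (_, _, dur) in zip(self.segments, self.resolve_sweep(sweep)):
            if seg.role_tag == role_tag:
                if seen == occurrence:
                    return (t, t + dur)
                seen += 1
            t += dur
        raise ProtocolError(f"no segment with role {role_tag!r} (occurrence {occurrence})")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        d["segments"] = [asdict(s) for s in self.segments]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "VoltageProtocol":
        d = json.loads(text)
        segs = tuple(ProtocolSegment(**s) for s in d.pop("segments"))
        vi = d.pop("variable_interpulse", None)
        return cls(
            segments=segs,
            variable_interpulse=tuple(vi) if vi is not None else None,
            **d,
        )


# ---------------------------------------------------------------------------
# Protocol library
# ---------------------------------------------------------------------------

def _seg(level, duration, role, inc=0.0, end=None, variable=False):
    return ProtocolSegment(
        level=level,
        duration=duration,
        level_end=end,
        per_sweep_increment=inc,
        role_tag=role,
        variable_duration=variable,
    )


def _nav_standard(holding=-90.0, seal_level=-110.0, seal_ms=20.0,
                  step_level=-10.0, step_ms=40.0, pre_ms=20.0, post_ms=20.0,
                  n_sweeps=5):
    """Standard Na+ pharmacology protocol: holding −90 mV, 20 ms seal step at
    −110 mV, 40 ms activation step at −10 mV, sweeps repeated at 1 s."""
    return VoltageProtocol(
        name="nav_standard",
        segments=(
            _seg(holding, pre_ms, "holding"),
            _seg(seal_level, seal_ms, "seal-test"),
            _seg(step_level, step_ms, "activation"),
            _seg(holding, post_ms, "holding"),
        ),
        n_sweeps=n_sweeps,
        inter_sweep_interval=1.0,
    )


def _nav_activation(holding=-90.0, start=-80.0, stop=60.0, inc=5.0, step_ms=40.0,
                    seal_level=-110.0, seal_ms=20.0, pre_ms=20.0, post_ms=20.0):
    n = int(round((stop - start) / inc)) + 1
    return VoltageProtocol(
        name="nav_activation",
        segments=(
            _seg(holding, pre_ms, "holding"),
            _seg(seal_level, seal_ms, "seal-test"),
            _seg(start, step_ms, "activation", inc=inc),
            _seg(holding, post_ms, "holding"),
        ),
        n_sweeps=n,
        inter_sweep_interval=5.0,
    )


def _nav_inactivation(holding=-120.0, start=-120.0, stop=40.0, inc=10.0,
                      cond_ms=1000.0, test_level=-30.0, test_ms=25.0,
                      pre_ms=20.0, post_ms=20.0):
    n = int(round((stop - start) / inc)) + 1
    return VoltageProtocol(
        name="nav_inactivation",
        segments=(
            _seg(holding, pre_ms, "holding"),
            _seg(start, cond_ms, "conditioning", inc=inc),
            _seg(test_level, test_ms, "activation"),
            _seg(holding, post_ms, "holding"),
        ),
        n_sweeps=n,
        inter_sweep_interval=5.0,
    )


def _nav_udb(holding=-120.0, pulse_level=-10.0, t_d=10.0, n_pulses=5,
             t_r_start=5.0, t_r_stop=50.0, t_r_inc=5.0, pre_ms=20.0, post_ms=20.0):
    """Use-dependent block: 5 pulses of 10 ms at −10 mV, interpulse intervals
    at −120 mV growing from 5 to 50 ms in 5 ms increments across sweeps."""
    n_sweeps = int(round((t_r_stop - t_r_start) / t_r_inc)) + 1
    t_r = tuple(t_r_start + t_r_inc * i for i in range(n_sweeps))
    segs = [_seg(holding, pre_ms, "holding")]
    for p in range(n_pulses):
        segs.append(_seg(pulse_level, t_d, "activation"))
        if p < n_pulses - 1:
            segs.append(_seg(holding, 1.0, "recovery", variable=True))
    segs.append(_seg(holding, post_ms, "holding"))
    return VoltageProtocol(
        name="nav_udb",
        segments=tuple(segs),
        n_sweeps=n_sweeps,
        inter_sweep_interval=5.0,
        variable_interpulse=t_r,
        pulse_duration=t_d,
    )


def _cipa_late_ina(holding=-90.0, precond_level=-110.0, precond_ms=20.0,
                   step_level=-10.0, step_ms=500.0, post_ms=20.0, n_sweeps=3):
    """Late-I_Na assay (CiPA-like): long depolarizing step; the persistent
    component is read in a late window of the step."""
    return VoltageProtocol(
        name="cipa_late_ina",
        segments=(
            _seg(holding, 20.0, "holding"),
            _seg(precond_level, precond_ms, "seal-test"),
            _seg(step_level, step_ms, "activation"),
            _seg(holding, post_ms, "holding"),
        ),
        n_sweeps=n_sweeps,
        inter_sweep_interval=8.0,
    )


def _cav_pharm(holding=-80.0, step1_level=-50.0, step1_ms=100.0,
               step2_level=0.0, step2_ms=200.0, pre_ms=20.0, post_ms=20.0,
               n_sweeps=5):
    return VoltageProtocol(
        name="cav_pharm",
        segments=(
            _seg(holding, pre_ms, "holding"),
            _seg(step1_level, step1_ms, "seal-test"),
            _seg(step2_level, step2_ms, "activation"),
            _seg(holding, post_ms, "holding"),
        ),
        n_sweeps=n_sweeps,
        inter_sweep_interval=20.0,
    )


def _cav_actinact(holding=-80.0, start=-80.0, stop=50.0, inc=10.0,
                  cond_ms=1000.0, test_level=10.0, test_ms=250.0,
                  pre_ms=20.0, post_ms=20.0):
    n = int(round((stop - start) / inc)) + 1
    return VoltageProtocol(
        name="cav_actinact",
        segments=(
            _seg(holding, pre_ms, "holding"),
            _seg(start, cond_ms, "conditioning", inc=inc),
            _seg(test_level, test_ms, "activation"),
            _seg(holding, post_ms, "holding"),
        ),
        n_sweeps=n,
        inter_sweep_interval=20.0,
    )


def _kv71_two_step(holding=-110.0, n_sweeps=5):
    """Kv7.1+minK two-step: 250 ms at −80 mV with a brief −90 mV seal step at
    the middle, 3 s depolarization at +60 mV, 1 s tail at −50 mV."""
    return VoltageProtocol(
        name="kv71_two_step",
        segments=(
            _seg(holding, 20.0, "holding"),
            _seg(-80.0, 100.0, "reference"),
            _seg(-90.0, 50.0, "seal-test"),
            _seg(-80.0, 100.0, "reference"),
            _seg(60.0, 3000.0, "activation"),
            _seg(-50.0, 1000.0, "tail"),
            _seg(holding, 20.0, "holding"),
        ),
        n_sweeps=n_sweeps,
        inter_sweep_interval=20.0,
    )


def _herg_two_step(holding=-70.0, n_sweeps=5):
    """hERG two-step: 100 ms reference at −50 mV, 2 s at +40 mV, 2 s tail at
    −50 mV eliciting the peak by rapid recovery from inactivation."""
    return VoltageProtocol(
        name="herg_two_step",
        segments=(
            _seg(holding, 20.0, "holding"),
            _seg(-50.0, 100.0, "reference"),
            _seg(40.0, 2000.0, "activation"),
            _seg(-50.0, 2000.0, "tail"),
            _seg(holding, 20.0, "holding"),
        ),
        n_sweeps=n_sweeps,
        inter_sweep_interval=10.0,
    )


def _hipsc_pacing(amplitude_pA=2000.0, stim_ms=0.5, n_stimuli=3,
                  interval_ms=3000.0, first_ms=500.0):
    """Current-clamp external pacing: 2 nA, 0.5 ms stimuli at 3 s intervals,
    first stimulus 500 ms after start of recording."""
    segs = [_seg(0.0, first_ms, "holding")]
    for i in range(n_stimuli):
        segs.append(_seg(amplitude_pA, stim_ms, "stimulus"))
        if i < n_stimuli - 1:
            segs.append(_seg(0.0, interval_ms - stim_ms, "holding"))
    segs.append(_seg(0.0, 500.0, "holding"))
    return VoltageProtocol(
        name="hipsc_pacing",
        segments=tuple(segs),
        n_sweeps=1,
        inter_sweep_interval=10.0,
        signal_kind="current",
    )


def _double_ramp(holding=-80.0, low=-120.0, high=80.0, ramp_ms=2000.0, n_sweeps=3):
    return VoltageProtocol(
        name="double_ramp",
        segments=(
            _seg(holding, 100.0, "holding"),
            _seg(low, ramp_ms, "ramp-up", end=high),
            _seg(high, ramp_ms, "ramp-down", end=low),
            _seg(holding, 100.0, "holding"),
        ),
        n_sweeps=n_sweeps,
        inter_sweep_interval=10.0,
    )


def _hold_only(level=-90.0, duration=100.0):
    return VoltageProtocol(
        name="hold_only",
        segments=(_seg(level, duration, "holding"),),
        n_sweeps=1,
        inter_sweep_interval=1.0,
    )


_REGISTRY = {
    "nav_standard": _nav_standard,
    "nav_activation": _nav_activation,
    "nav_inactivation": _nav_inactivation,
    "nav_udb": _nav_udb,
    "cipa_late_ina": _cipa_late_ina,
    "cav_pharm": _cav_pharm,
    "cav_actinact": _cav_actinact,
    "kv71_two_step": _kv71_two_step,
    "herg_two_step": _herg_two_step,
    "hipsc_pacing": _hipsc_pacing,
    "double_ramp": _double_ramp,
    "hold_only": _hold_only,
}


def available_protocols() -> list[str]:
    return sorted(_REGISTRY)


def build_protocol(name: str, **overrides) -> VoltageProtocol:
    """Build a library protocol, optionally overriding declared parameters.

    Raises :class:`ProtocolError` for unknown names or overrides of
    parameters the protocol does not declare.
    """
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise ProtocolError(
            f"unknown protocol {name!r}; available: {', '.join(available_protocols())}"
        ) from None
    allowed = set(inspect.signature(builder).parameters)
    bad = set(overrides) - allowed
    if bad:
        raise ProtocolError(
            f"protocol {name!r} has no parameter(s) {sorted(bad)}; "
            f"declared: {sorted(allowed)}"
        )
    return builder(**overrides)
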