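"""Stimulation schedules and clamp directives.

Stimuli are square current pulses (default 40 pA/pF for 1 ms).  Clamps
come in three modes: hold a quantity constant, follow a scaled copy of a
reference trace, or ramp a current linearly from its value at onset.
Clamping ``Ca_sub`` always sets the JXN and SL compartments simultaneously
to the same value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _indices as ix

__all__ = [
    "StimulusProtocol", "ClampDirective", "build_stimulus",
    "clamp_levels_from_trace", "make_scaled_trace_clamp", "make_ramp_clamp",
]

_TARGET_CODES = {
    "Ca_sub": ix.CL_CASUB,
    "V_m": ix.CL_VM,
    "I_CaL": ix.CL_ICAL,
    "I_NCX": ix.CL_INCX,
}
_MODE_CODES = {
    "constant": ix.CM_CONST,
    "scaled_trace": ix.CM_TRACE,
    "linear_ramp": ix.CM_RAMP,
}


@dataclass(frozen=True)
class StimulusProtocol:
    """A pacing schedule: single pulse, S1S1 train, or S1S1+S2."""

    kind: str = "single"
    amplitude: float = 40.0   # pA/pF
    duration: float = 1.0     # ms
    s1_interval: float = 1000.0
    s2_interval: float = 2000.0
    n_s1: int = 1

    def __post_init__(self):
        if self.kind not in ("single", "S1S1", "S1S2"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.amplitude <= 0 or self.duration <= 0:
            raise ValueError("amplitude and duration must be positive")
        if self.kind in ("S1S1", "S1S2") and self.s1_interval <= self.duration:
            raise ValueError("S1 interval must exceed the pulse duration")
        if self.kind == "S1S2" and self.s2_interval <= self.duration:
            raise ValueError("S2 interval must exceed the pulse duration")

    def pulse_times(self) -> np.ndarray:
        if self.kind == "single":
            return np.array([0.0])
        if self.kind == "S1S1":
            return np.arange(self.n_s1) * self.s1_interval
        # S1S2: n_s1 beats at the S1 interval, then one beat an S2
        # interval after the last S1
        s1 = np.arange(self.n_s1) * self.s1_interval
        return np.append(s1, s1[-1] + self.s2_interval)

    def i_sti(self, t: float) -> float:
        for t0 in self.pulse_times():
            if t0 <= t < t0 + self.duration:
                return self.amplitude
        return 0.0

    def last_pulse_time(self) -> float:
        return float(self.pulse_times()[-1])

    def describe(self) -> dict:
        return {
            "kind": self.kind, "amplitude_pApF": self.amplitude,
            "duration_ms": self.duration, "s1_interval_ms": self.s1_interval,
            "s2_interval_ms": self.s2_interval, "n_s1": self.n_s1,
        }


def build_stimulus(kind: str = "single", amplitude: float = 40.0,
                   duration: float = 1.0, s1_interval: float = 1000.0,
                   s2_interval: float = 2000.0, n_s1: int = 1) -> StimulusProtocol:
    """Convenience constructor for a :class:`StimulusProtocol`."""
    return StimulusProtocol(kind=kind, amplitude=amplitude, duration=duration,
                            s1_interval=s1_interval, s2_interval=s2_interval,
                            n_s1=n_s1)


@dataclass(frozen=True)
class ClampDirective:
    """One clamped quantity over a time window.

    ``value=None`` on a constant current/voltage clamp means "hold at the
    value the quantity has at t_on".  ``reference``/``scale`` drive the
    scaled-trace mode; ``end_value`` the linear ramp (from the value at
    onset toward ``end_value`` at ``t_off``).
    """

    target: str
    mode: str = "constant"
    t_on: float = 0.0
    t_off: float = 1e12
    value: Optional[float] = None
    scale: float = 1.0
    end_value: Optional[float] = None
    reference: Optional[np.ndarray] = field(default=None, repr=False)
    reference_dt: float = 1.0

    def __post_init__(self):
        if self.target not in _TARGET_CODES:
            raise KeyError(f"unknown clamp target {self.target!r}")
        if self.mode not in _MODE_CODES:
            raise ValueError(f"unknown clamp mode {self.mode!r}")
        if self.t_on >= self.t_off:
            raise ValueError("clamp window must satisfy t_on < t_off")
        if self.mode == "scaled_trace":
            if self.reference is None:
                raise ValueError("scaled_trace mode needs a reference series")
            if self.scale < 0:
                raise ValueError("scale must be non-negative")

    def target_code(self) -> int:
        return _TARGET_CODES[self.target]

    def mode_code(self) -> int:
        return _MODE_CODES[self.mode]

    def value_at(self, t: float) -> float:
        """Instantaneous clamp value (Python-side mirror of the kernel)."""
        if self.mode == "constant":
            if self.value is None:
                raise ValueError("hold-at-onset value is resolved at run time")
            return self.value
        if self.mode == "scaled_trace":
            r = np.asarray(self.reference, dtype=float) * self.scale
            idx = min(t / self.reference_dt, len(r) - 1)
            i0 = int(idx)
            if i0 >= len(r) - 1:
                return float(r[-1])
            w = idx - i0
            return float(r[i0] * (1 - w) + r[i0 + 1] * w)
        if self.value is None:
            raise ValueError("ramp start value is resolved at run time")
        return float(self.value + (self.end_value - self.value)
                     * (t - self.t_on) / (self.t_off - self.t_on))

    def describe(self) -> dict:
        return {
            "target": self.target, "mode": self.mode,
            "t_on_ms": self.t_on,
            "t_off_ms": None if self.t_off >= 1e12 else self.t_off,
            "value": self.value, "scale": self.scale,
            "end_value": self.end_value,
            "has_reference": self.reference is not None,
        }


def clamp_levels_from_trace(trace, signal: str,
                            window: tuple[float, float]) -> tuple[float, float]:
    """Lowest and highest level of a signal over a window.

    These are the two constant clamp levels used by the dissection
    experiments (clamp at the bottom and the top of the oscillation range).
    """
    sl = trace.window_slice(window)
    x = trace.signal(signal)[sl]
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.min(x)), float(np.max(x))


def make_scaled_trace_clamp(trace, signal: str, scale: float,
                            window: tuple[float, float]) -> ClampDirective:
    """Clamp ``signal`` to ``scale`` times its course in a reference trace.

    The reference is the full stored series of the trace (sampled on its
    storage grid, indexed from t = 0), so the clamp follows the recorded
    time course point-wise inside the window.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    t0, t1 = window
    if t1 > trace.t[-1] + trace.dt:
        raise ValueError("reference trace does not cover the clamp window")
    return ClampDirective(target=signal, mode="scaled_trace",
                          t_on=t0, t_off=t1, scale=scale,
                          reference=trace.signal(signal).copy(),
                          reference_dt=trace.dt)


def make_ramp_clamp(target: str, takeoff_time: float, end_value: float,
                    window: tuple[float, float]) -> ClampDirective:
    """Replace a current by a linear ramp from its value at takeoff.

    Before ``takeoff_time`` the current is free; from takeoff to the end of
    the window it is interpolated linearly from its instantaneous value at
    takeoff toward ``end_value``.
    """
    t0, t1 = window
    if not (t0 <= takeoff_time < t1):
        raise ValueError("takeoff time must lie inside the window")
    return ClampDirective(target=target, mode="linear_ramp",
                          t_on=takeoff_time, t_off=t1,
                          value=None, end_value=end_value)
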