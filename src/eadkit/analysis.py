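"""Detectors for APs, afterdepolarizations, oscillations and phase relations.

All operations work on stored traces sampled at 1 ms (or finer).  An EAD is
registered where dV/dt crosses from negative to positive inside the
plateau/repolarization voltage band and the subsequent local maximum
exceeds the takeoff voltage by at least the amplitude threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "EADEvent", "OscillationReport", "PhaseRelation",
    "measure_apd", "detect_eads", "detect_oscillations", "phase_relation",
    "EAD_VBAND", "EAD_AMPLITUDE_THRESHOLD", "OSC_PROMINENCE_FRACTION",
    "REPOL_THRESHOLD",
]

#: takeoff voltage band for EADs (mV): excludes upstroke and rest
EAD_VBAND = (-70.0, 20.0)
#: minimum peak-above-takeoff amplitude for an EAD (mV)
EAD_AMPLITUDE_THRESHOLD = 1.0
#: oscillation prominence threshold, as a fraction of the signal range
OSC_PROMINENCE_FRACTION = 0.05
#: APD / repolarization-failure voltage threshold (mV)
REPOL_THRESHOLD = -75.0


@dataclass(frozen=True)
class EADEvent:
    """One afterdepolarization: takeoff (dV/dt sign change) to local max."""

    takeoff_time: float
    takeoff_voltage: float
    peak_time: float
    peak_voltage: float

    @property
    def amplitude(self) -> float:
        return self.peak_voltage - self.takeoff_voltage


@dataclass(frozen=True)
class OscillationReport:
    """Qualifying maxima/minima of one signal over a window."""

    n_cycles: int
    peak_times: tuple
    trough_times: tuple
    mean_amplitude: float

    @property
    def oscillating(self) -> bool:
        return self.n_cycles >= 2


@dataclass(frozen=True)
class PhaseRelation:
    """Pairing of V_m turning points with the nearest Ca turning points.

    ``mean_lag`` is signed in ms; positive means V_m turns before Ca
    (V_m leads).  Labels: in_phase if |lag| < 10% of the mean cycle
    period, out_of_phase if |lag| > 40%, otherwise vm_leads / ca_leads
    by the sign of the lag.
    """

    mean_lag: float
    period: float
    label: str
    n_pairs: int


class InsufficientOscillation(ValueError):
    """Fewer than two cycles available for phase analysis."""


def _upstroke_index(trace) -> int:
    v = trace.V_m
    dv = np.gradient(v, trace.t)
    cand = np.where((dv > 5.0) & (v > -40.0))[0]
    if len(cand) == 0:
        raise ValueError("no stimulus-evoked upstroke in trace")
    return int(cand[0])


def measure_apd(trace, repol_threshold: float = REPOL_THRESHOLD,
                pacing_interval: float | None = None) -> tuple[float, bool]:
    """AP duration and whether the AP repolarized.

    APD is measured from the upstroke to the first downward crossing of
    ``repol_threshold``.  ``repolarized`` is False when no crossing occurs
    before the end of the trace, or — for paced runs — when the APD
    exceeds the pacing interval.
    """
    i_up = _upstroke_index(trace)
    v = trace.V_m
    below = np.where(v[i_up:] < repol_threshold)[0]
    if len(below) == 0:
        return float(trace.t[-1] - trace.t[i_up]), False
    apd = float(trace.t[i_up + below[0]] - trace.t[i_up])
    repolarized = True
    if pacing_interval is not None and apd > pacing_interval:
        repolarized = False
    return apd, repolarized


def detect_eads(trace, window: tuple[float, float] | None = None,
                v_band: tuple[float, float] = EAD_VBAND,
                amplitude_threshold: float = EAD_AMPLITUDE_THRESHOLD) -> list[EADEvent]:
    """All EAD events in the window, ordered by takeoff time."""
    if trace.dt > 1.0 + 1e-9:
        raise ValueError("detect_eads needs sampling at 1 ms or finer")
    if window is None:
        sl = slice(0, len(trace.t))
    else:
        sl = trace.window_slice(window)
    t = trace.t[sl]
    v = trace.V_m[sl]
    if len(v) < 5:
        raise ValueError("window outside trace")
    # secondary depolarizations: local maxima of sufficient prominence and
    # width.  Candidates are found on a 10 ms block-averaged copy — an EAD
    # hump spans tens of ms whereas sampling noise decorrelates between
    # blocks — and the takeoff is the preceding minimum of the averaged
    # series, the point where dV/dt turns from negative to positive.
    bin_ms = 10.0
    nb = max(1, int(round(bin_ms / trace.dt)))
    nfit = (len(v) // nb) * nb
    vb = v[:nfit].reshape(-1, nb).mean(axis=1)
    tb = t[:nfit].reshape(-1, nb).mean(axis=1)
    peaks, _ = find_peaks(vb, prominence=amplitude_threshold, width=2)
    events = []
    prev = 0
    for j in peaks:
        i = prev + int(np.argmin(vb[prev:j])) if j > prev else prev
        take_v = float(vb[i])
        if (v_band[0] <= take_v <= v_band[1] and i < j
                and float(vb[j]) - take_v >= amplitude_threshold):
            events.append(EADEvent(
                takeoff_time=float(tb[i]), takeoff_voltage=take_v,
                peak_time=float(tb[j]), peak_voltage=float(vb[j])))
        prev = j
    return events


def _window_after_upstroke(trace):
    """Analysis window excluding the primary stimulus-evoked transient:
    starts at the first post-upstroke minimum of V_m."""
    i_up = _upstroke_index(trace)
    v = trace.V_m
    i_pk = i_up + int(np.argmax(v[i_up:i_up + int(50 / trace.dt) + 1]))
    return (float(trace.t[min(i_pk + int(5 / trace.dt), len(v) - 1)]),
            float(trace.t[-1]) + trace.dt)


def detect_oscillations(trace, signal: str = "Ca_sub",
                        window: tuple[float, float] | None = None,
                        prominence_fraction: float = OSC_PROMINENCE_FRACTION,
                        min_prominence: float | None = None) -> OscillationReport:
    """Count qualifying local maxima of a signal over a window.

    Prominence threshold is a fraction of the signal range in the window;
    ``min_prominence`` (absolute, signal units) guards against counting
    numerical ripple on an essentially flat signal.
    """
    x = trace.signal(signal)
    if window is None:
        try:
            window = _window_after_upstroke(trace)
        except ValueError:
            window = (float(trace.t[0]), float(trace.t[-1]) + trace.dt)
    sl = trace.window_slice(window)
    xs = x[sl]
    ts = trace.t[sl]
    rng = float(np.ptp(xs))
    if min_prominence is None:
        # flat-signal guard: 0.5 mV for voltages, 2% of mean for others
        min_prominence = 0.5 if signal == "V_m" else 0.02 * abs(float(np.mean(xs))) + 1e-12
    prom = max(prominence_fraction * rng, min_prominence)
    peaks, _ = find_peaks(xs, prominence=prom)
    troughs, _ = find_peaks(-xs, prominence=prom)
    if len(peaks) and len(troughs):
        amp = float(np.mean(xs[peaks])) - float(np.mean(xs[troughs]))
    else:
        amp = 0.0
    return OscillationReport(
        n_cycles=int(len(peaks)),
        peak_times=tuple(float(ts[i]) for i in peaks),
        trough_times=tuple(float(ts[i]) for i in troughs),
        mean_amplitude=amp,
    )


def phase_relation(trace, window: tuple[float, float] | None = None,
                   in_phase_fraction: float = 0.10,
                   out_of_phase_fraction: float = 0.40) -> PhaseRelation:
    """Lag between V_m and Ca_sub turning points over a window.

    Each rising turning point (trough) of V_m is paired with the nearest
    Ca trough; the mean signed difference (positive = V_m turns first) is
    compared with the mean cycle period to label the relation.
    """
    if window is None:
        # default to the EAD phase: from the first takeoff to trace end
        eads = detect_eads(trace)
        if eads:
            window = (eads[0].takeoff_time, float(trace.t[-1]) + trace.dt)
    rep_v = detect_oscillations(trace, "V_m", window)
    rep_c = detect_oscillations(trace, "Ca_sub", window)
    if rep_v.n_cycles < 2 or rep_c.n_cycles < 2:
        raise InsufficientOscillation(
            f"need >= 2 cycles in both signals (V_m: {rep_v.n_cycles}, "
            f"Ca: {rep_c.n_cycles})")
    vt = np.asarray(rep_v.trough_times)
    ct = np.asarray(rep_c.trough_times)
    if len(vt) == 0 or len(ct) == 0:
        raise InsufficientOscillation("no interior turning points")
    period = float(np.mean(np.diff(rep_v.peak_times)))
    lags = []
    for tv in vt:
        tc = ct[np.argmin(np.abs(ct - tv))]
        lags.append(tc - tv)
    lag = float(np.mean(lags))
    frac = abs(lag) / period if period > 0 else 0.0
    if frac < in_phase_fraction:
        label = "in_phase"
    elif frac > out_of_phase_fraction:
        label = "out_of_phase"
    else:
        label = "vm_leads" if lag > 0 else "ca_leads"
    return PhaseRelation(mean_lag=lag, period=period, label=label,
                         n_pairs=len(lags))
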