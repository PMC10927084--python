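"""Clamp-experiment orchestration and EAD mechanism classification.

The classifier formalizes the case-by-case clamp reasoning into one
decision tree, applied to a parameter point:

1. Run the baseline AP.  No EAD and repolarized -> ``none``; not
   repolarized by the horizon (or APD beyond the pacing interval under
   pacing) -> ``repol_failure``.
2. EADs present with a non-oscillatory [Ca]_sub -> ``typeIV``
   (Ca-transient driven; confirmed by the 0.5x scaled-trace Ca clamp
   abolishing the EAD).
3. Otherwise clamp [Ca]_sub at the lowest and highest level of its
   EAD-phase range: V_m oscillations persisting under either clamp ->
   ``typeI`` (voltage driven).
4. Otherwise clamp V_m at the lowest and highest plateau level: Ca
   oscillations persisting -> ``typeII`` (Ca driven; confirmed by the
   constant I_NCX clamp silencing V_m while Ca still oscillates, and the
   constant I_CaL clamp preserving both).
5. Otherwise -> ``typeIII`` (coupling driven: neither subsystem
   oscillates alone).

"Oscillations persist" means at least two qualifying cycles in the
clamped run inside the clamp window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (ModelParameters, Trace, integrate, SimulationDiverged,
                    variant_initial_state)
from .protocols import (StimulusProtocol, ClampDirective, build_stimulus,
                        clamp_levels_from_trace, make_scaled_trace_clamp)
from . import analysis
from .analysis import (detect_eads, detect_oscillations, measure_apd,
                       phase_relation, InsufficientOscillation,
                       EADEvent, PhaseRelation)

__all__ = ["ClampExperimentResult", "EADClassification", "run_dissection"]

LABELS = ("none", "repol_failure", "typeI", "typeII", "typeIII", "typeIV")


@dataclass(frozen=True)
class ClampExperimentResult:
    """Outcome of one clamped simulation."""

    directive: ClampDirective
    vm_oscillates: bool
    ca_oscillates: bool
    vm_cycles: int
    ca_cycles: int
    notes: str = ""


@dataclass
class EADClassification:
    """Mechanism label with the clamp-experiment evidence behind it."""

    label: str
    baseline_eads: list = field(default_factory=list)
    baseline_apd: float = float("nan")
    repolarized: bool = True
    ca_cycles_baseline: int = 0
    phase: PhaseRelation | None = None
    evidence: list = field(default_factory=list)
    notes: str = ""
    alpha: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "alpha": dict(self.alpha),
            "baseline_apd_ms": self.baseline_apd,
            "repolarized": self.repolarized,
            "n_eads": len(self.baseline_eads),
            "eads": [
                {"takeoff_ms": e.takeoff_time, "takeoff_mV": e.takeoff_voltage,
                 "peak_ms": e.peak_time, "amplitude_mV": e.amplitude}
                for e in self.baseline_eads
            ],
            "ca_cycles_baseline": self.ca_cycles_baseline,
            "phase": None if self.phase is None else {
                "label": self.phase.label, "mean_lag_ms": self.phase.mean_lag,
                "period_ms": self.phase.period},
            "evidence": [
                {"target": r.directive.target, "mode": r.directive.mode,
                 "value": r.directive.value, "scale": r.directive.scale,
                 "vm_oscillates": r.vm_oscillates,
                 "ca_oscillates": r.ca_oscillates,
                 "vm_cycles": r.vm_cycles, "ca_cycles": r.ca_cycles,
                 "notes": r.notes}
                for r in self.evidence
            ],
            "notes": self.notes,
        }


def _clamped_oscillations(params, protocol, directive, window, t_end, dt, y0):
    """Run one clamped simulation and report oscillation flags."""
    try:
        tr = integrate(params, protocol, clamps=[directive], t_end=t_end,
                       dt=dt, y0=y0, stop_when_repolarized=False)
    except SimulationDiverged as e:
        return ClampExperimentResult(directive, False, False, 0, 0,
                                     notes=f"diverged at {e.t_fail:.0f} ms"), None
    w = (window[0], min(window[1], float(tr.t[-1]) + tr.dt))
    rep_v = detect_oscillations(tr, "V_m", w)
    rep_c = detect_oscillations(tr, "Ca_sub", w)
    return ClampExperimentResult(
        directive,
        vm_oscillates=rep_v.n_cycles >= 2,
        ca_oscillates=rep_c.n_cycles >= 2,
        vm_cycles=rep_v.n_cycles,
        ca_cycles=rep_c.n_cycles), tr


def run_dissection(params: ModelParameters,
                   protocol: StimulusProtocol | None = None,
                   t_end: float = 10000.0,
                   dt: float = 0.01,
                   y0: np.ndarray | None = None,
                   with_confirmatory: bool = True) -> EADClassification:
    """Classify the EAD mechanism at one parameter point.

    ``protocol`` defaults to the single-stimulus protocol.  Under S1S1 /
    S1S2 pacing, the classification is applied to the final beat and the
    repolarization-failure criterion becomes APD > pacing interval.
    """
    if protocol is None:
        protocol = build_stimulus("single")
    if y0 is None:
        y0 = variant_initial_state(
            ModelParameters(fss_flattened=params.fss_flattened))
    result = EADClassification(label="none", alpha=dict(params.alpha))
    try:
        base = integrate(params, protocol, t_end=t_end, dt=dt, y0=y0,
                         stop_when_repolarized=True)
    except SimulationDiverged as e:
        raise

    t_beat = protocol.last_pulse_time()
    pacing = protocol.s1_interval if protocol.kind == "S1S1" else None
    beat = _subtrace(base, t_beat)
    apd, repolarized = measure_apd(beat, pacing_interval=pacing)
    result.baseline_apd = apd
    result.repolarized = repolarized

    try:
        ead_window = analysis._window_after_upstroke(beat)
    except ValueError:
        result.label = "none"
        result.notes = "no upstroke in final beat"
        return result
    eads = detect_eads(beat, ead_window)
    result.baseline_eads = eads

    if not repolarized:
        result.label = "repol_failure"
        return result
    if not eads:
        result.label = "none"
        return result

    # EAD-phase window: first takeoff to end of repolarization (plus margin)
    t_on = eads[0].takeoff_time
    t_repol = beat.t[_first_below(beat, analysis.REPOL_THRESHOLD)]
    w = (t_on, float(t_repol))
    w_levels = w
    rep_ca = detect_oscillations(beat, "Ca_sub", w)
    result.ca_cycles_baseline = rep_ca.n_cycles
    try:
        result.phase = phase_relation(beat, w)
    except InsufficientOscillation:
        result.phase = None

    # absolute windows in simulation time for the clamp runs
    off = t_beat
    w_abs = (w[0] + off, w[1] + off)
    t_end_clamp = min(t_end, w_abs[1] + 2000.0)
    w_clamp = (w_abs[0], t_end_clamp)

    if rep_ca.n_cycles == 0:
        result.label = "typeIV"
        if with_confirmatory:
            # the confirmatory clamp follows 0.5x the recorded Ca course
            # over the whole beat, not just the EAD phase
            ref = Trace(t=base.t, states=base.states, currents=base.currents)
            t_half = min(t_end_clamp, float(base.t[-1]))
            half = make_scaled_trace_clamp(ref, "Ca_sub", 0.5,
                                           (t_beat, t_half))
            res, tr = _clamped_oscillations(params, protocol, half,
                                            (w_abs[0], t_half), t_half, dt, y0)
            if tr is not None:
                sub = _subtrace(tr, t_beat)
                try:
                    n_left = len(detect_eads(sub, analysis._window_after_upstroke(sub)))
                except ValueError:
                    n_left = 0
                res = ClampExperimentResult(
                    half, res.vm_oscillates, res.ca_oscillates,
                    res.vm_cycles, res.ca_cycles,
                    notes=f"EADs under 0.5x Ca trace clamp: {n_left}")
            result.evidence.append(res)
        return result

    # --- Ca_sub clamp at lowest / highest level of its EAD-phase range ---
    lo, hi = clamp_levels_from_trace(beat, "Ca_sub", w_levels)
    vm_persists = False
    for level in (lo, hi):
        d = ClampDirective(target="Ca_sub", mode="constant",
                           t_on=w_abs[0], t_off=t_end_clamp, value=level)
        res, _ = _clamped_oscillations(params, protocol, d, w_clamp,
                                       t_end_clamp, dt, y0)
        result.evidence.append(res)
        vm_persists = vm_persists or res.vm_oscillates
    if vm_persists:
        result.label = "typeI"
        return result

    # --- V_m clamp at lowest / highest plateau level ---
    vlo, vhi = clamp_levels_from_trace(beat, "V_m", w_levels)
    ca_persists = False
    for level in (vlo, vhi):
        d = ClampDirective(target="V_m", mode="constant",
                           t_on=w_abs[0], t_off=t_end_clamp, value=level)
        res, _ = _clamped_oscillations(params, protocol, d, w_clamp,
                                       t_end_clamp, dt, y0)
        result.evidence.append(res)
        ca_persists = ca_persists or res.ca_oscillates
    if ca_persists:
        result.label = "typeII"
        if with_confirmatory:
            # longer horizon: the Ca-cycling rhythm can be slow and two
            # full cycles must fit inside the clamp window
            t_end_conf = min(t_end, w_abs[1] + 6000.0)
            for target in ("I_NCX", "I_CaL"):
                d = ClampDirective(target=target, mode="constant",
                                   t_on=w_abs[0], t_off=t_end_conf, value=None)
                res, _ = _clamped_oscillations(params, protocol, d,
                                               (w_abs[0], t_end_conf),
                                               t_end_conf, dt, y0)
                result.evidence.append(res)
        return result

    # neither subsystem oscillates alone: coupling-driven if the baseline
    # Ca truly cycles (>= 2 cycles, same convention as "persists"); with a
    # single Ca hump the event is transient-driven, not an oscillation
    result.label = "typeIII" if rep_ca.n_cycles >= 2 else "typeIV"
    uncertain = any("diverged" in r.notes for r in result.evidence)
    if uncertain:
        result.notes = "uncertain: a clamp run diverged"
    return result


def _subtrace(trace: Trace, t_start: float) -> Trace:
    """View of a trace from t_start on, re-timed to start at 0."""
    if t_start <= 0:
        return trace
    i0 = int(np.searchsorted(trace.t, t_start, side="left"))
    return Trace(t=trace.t[i0:] - trace.t[i0], states=trace.states[i0:],
                 currents=trace.currents[i0:], meta=dict(trace.meta))


def _first_below(trace: Trace, threshold: float) -> int:
    v = trace.V_m
    i_up = analysis._upstroke_index(trace)
    below = np.where(v[i_up:] < threshold)[0]
    if len(below) == 0:
        return len(v) - 1
    return i_up + int(below[0])
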