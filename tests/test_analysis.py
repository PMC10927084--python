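"""Detectors: APD, EADs, oscillations, phase relations."""

import numpy as np
import pytest

from eadkit.model import Trace
from eadkit import _indices as ix
from eadkit.analysis import (measure_apd, detect_eads, detect_oscillations,
                             phase_relation, InsufficientOscillation)
from eadkit.synthetic import SyntheticTraceSpec, generate_trace


def _trace_from_series(t, v, ca=None):
    states = np.zeros((len(t), ix.NSTATE))
    states[:, ix.IV] = v
    if ca is not None:
        states[:, ix.ICASL] = ca
        states[:, ix.ICAJ] = ca
    return Trace(t=np.asarray(t, dtype=float), states=states,
                 currents=np.zeros((len(t), ix.NCUR)))


class TestAPD:
    def test_rectangular_pulse_width(self):
        t = np.arange(0.0, 1000.0)
        v = np.full_like(t, -85.0)
        v[10:310] = 10.0          # 300 ms above threshold
        tr = _trace_from_series(t, v)
        apd, repolarized = measure_apd(tr)
        assert repolarized
        assert apd == pytest.approx(300.0, abs=2.0)

    def test_no_crossing_is_failure(self):
        t = np.arange(0.0, 1000.0)
        v = np.full_like(t, -85.0)
        v[10:] = 0.0
        apd, repolarized = measure_apd(_trace_from_series(t, v))
        assert not repolarized

    def test_paced_failure_criterion(self):
        t = np.arange(0.0, 3000.0)
        v = np.full_like(t, -85.0)
        v[10:1500] = 10.0
        _, rep_free = measure_apd(_trace_from_series(t, v))
        _, rep_paced = measure_apd(_trace_from_series(t, v),
                                   pacing_interval=1000.0)
        assert rep_free and not rep_paced

    def test_no_upstroke_signalled(self):
        t = np.arange(0.0, 100.0)
        v = np.full_like(t, -85.0)
        with pytest.raises(ValueError):
            measure_apd(_trace_from_series(t, v))


class TestDetectEads:
    def test_monotonic_repolarization_is_clean(self):
        tr = generate_trace(SyntheticTraceSpec(n_humps=0))
        assert detect_eads(tr) == []

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_count_matches_constructed_humps(self, k):
        tr = generate_trace(SyntheticTraceSpec(n_humps=k, hump_amplitude=12.0))
        events = detect_eads(tr)
        assert len(events) == k
        # takeoffs at the constructed inter-hump minima (one period apart)
        expected = tr.meta["takeoff_times"]
        for e, t0 in zip(events, expected):
            assert abs(e.takeoff_time - t0) < 40.0
        for e in events:
            assert e.takeoff_time < e.peak_time
            assert e.amplitude > 0

    @pytest.mark.parametrize("seed", range(8))
    def test_sharpness_recall_and_specificity(self, seed):
        # amplitudes at least twice the threshold and noise at most a tenth
        # of the amplitude: perfect recall and zero false positives
        tr = generate_trace(SyntheticTraceSpec(
            n_humps=3, hump_amplitude=10.0, noise_sd=1.0, seed=seed))
        assert len(detect_eads(tr)) == 3
        # amplitudes at half the threshold: nothing detected
        tr0 = generate_trace(SyntheticTraceSpec(
            n_humps=3, hump_amplitude=0.5, noise_sd=0.0, seed=seed))
        assert detect_eads(tr0) == []

    def test_invariance_to_time_shift_and_offset(self):
        tr = generate_trace(SyntheticTraceSpec(n_humps=2, hump_amplitude=10.0))
        e0 = detect_eads(tr)
        shifted = Trace(t=tr.t + 500.0, states=tr.states + 0.0,
                        currents=tr.currents)
        shifted.states = shifted.states.copy()
        shifted.states[:, ix.IV] += 7.0
        e1 = detect_eads(shifted)
        assert len(e0) == len(e1)
        for a, b in zip(e0, e1):
            assert b.takeoff_time - a.takeoff_time == pytest.approx(500.0)
            assert b.amplitude == pytest.approx(a.amplitude)

    def test_window_outside_trace_rejected(self):
        tr = generate_trace(SyntheticTraceSpec())
        with pytest.raises(ValueError):
            detect_eads(tr, (5000.0, 6000.0))


class TestOscillations:
    def test_constant_signal_has_no_cycles(self):
        t = np.arange(0.0, 2000.0)
        tr = _trace_from_series(t, np.full_like(t, -20.0),
                                np.full_like(t, 1e-3))
        rep = detect_oscillations(tr, "Ca_sub", (0.0, 2000.0))
        assert rep.n_cycles == 0

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_sinusoid_counts_full_periods(self, n):
        t = np.arange(0.0, n * 250.0 + 200.0)
        ca = 1e-3 + 5e-4 * np.sin(2 * np.pi * np.arange(len(t)) / 250.0)
        ca[int(n * 250.0):] = 1e-3   # flat tail
        tr = _trace_from_series(t, np.full_like(t, -20.0), ca)
        rep = detect_oscillations(tr, "Ca_sub", (0.0, float(t[-1])))
        assert rep.n_cycles == n

    def test_peaks_and_troughs_interleave(self):
        t = np.arange(0.0, 1200.0)
        ca = 1e-3 + 5e-4 * np.sin(2 * np.pi * t / 200.0)
        tr = _trace_from_series(t, np.full_like(t, -20.0), ca)
        rep = detect_oscillations(tr, "Ca_sub", (0.0, 1200.0))
        merged = sorted([(x, "p") for x in rep.peak_times]
                        + [(x, "t") for x in rep.trough_times])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_unknown_signal_rejected(self):
        tr = generate_trace(SyntheticTraceSpec())
        with pytest.raises(KeyError):
            detect_oscillations(tr, "I_bogus")


class TestPhaseRelation:
    def test_identical_signals_in_phase(self):
        tr = generate_trace(SyntheticTraceSpec(n_humps=4, hump_amplitude=10.0,
                                               phase_lag=0.0))
        pr = phase_relation(tr)
        assert pr.label == "in_phase"
        assert abs(pr.mean_lag) < 0.1 * pr.period

    def test_half_period_shift_out_of_phase(self):
        tr = generate_trace(SyntheticTraceSpec(n_humps=4, hump_amplitude=10.0,
                                               phase_lag=100.0))
        assert phase_relation(tr).label == "out_of_phase"

    def test_known_shift_recovered(self):
        tr = generate_trace(SyntheticTraceSpec(n_humps=4, hump_amplitude=10.0,
                                               phase_lag=30.0))
        pr = phase_relation(tr)
        assert pr.label == "vm_leads"
        assert pr.mean_lag == pytest.approx(30.0, abs=10.0)

    def test_insufficient_cycles_signalled(self):
        tr = generate_trace(SyntheticTraceSpec(n_humps=0))
        with pytest.raises(InsufficientOscillation):
            phase_relation(tr, (100.0, 2000.0))
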