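"""Synthetic V_m/[Ca]_sub trace pairs with controlled EAD morphology.

The generator builds a piecewise action-potential template and inserts a
damped-sinusoid oscillation train into the repolarization phase, with a
phase-shifted Ca copy (or a single prolonged Ca transient for the
Ca-transient-driven morphology).  It exists so the detectors and the
classifier logic can be tested against traces whose ground truth is known
by construction; it is not a surrogate for the biophysical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Trace
from . import _indices as ix

__all__ = ["SyntheticTraceSpec", "generate_trace"]


@dataclass(frozen=True)
class SyntheticTraceSpec:
    resting_vm: float = -85.0     # mV
    plateau_vm: float = 0.0       # mV
    apd_base: float = 300.0       # ms, plateau duration before the EAD train
    n_humps: int = 0              # oscillation count
    hump_amplitude: float = 10.0  # mV
    ca_amplitude: float = 5e-4    # mM
    period: float = 200.0         # ms
    phase_lag: float = 0.0        # ms, Ca relative to V_m (positive: Ca later)
    ca_oscillates: bool = True    # False -> single prolonged Ca transient
    ca_base: float = 1e-4         # mM diastolic Ca
    noise_sd: float = 0.0         # mV (Ca noise scaled by ca_amp/hump_amp)
    dt: float = 1.0               # ms sampling
    t_end: float = 3000.0         # ms
    seed: int = 0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.n_humps < 0:
            raise ValueError("n_humps must be >= 0")


def _ap_template(t, spec):
    """Stylized AP: upstroke at 10 ms, plateau with slow decay, then
    exponential repolarization after the EAD train window."""
    v = np.full_like(t, spec.resting_vm)
    t_up = 10.0
    train = spec.n_humps * spec.period
    t_repol = t_up + spec.apd_base + train
    rise = (t >= t_up) & (t < t_up + 2.0)
    v[rise] = spec.resting_vm + (spec.plateau_vm + 40.0 - spec.resting_vm) \
        * (t[rise] - t_up) / 2.0
    on_plateau = (t >= t_up + 2.0) & (t < t_repol)
    tp = t[on_plateau] - t_up
    v[on_plateau] = spec.plateau_vm + 40.0 * np.exp(-tp / 80.0)
    after = t >= t_repol
    v[after] = spec.resting_vm + (spec.plateau_vm - spec.resting_vm) \
        * np.exp(-(t[after] - t_repol) / 15.0)
    return v, t_up, t_repol


def generate_trace(spec: SyntheticTraceSpec) -> Trace:
    """Build the synthetic trace pair as one Trace (V_m + Ca_sub columns).

    The EAD train is a damped sinusoid (decay constant two periods)
    starting at the end of the base plateau; takeoffs sit at the local
    minima preceding each hump.  The Ca series is a phase-shifted scaled
    copy riding on a stylized Ca transient, or a single prolonged
    transient when ``ca_oscillates`` is false.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.t_end + spec.dt / 2, spec.dt)
    v, t_up, t_repol = _ap_template(t, spec)

    train_start = t_up + spec.apd_base
    if spec.n_humps > 0:
        # each hump rises from and returns to the template (continuous at
        # the train boundaries); takeoffs sit at the inter-hump minima
        phase = 2 * np.pi * (t - train_start) / spec.period
        env = np.exp(-(t - train_start) / (2 * spec.period))
        osc = 0.5 * spec.hump_amplitude * (1.0 - np.cos(phase)) * env
        in_train = (t >= train_start) & (t < train_start + spec.n_humps * spec.period)
        v = v.copy()
        v[in_train] += osc[in_train]
    ca = np.full_like(t, spec.ca_base)
    decay = 400.0 if spec.ca_oscillates else (spec.apd_base + spec.n_humps
                                              * spec.period + 200.0)
    after_up = t >= t_up
    ca[after_up] += 3 * spec.ca_amplitude * np.exp(-(t[after_up] - t_up) / decay) \
        * (1 - np.exp(-(t[after_up] - t_up) / 20.0))
    if spec.n_humps > 0 and spec.ca_oscillates:
        phase_ca = 2 * np.pi * (t - train_start - spec.phase_lag) / spec.period
        env = np.exp(-(t - train_start) / (2 * spec.period))
        osc_ca = 0.5 * spec.ca_amplitude * (1.0 - np.cos(phase_ca)) * env
        in_train_ca = ((t >= train_start + spec.phase_lag)
                       & (t < train_start + spec.n_humps * spec.period
                          + spec.phase_lag))
        ca[in_train_ca] += osc_ca[in_train_ca]
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
        ca_sd = spec.noise_sd * (spec.ca_amplitude
                                 / max(spec.hump_amplitude, 1e-9))
        ca = ca + rng.normal(0.0, ca_sd, size=ca.shape)
    ca = np.maximum(ca, 0.0)

    states = np.zeros((len(t), ix.NSTATE))
    states[:, ix.IV] = v
    states[:, ix.ICASL] = ca
    states[:, ix.ICAJ] = ca
    currents = np.zeros((len(t), ix.NCUR))
    hump_amps = [float(spec.hump_amplitude * np.exp(-(k + 0.5) / 2.0))
                 for k in range(spec.n_humps)]
    meta = {
        "synthetic": True,
        "spec": {k: getattr(spec, k) for k in spec.__dataclass_fields__},
        "hump_amplitudes": hump_amps,
        "takeoff_times": [float(train_start + k * spec.period)
                          for k in range(spec.n_humps)],
    }
    return Trace(t=t, states=states, currents=currents, meta=meta)
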