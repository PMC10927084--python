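"""Simulate the control action potential and report its basic features.

The control cell is stimulated once (1 ms, 40 pA/pF) from its rested
state.  Expected output: a normal AP that repolarizes in roughly 200 ms
with no afterdepolarizations, with a junctional Ca transient that relaxes
back to the diastolic level.
"""
from eadkit import control_parameters, build_stimulus, integrate
from eadkit.model import default_initial_state
from eadkit.analysis import measure_apd, detect_eads, _window_after_upstroke

trace = integrate(control_parameters(), build_stimulus("single"),
                  t_end=10000.0, dt=0.01, y0=default_initial_state(),
                  stop_when_repolarized=True)
apd, repolarized = measure_apd(trace)
eads = detect_eads(trace, _window_after_upstroke(trace))

print(f"peak V_m            : {trace.V_m.max():7.1f} mV")
print(f"APD (-75 mV)        : {apd:7.0f} ms   repolarized: {repolarized}")
print(f"afterdepolarizations: {len(eads):7d}")
print(f"peak [Ca]_sub       : {1e3 * trace.Ca_sub.max():7.3f} uM")
print(f"peak junctional Ca  : {1e3 * trace.state('Ca_jxn').max():7.3f} uM")
# APD ~200 ms with zero EADs is the healthy-baseline reference against
# which every scaled parameter set is compared.
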