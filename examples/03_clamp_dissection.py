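"""Reproduce one clamp experiment by hand: Ca clamp at a voltage-driven point.

At a point whose EADs are voltage-driven, holding submembrane Ca constant
at either extreme of its oscillation range must NOT silence the V_m
oscillations - the voltage subsystem oscillates on its own.
"""
from eadkit import (control_parameters, apply_scaling, build_stimulus,
                    integrate, ClampDirective, clamp_levels_from_trace)
from eadkit.model import default_initial_state
from eadkit.analysis import detect_eads, detect_oscillations, _window_after_upstroke

alpha = dict(k_max=2, J_Caslmyo=2.64, I_NCX_bar=1, G_Ks=1.16, P_Ca=5.4)
params = apply_scaling(control_parameters(), alpha)
rest = default_initial_state()

baseline = integrate(params, build_stimulus(), t_end=10000.0, dt=0.01,
                     y0=rest, stop_when_repolarized=True)
eads = detect_eads(baseline, _window_after_upstroke(baseline))
t_on = eads[0].takeoff_time
print(f"baseline: {len(eads)} EADs, first takeoff at {t_on:.0f} ms")

# the clamp range spans the EAD phase: takeoff to repolarization
import numpy as np
i_rep = int(np.argmax(baseline.V_m[int(t_on):] < -75.0)) + int(t_on)
t_rep = float(baseline.t[i_rep])
lo, hi = clamp_levels_from_trace(baseline, "Ca_sub", (t_on, t_rep))
for level, tag in ((lo, "lowest"), (hi, "highest")):
    clamp = ClampDirective(target="Ca_sub", mode="constant",
                           t_on=t_on, t_off=t_on + 3000.0, value=level)
    tr = integrate(params, build_stimulus(), clamps=[clamp],
                   t_end=t_on + 3000.0, dt=0.01, y0=rest)
    rep = detect_oscillations(tr, "V_m", (t_on, t_on + 3000.0))
    print(f"Ca clamped at {tag} level ({1e3*level:.2f} uM): "
          f"{rep.n_cycles} V_m cycles -> "
          f"{'oscillation persists' if rep.n_cycles >= 2 else 'silent'}")
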