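"""The flattened-f_ss model variant and steady-state characterizations.

The late elevated portion of the I_CaL steady-state inactivation curve is
what allows sustained Ca entry at plateau voltages.  ``flatten_fss``
formalizes its removal: the curve is held constant at its minimum for all
voltages above the argmin.  The characterization protocols probe the two
relationships the mechanism analysis rests on: peak I_CaL versus clamped
submembrane Ca (Ca-dependent inactivation), and steady-state submembrane
Ca versus holding voltage (the non-monotonic window relationship).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (ModelParameters, control_parameters, apply_scaling,
                    integrate, fss_table)
from .protocols import ClampDirective
from .model import variant_initial_state
from .analysis import detect_oscillations

__all__ = ["GatingCurveSpec", "flatten_fss", "peak_ical_vs_casub",
           "casub_vs_holding_vm"]


@dataclass(frozen=True)
class GatingCurveSpec:
    """A tabulated steady-state inactivation curve f_ss(V)."""

    voltages: np.ndarray
    values: np.ndarray
    variant: str = "original"   # "original" | "flattened"

    def __post_init__(self):
        v = np.asarray(self.voltages, dtype=float)
        f = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.shape != f.shape:
            raise ValueError("voltages and values must be 1-D and matching")
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltage grid must be strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("gating values must lie in [0, 1]")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "values", f)

    @classmethod
    def from_model(cls, params: ModelParameters | None = None,
                   flattened: bool = False,
                   v_grid: np.ndarray | None = None) -> "GatingCurveSpec":
        v, f = fss_table(v_grid, flattened=flattened, params=params)
        return cls(v, f, "flattened" if flattened else "original")


def flatten_fss(curve: GatingCurveSpec) -> GatingCurveSpec:
    """Hold the curve at its minimum beyond the argmin.

    The output equals the input up to the voltage of the minimum and is
    constant at that minimum for all higher voltages, hence non-increasing
    whenever the input is non-increasing up to its argmin.  Idempotent.
    """
    f = curve.values.copy()
    i_min = int(np.argmin(f))
    f[i_min:] = f[i_min]
    return GatingCurveSpec(curve.voltages.copy(), f, "flattened")


def peak_ical_vs_casub(holding_vms, casub_levels,
                       base: ModelParameters | None = None,
                       hold_ms: float = 2000.0,
                       step_ms: float = 500.0,
                       dt: float = 0.01) -> pd.DataFrame:
    """Peak |I_CaL| after a voltage step, versus clamped [Ca]_sub.

    For each pair the membrane is clamped at -80 mV with [Ca]_sub held at
    the requested level long enough for the gates to settle, then stepped
    to the holding voltage; the peak magnitude of I_CaL during the step is
    tabulated (A/F, reported as positive magnitude).
    """
    if base is None:
        base = control_parameters()
    if np.any(np.asarray(casub_levels) <= 0):
        raise ValueError("Ca levels must be positive")
    y0 = variant_initial_state(base)
    rows = []
    t_total = hold_ms + step_ms
    for ca in casub_levels:
        for vh in holding_vms:
            clamps = [
                ClampDirective(target="Ca_sub", mode="constant",
                               t_on=0.0, t_off=t_total, value=float(ca)),
                ClampDirective(target="V_m", mode="constant",
                               t_on=0.0, t_off=hold_ms, value=-80.0),
                ClampDirective(target="V_m", mode="constant",
                               t_on=hold_ms, t_off=t_total, value=float(vh)),
            ]
            tr = integrate(base, None, clamps=clamps, t_end=t_total, dt=dt,
                           y0=y0, store_every_ms=0.5)
            sl = tr.window_slice((hold_ms, t_total))
            ical = tr.current("I_CaL")[sl]
            rows.append({"holding_vm_mV": float(vh), "casub_mM": float(ca),
                         "peak_ical_AF": float(np.max(np.abs(ical)))})
    return pd.DataFrame(rows)


def casub_vs_holding_vm(levels,
                        variant: str = "zero_NCX",
                        base: ModelParameters | None = None,
                        hold_ms: float = 20000.0,
                        dt: float = 0.01) -> pd.DataFrame:
    """Late-time [Ca]_sub after switching V_m from -80 mV to each level.

    ``variant`` removes one coupling pathway: ``zero_NCX`` (alpha on the
    NCX density set to 0), ``zero_ICaL`` (alpha on P_Ca set to 0), or
    ``full``.  The reported value is the mean of the final 10% of the
    hold; if [Ca]_sub still oscillates there, the cycle mean is reported
    and flagged.
    """
    if variant not in ("full", "zero_NCX", "zero_ICaL"):
        raise ValueError(f"unknown variant {variant!r}")
    if base is None:
        base = control_parameters()
    if variant == "zero_NCX":
        params = apply_scaling(base, {"I_NCX_bar": 0.0})
    elif variant == "zero_ICaL":
        params = apply_scaling(base, {"P_Ca": 0.0})
    else:
        params = base
    y0 = variant_initial_state(base)
    rows = []
    for vh in levels:
        clamps = [ClampDirective(target="V_m", mode="constant",
                                 t_on=0.0, t_off=hold_ms, value=float(vh))]
        tr = integrate(params, None, clamps=clamps, t_end=hold_ms, dt=dt,
                       y0=y0, store_every_ms=2.0)
        tail = (0.9 * hold_ms, hold_ms)
        sl = tr.window_slice(tail)
        ca = tr.Ca_sub[sl]
        rep = detect_oscillations(tr, "Ca_sub", (0.5 * hold_ms, hold_ms))
        rows.append({"holding_vm_mV": float(vh),
                     "casub_mM": float(np.mean(ca)),
                     "oscillating": bool(rep.n_cycles >= 2)})
    return pd.DataFrame(rows)
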