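"""Core model: resting equilibrium, conservation, clamps, scaling, integrator."""

import numpy as np
import pytest

from eadkit.model import (ModelParameters, control_parameters, apply_scaling,
                          compute_derivatives, integrate, total_ca_mass,
                          SimulationDiverged)
from eadkit.protocols import build_stimulus, ClampDirective
from eadkit import _indices as ix


class TestRestingState:
    def test_derivatives_vanish_at_rest(self, rest_state, control):
        # the rested state is obtained by 20 s of unstimulated relaxation;
        # everything but the ultra-slow Na balance is numerically settled
        dy, _ = compute_derivatives(rest_state, control)
        fast = np.delete(dy, ix.INAI)
        assert np.max(np.abs(fast)) < 1e-4
        assert abs(dy[ix.INAI]) < 1e-4

    def test_equilibrium_persists_unstimulated(self, rest_state, control):
        tr = integrate(control, None, t_end=2000.0, dt=0.01, y0=rest_state)
        assert np.ptp(tr.V_m) < 1.0

    def test_invalid_state_rejected(self, rest_state, control):
        bad = rest_state.copy()
        bad[ix.IV] = np.nan
        with pytest.raises(ValueError):
            compute_derivatives(bad, control)


class TestDerivativeContracts:
    def test_voltage_equation_is_sum_of_components(self, rest_state, control):
        # dV/dt must equal -(sum of current components) + I_sti exactly
        y = rest_state.copy()
        y[ix.IV] = -20.0   # probe off-equilibrium
        dy, snap = compute_derivatives(y, control, i_sti=3.0)
        total = sum(snap.components.values())
        assert abs(snap.I_ion - total) < 1e-10
        assert abs(dy[ix.IV] - (-snap.I_ion + 3.0)) < 1e-10

    def test_ca_sub_clamp_zeroes_both_compartments(self, rest_state, control):
        cl = ClampDirective(target="Ca_sub", mode="constant", t_on=0.0,
                            t_off=100.0, value=5e-4)
        dy, _ = compute_derivatives(rest_state, control, clamps=[cl], t=1.0)
        assert dy[ix.ICAJ] == 0.0
        assert dy[ix.ICASL] == 0.0

    def test_unknown_clamp_target_rejected(self):
        with pytest.raises(KeyError):
            ClampDirective(target="I_Kr", mode="constant", value=0.0)

    def test_current_clamp_substituted_in_fluxes(self, rest_state, control):
        # clamping I_CaL to a large inward value must show up as a Ca influx
        cl = ClampDirective(target="I_CaL", mode="constant", t_on=0.0,
                            t_off=100.0, value=-10.0)
        dy_c, snap_c = compute_derivatives(rest_state, control, clamps=[cl],
                                           t=1.0)
        dy_0, _ = compute_derivatives(rest_state, control)
        assert snap_c.I_CaL == pytest.approx(-10.0)
        assert dy_c[ix.ICAJ] > dy_0[ix.ICAJ]


class TestScaling:
    def test_identity(self, control):
        p = apply_scaling(control, {n: 1.0 for n in
                                    ("k_max", "J_Caslmyo", "P_Ca", "G_Ks",
                                     "I_NCX_bar")})
        for n in ("k_max", "J_Caslmyo", "P_Ca", "G_Ks", "I_NCX_bar"):
            assert getattr(p, n) == getattr(control, n)

    @pytest.mark.parametrize("name,factor,expected", [
        ("P_Ca", 5.4, 5.4 * 0.00027),
        ("G_Ks", 0.56, 0.56 * 1.23),
        ("k_max", 7.0, 7.0 * 0.2),
    ])
    def test_arithmetic(self, control, name, factor, expected):
        p = apply_scaling(control, {name: factor})
        assert getattr(p, name) == pytest.approx(expected)

    def test_negative_factor_rejected(self, control):
        with pytest.raises(ValueError):
            apply_scaling(control, {"P_Ca": -1.0})

    def test_unknown_name_rejected(self, control):
        with pytest.raises(KeyError):
            apply_scaling(control, {"G_Kr": 2.0})

    def test_double_scaling_rejected(self, control):
        p = apply_scaling(control, {"P_Ca": 2.0})
        with pytest.raises(ValueError):
            apply_scaling(p, {"P_Ca": 2.0})


class TestIntegrator:
    def test_control_ap_repolarizes_without_eads(self, rest_state, control):
        from eadkit.analysis import measure_apd, detect_eads, _window_after_upstroke
        tr = integrate(control, build_stimulus(), t_end=10000.0, dt=0.01,
                       y0=rest_state, stop_when_repolarized=True)
        apd, repolarized = measure_apd(tr)
        assert repolarized
        assert 100.0 < apd < 450.0
        assert detect_eads(tr, _window_after_upstroke(tr)) == []

    def test_bit_identical_reruns(self, rest_state, control):
        a = integrate(control, build_stimulus(), t_end=500.0, dt=0.01,
                      y0=rest_state)
        b = integrate(control, build_stimulus(), t_end=500.0, dt=0.01,
                      y0=rest_state)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.currents, b.currents)

    def test_gating_variables_stay_in_unit_interval(self, rest_state, control):
        tr = integrate(control, build_stimulus(), t_end=600.0, dt=0.01,
                       y0=rest_state)
        gates = tr.states[:, [ix.IM, ix.IH, ix.IJ, ix.ID, ix.IF, ix.IXR,
                              ix.IXS, ix.IXTO, ix.IYTO, ix.IFCAJ, ix.IFCASL,
                              ix.IF2]]
        assert gates.min() >= 0.0
        assert gates.max() <= 1.0 + 1e-9

    def test_ryr_occupancies_sum_to_one(self, rest_state, control):
        tr = integrate(control, build_stimulus(), t_end=600.0, dt=0.01,
                       y0=rest_state)
        s = tr.states[:, ix.IRYR_R:ix.IRYR_RI + 1].sum(axis=1)
        assert np.max(np.abs(s - 1.0)) < 1e-9

    def test_submembrane_gradient_bounded(self, rest_state, control):
        # the junctional pool runs above the subsarcolemmal one while I_CaL
        # and SR release feed it, but the gradient stays bounded and decays
        # through the plateau (the two pools never decouple)
        tr = integrate(control, build_stimulus(), t_end=400.0, dt=0.01,
                       y0=rest_state)
        sl = tr.window_slice((30.0, 200.0))
        caj = tr.states[sl, ix.ICAJ]
        casl = tr.states[sl, ix.ICASL]
        ratio = caj / casl
        assert np.all(ratio > 0.9)
        assert np.max(ratio) < 6.0
        rel = np.abs(caj - casl) / (0.5 * (caj + casl))
        assert rel[-1] < rel[0]

    def test_ca_mass_conserved_without_membrane_fluxes(self, rest_state,
                                                       control):
        p = control.replace(zero_ca_membrane_flux=True)
        tr = integrate(p, build_stimulus(), t_end=5000.0, dt=0.01,
                       y0=rest_state)
        m = np.array([total_ca_mass(s) for s in tr.states[::250]])
        assert np.max(np.abs(m - m[0]) / m[0]) < 1e-3

    def test_divergence_signalled_with_failure_time(self, rest_state, control):
        y0 = rest_state.copy()
        y0[ix.IV] = 600.0
        with pytest.raises(SimulationDiverged) as exc:
            integrate(control, None, t_end=100.0, dt=0.01, y0=y0)
        assert exc.value.t_fail >= 0.0

    def test_invalid_dt_rejected(self, control):
        with pytest.raises(ValueError):
            integrate(control, None, t_end=10.0, dt=-0.01)

    def test_step_halving_convergence(self, rest_state, control):
        # Euler at dt = 0.01 vs 0.005: V_m agrees below 0.5 mV once the
        # 130 mV/ms upstroke has passed (there the same bound corresponds
        # to a few microseconds of timing shift)
        a = integrate(control, build_stimulus(), t_end=600.0, dt=0.01,
                      y0=rest_state)
        b = integrate(control, build_stimulus(), t_end=600.0, dt=0.005,
                      y0=rest_state)
        d = np.abs(a.V_m - b.V_m)
        assert np.max(d[5:]) < 0.5
        assert np.max(d[:5]) < 1.0
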