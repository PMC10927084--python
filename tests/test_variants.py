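"""f_ss flattening rule and the variant gating curves."""

import numpy as np
import pytest

from eadkit.model import control_parameters, fss_table
from eadkit.variants import GatingCurveSpec, flatten_fss


def brute_force_flatten(v, f):
    """Independent statement of the rule: equal up to the argmin, constant
    at the minimum beyond it."""
    i = int(np.argmin(f))
    out = f.copy()
    for j in range(len(f)):
        if j >= i:
            out[j] = f[i]
    return out


class TestFlattenRule:
    def test_monotone_input_unchanged(self):
        v = np.linspace(-80.0, 40.0, 121)
        f = 1.0 / (1.0 + np.exp((v + 35.0) / 4.0))
        flat = flatten_fss(GatingCurveSpec(v, f))
        # non-increasing curve: argmin at the end, output equals input
        assert np.allclose(flat.values, f)

    def test_model_curve_matches_brute_force(self):
        curve = GatingCurveSpec.from_model()
        flat = flatten_fss(curve)
        assert np.allclose(flat.values,
                           brute_force_flatten(curve.voltages, curve.values))
        i = int(np.argmin(curve.values))
        assert np.all(np.diff(flat.values[i:]) == 0.0)
        assert np.all(np.diff(flat.values) <= 1e-12)

    def test_idempotent(self):
        curve = GatingCurveSpec.from_model()
        once = flatten_fss(curve)
        twice = flatten_fss(once)
        assert np.allclose(once.values, twice.values)

    def test_kernel_variant_matches_rule(self):
        # the compiled model's flattened curve equals the tabulated rule
        v, f = fss_table()
        v2, ff = fss_table(flattened=True)
        expect = brute_force_flatten(v, f)
        # the kernel holds the value for V strictly above the (continuous)
        # argmin; at the grid level both agree to the grid resolution
        assert np.max(np.abs(ff - expect)) < 5e-3
        assert np.all(np.diff(ff) <= 1e-12)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            GatingCurveSpec(np.array([0.0, 1.0]), np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            GatingCurveSpec(np.array([1.0, 0.0]), np.array([0.5, 0.5]))


class TestControlCurveShape:
    def test_non_monotonic_with_late_elevation(self):
        v, f = fss_table()
        i_min = int(np.argmin(f))
        assert -40.0 < v[i_min] < 10.0
        # falls before the minimum, rises after it
        assert f[0] > f[i_min]
        assert f[-1] > f[i_min] * 1.5

    def test_values_in_unit_interval(self):
        _, f = fss_table()
        assert f.min() >= 0.0 and f.max() <= 1.0
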