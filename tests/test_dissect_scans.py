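"""Classifier tree and parameter scans (fast cases only; the full
representative-point dissections live in the acceptance suite)."""

import numpy as np
import pytest

from eadkit.model import control_parameters, apply_scaling
from eadkit.dissect import run_dissection
from eadkit.scans import monte_carlo, phase_diagram
from conftest import REPRESENTATIVE_ALPHA


class TestDissection:
    def test_control_is_unlabelled(self, rest_state, control):
        c = run_dissection(control, y0=rest_state)
        assert c.label == "none"
        assert c.repolarized
        assert c.baseline_eads == []

    def test_type_iv_point_quick(self, rest_state):
        p = apply_scaling(control_parameters(), REPRESENTATIVE_ALPHA["typeIV"])
        c = run_dissection(p, y0=rest_state, with_confirmatory=False)
        assert c.label == "typeIV"
        assert c.ca_cycles_baseline == 0

    def test_classification_deterministic(self, rest_state):
        p = apply_scaling(control_parameters(), REPRESENTATIVE_ALPHA["typeIV"])
        a = run_dissection(p, y0=rest_state, with_confirmatory=False)
        b = run_dissection(p, y0=rest_state, with_confirmatory=False)
        assert a.to_dict() == b.to_dict()

    def test_report_serializes(self, rest_state):
        import json
        p = apply_scaling(control_parameters(), REPRESENTATIVE_ALPHA["typeIV"])
        c = run_dissection(p, y0=rest_state)
        d = c.to_dict()
        json.dumps(d)
        assert d["label"] == "typeIV"
        assert d["n_eads"] >= 1


class TestMonteCarlo:
    def test_degenerate_range_is_all_control(self, rest_state):
        res = monte_carlo(n=5, alpha_range=(1.0, 1.0), seed=3)
        assert res.n_ead_positive == 0
        assert set(res.samples["label"]) == {"none"}

    def test_same_seed_bitwise_identical(self):
        a = monte_carlo(n=6, seed=11)
        b = monte_carlo(n=6, seed=11)
        assert a.samples.equals(b.samples)
        assert a.fractions == b.fractions

    def test_different_seed_different_draws(self):
        a = monte_carlo(n=6, seed=11)
        b = monte_carlo(n=6, seed=12)
        assert not a.samples[[c for c in a.samples if c.startswith("alpha")]]\
            .equals(b.samples[[c for c in b.samples if c.startswith("alpha")]])

    def test_log_uniform_draws_within_range(self):
        res = monte_carlo(n=12, seed=2, alpha_range=(0.1, 10.0))
        cols = [c for c in res.samples if c.startswith("alpha")]
        vals = res.samples[cols].to_numpy()
        assert vals.min() >= 0.1 and vals.max() <= 10.0

    def test_fractions_sum_to_one_when_positive(self):
        res = monte_carlo(n=40, seed=1)
        if res.n_ead_positive:
            assert sum(res.fractions.values()) == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo(n=0)
        with pytest.raises(ValueError):
            monte_carlo(n=2, alpha_range=(0.0, 1.0))


class TestPhaseDiagram:
    def test_control_cell_is_none(self):
        grid = phase_diagram([1.0], [1.0])
        assert grid.labels.shape == (1, 1)
        assert grid.label_at(1.0, 1.0) == "none"

    def test_frame_has_all_cells(self):
        grid = phase_diagram([0.5, 1.0], [1.0])
        df = grid.to_frame()
        assert len(df) == 2
        assert set(df.columns) == {"alpha_PCa", "alpha_GKs", "label"}
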