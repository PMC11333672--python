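"""Learning-curve analysis: segmentation, windows, paired statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from bgloop.config import make_fixture_curve
from bgloop.experiment import (
    LearningCurve, compare_conditions, paired_test, perturb_robustness,
    response_time_summary, run_condition, segment_phases, window_error,
)
from bgloop.lesion import LesionSpec


class TestSegmentation:
    def test_constant_zero_curve(self):
        seg = segment_phases(np.zeros(40))
        assert seg.early_end == 0
        assert seg.progressing_end == 10
        assert seg.learning_time == 10
        assert seg.complete

    def test_three_plateau_synthetic_curve(self):
        """Error 1.0 for epochs 1-20, 0.40 for 21-50, 0.03 from 51."""
        curve = np.concatenate([np.full(20, 1.0), np.full(30, 0.40),
                                np.full(50, 0.03)])
        seg = segment_phases(curve)
        assert seg.early_end == 20
        assert seg.progressing_end == 60
        assert seg.learning_time == 60

    def test_never_learning_curve_incomplete(self):
        curve = np.full(300, 0.30)
        seg = segment_phases(curve)
        assert seg.early_end == 0            # below chance immediately
        assert seg.progressing_end is None
        assert not seg.complete
        assert seg.learning_time is None

    def test_phase_ordering_invariant_on_fixture_curves(self):
        for seed in range(20):
            fc = make_fixture_curve(
                plateaus=(0.9, 0.4, 0.02), changepoints=(15, 40),
                n_epochs=120, noise_sd=0.05, seed=seed,
            )
            seg = segment_phases(fc.values)
            assert 0 <= seg.early_end <= 120
            if seg.complete:
                assert seg.early_end <= seg.progressing_end <= 120

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            segment_phases(np.array([]))


class TestWindowError:
    def test_constant_half_curve(self):
        assert window_error(np.full(100, 0.5), 1, 30) == pytest.approx(50.0)
        assert window_error(np.full(100, 0.5), 60, 30) == pytest.approx(50.0)

    def test_zero_curve(self):
        assert window_error(np.zeros(100), 31, 30) == 0.0

    def test_synthetic_curve_window_mean(self):
        curve = np.concatenate([np.full(20, 1.0), np.full(30, 0.40),
                                np.full(50, 0.03)])
        assert window_error(curve, 21, 30) == pytest.approx(40.0)

    def test_out_of_range_window_rejected(self):
        with pytest.raises(ValueError):
            window_error(np.zeros(50), 30, 30)
        with pytest.raises(ValueError):
            window_error(np.zeros(50), 0, 10)


class TestPairedTest:
    def test_identical_samples_flagged_degenerate(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert math.isnan(res.p)

    def test_constant_shift_flagged_degenerate(self):
        """Pairs (1,2),(2,3),(3,4): zero variance of differences."""
        res = paired_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate
        assert res.mean_diff == pytest.approx(-1.0)

    def test_matches_closed_form_paired_t(self):
        """Pairs (1,2),(2,2),(3,5): t and p from the textbook formula."""
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 2.0, 5.0])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        res = paired_test(a, b)
        assert res.t == pytest.approx(t_expected, abs=1e-9)
        # closed-form two-sided p for df=2: F(t) = 1/2 + t / (2 sqrt(2+t^2))
        t = abs(t_expected)
        p_expected = 2 * (1 - (0.5 + t / (2 * math.sqrt(2 + t * t))))
        assert res.p == pytest.approx(p_expected, abs=1e-9)

    def test_bonferroni_adjustment_caps_at_one(self):
        res = paired_test([1.0, 2.0, 3.0], [2.0, 2.0, 5.0], n_comparisons=5)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p * 5))
        res2 = paired_test([1.0, 2.0, 3.0], [1.1, 2.0, 3.2],
                           n_comparisons=1000)
        assert res2.p_adjusted == 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestResponseTimeSummary:
    def make_trials(self, times_by_net):
        rows = []
        for net, times in times_by_net.items():
            for k, t in enumerate(times):
                rows.append((net, 1, k + 1, 1, 1, True, t))
        return pd.DataFrame(rows, columns=["network", "epoch", "trial",
                                           "stimulus", "response", "correct",
                                           "response_time"])

    def test_uniform_times(self):
        per_net, mean = response_time_summary(
            self.make_trials({0: [400.0] * 4}))
        assert mean == 400.0

    def test_mixed_times_average(self):
        per_net, mean = response_time_summary(
            self.make_trials({0: [400.0, 800.0]}))
        assert mean == 600.0

    def test_all_no_response_uses_deadline(self):
        """No-response trials are logged at the 800 ms deadline."""
        per_net, mean = response_time_summary(
            self.make_trials({0: [800.0] * 3, 1: [800.0] * 3}))
        assert mean == 800.0
        assert np.allclose(per_net, 800.0)


class TestLearningCurveContainer:
    def test_mean_and_sd_shapes(self):
        c = LearningCurve(np.array([[1.0, 0.5, 0.0], [0.5, 0.5, 0.0]]))
        assert c.n_networks == 2 and c.n_epochs == 3
        assert np.allclose(c.mean_error, [0.75, 0.5, 0.0])

    def test_rejects_out_of_range_errors(self):
        with pytest.raises(ValueError):
            LearningCurve(np.array([[1.5, 0.0]]))


class TestRunCondition:
    def test_smoke_run_defines_curve_for_all_epochs(self):
        cond = run_condition(LesionSpec(0.0), n_networks=2, n_epochs=10,
                             base_seed=7)
        assert cond.curve.per_network.shape == (2, 10)
        assert len(cond.trials) == 2 * 10 * 4
        assert cond.response_times.shape == (2,)

    def test_same_base_seed_identical_summaries(self):
        a = run_condition(LesionSpec(0.0), n_networks=2, n_epochs=6,
                          base_seed=3)
        b = run_condition(LesionSpec(0.0), n_networks=2, n_epochs=6,
                          base_seed=3)
        assert np.array_equal(a.curve.per_network, b.curve.per_network)
        assert a.trials.equals(b.trials)
        assert np.array_equal(a.learning_times, b.learning_times)

    def test_requires_at_least_one_network(self):
        with pytest.raises(ValueError):
            run_condition(LesionSpec(0.0), n_networks=0, n_epochs=5)


class TestCompareConditions:
    def small(self, lesion, base_seed=3):
        return run_condition(LesionSpec(lesion), n_networks=3, n_epochs=8,
                             base_seed=base_seed)

    def test_empty_lesioned_list_gives_empty_table(self):
        healthy = self.small(0.0)
        table = compare_conditions(healthy, [], window_starts=(1,),
                                   window_length=5)
        assert len(table) == 0

    def test_healthy_vs_itself_degenerate(self):
        healthy = self.small(0.0)
        table = compare_conditions(healthy, [healthy], window_starts=(1,),
                                   window_length=5)
        assert table["degenerate"].all() or (table["p_adjusted"] > 0.05).all()

    def test_mismatched_pairing_rejected(self):
        healthy = self.small(0.0, base_seed=3)
        other = self.small(0.3, base_seed=4)
        with pytest.raises(ValueError, match="base_seed"):
            compare_conditions(healthy, [other], window_starts=(1,),
                               window_length=5)


class TestPerturbRobustness:
    def test_zero_networks_empty_report(self):
        report = perturb_robustness(0.05, n=0, n_epochs=2)
        assert len(report) == 0

    def test_zero_scale_matches_unperturbed_baseline(self):
        a = perturb_robustness(0.0, n=1, n_epochs=4, base_seed=8)
        b = perturb_robustness(0.0, n=1, n_epochs=4, base_seed=8)
        assert a.equals(b)
        cond = run_condition(LesionSpec(0.0), n_networks=1, n_epochs=4,
                             base_seed=8)
        assert a["final_error"].iloc[0] == pytest.approx(
            cond.curve.per_network[0, -4:].mean()
        )
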