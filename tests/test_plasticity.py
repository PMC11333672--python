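"""The two-phase learning rule: scalar oracles, boundedness, directionality."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bgloop.params import LearningParams
from bgloop.plasticity import (
    ActivationSnapshot, apply_cortical_update, apply_striatal_update,
    combine_update, error_delta, hebbian_delta, soft_bound,
    windowed_activation,
)

LP = LearningParams()

unit = st.floats(min_value=0.0, max_value=1.0)


def snap(layer, phase, values, window=60.0):
    return ActivationSnapshot(layer=layer, phase=phase,
                              values=np.asarray(values, float), window=window)


class TestScalarComponents:
    @pytest.mark.parametrize(
        "x,y,w,expected",
        [(0.3, 0.7, 0.3, 0.0),       # fixed point at w = x
         (0.5, 0.0, 0.1, 0.0),       # silent postsynapse, no change
         (0.8, 0.5, 0.3, 0.25)],     # hand evaluation
    )
    def test_hebbian_delta(self, x, y, w, expected):
        assert hebbian_delta(x, y, w) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "xp,yp,xm,ym,expected",
        [(0.4, 0.6, 0.4, 0.6, 0.0),  # identical phases
         (1.0, 1.0, 0.0, 0.0, 1.0),
         (0.0, 0.0, 0.5, 0.6, -0.3)],
    )
    def test_error_delta(self, xp, yp, xm, ym, expected):
        assert error_delta(xp, yp, xm, ym) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "delta,w,expected",
        [(0.5, 1.0, 0.0),            # ceiling
         (-0.5, 0.0, 0.0),           # floor
         (0.4, 0.25, 0.3),           # 0.4 * (1 - 0.25)
         (-0.4, 0.25, -0.1)],        # -0.4 * 0.25
    )
    def test_soft_bound(self, delta, w, expected):
        assert soft_bound(delta, w) == pytest.approx(expected, abs=1e-15)

    def test_combine_update_hand_value(self):
        assert combine_update(0.25, 0.3, eps=0.1, k_hebb=0.01) == pytest.approx(
            0.02995, abs=1e-12
        )

    def test_combine_update_pure_hebbian_limit(self):
        assert combine_update(0.37, 0.9, eps=0.2, k_hebb=1.0) == pytest.approx(
            0.2 * 0.37
        )

    def test_combine_update_zero(self):
        assert combine_update(0.0, 0.0, eps=0.1, k_hebb=0.01) == 0.0


class TestWindowedActivation:
    def test_silent_train_is_zero(self):
        assert windowed_activation(np.zeros(50), 60.0, 2.0) == 0.0

    def test_every_step_saturates(self):
        assert windowed_activation(np.ones(30), 60.0, 2.0) == 1.0

    def test_half_filled_window(self):
        counts = np.zeros(30)
        counts[::2] = 1.0          # 15 spikes over 30 steps
        assert windowed_activation(counts, 60.0, 2.0) == pytest.approx(0.5)

    def test_uses_trailing_window_only(self):
        counts = np.concatenate([np.ones(40), np.zeros(30)])
        assert windowed_activation(counts, 60.0, 2.0) == 0.0

    def test_multi_spike_steps_count_once(self):
        counts = np.full(30, 3.0)
        assert windowed_activation(counts, 60.0, 2.0) == 1.0

    def test_window_shorter_than_step_rejected(self):
        with pytest.raises(ValueError):
            windowed_activation(np.zeros(30), 0.5, 2.0)


class TestStriatalUpdate:
    def oracle(self, w, xm, xp, ym, yp, params):
        """Scalar re-derivation of the full rule, one synapse at a time."""
        d_hebb = yp * (xp - w)
        d_err = xp * yp - xm * ym
        d_sberr = d_err * (1 - w) if d_err > 0 else d_err * w
        raw = params.k_hebb * d_hebb + (1 - params.k_hebb) * d_sberr
        eps = params.eps_ltp if raw > 0 else params.eps_ltd
        return min(1.0, max(0.0, w + eps * raw))

    def test_matches_scalar_oracle_on_toy_network(self):
        """3-synapse toy projection equals the scalar trace to 1e-12."""
        pre = np.array([0, 1, 2])
        post = np.array([0, 0, 1])
        w = np.array([0.3, 0.9, 0.05])
        xm = snap("input", "response", [0.2, 0.8, 0.5])
        xp = snap("input", "feedback", [0.3, 0.7, 0.5])
        ym = snap("striatum_go", "response", [0.4, 0.1])
        yp = snap("striatum_go", "feedback", [0.9, 0.0])
        out = apply_striatal_update(w, pre, post, xm, xp, ym, yp, LP)
        for k in range(3):
            expected = self.oracle(
                w[k], xm.values[pre[k]], xp.values[pre[k]],
                ym.values[post[k]], yp.values[post[k]], LP,
            )
            assert out[k] == pytest.approx(expected, abs=1e-12)

    def test_single_synapse_hand_trace(self):
        """x-=x+=1, y-=0, y+=1, w=0 gives w <- 0.1 at default rates."""
        out = apply_striatal_update(
            np.array([0.0]), np.array([0]), np.array([0]),
            snap("input", "response", [1.0]), snap("input", "feedback", [1.0]),
            snap("striatum_go", "response", [0.0]),
            snap("striatum_go", "feedback", [1.0]),
            LP,
        )
        assert out[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_phases_no_error_term(self):
        lp = LearningParams(k_hebb=0.0)
        w = np.array([0.2, 0.7])
        s_in = [0.5, 0.6]
        s_y = [0.3, 0.4]
        out = apply_striatal_update(
            w, np.array([0, 1]), np.array([0, 1]),
            snap("input", "response", s_in), snap("input", "feedback", s_in),
            snap("striatum_go", "response", s_y),
            snap("striatum_go", "feedback", s_y),
            lp,
        )
        assert np.allclose(out, w)

    def test_saturated_weight_stays_at_ceiling(self):
        out = apply_striatal_update(
            np.array([1.0]), np.array([0]), np.array([0]),
            snap("input", "response", [0.0]), snap("input", "feedback", [1.0]),
            snap("striatum_go", "response", [0.0]),
            snap("striatum_go", "feedback", [1.0]),
            LP,
        )
        assert out[0] == pytest.approx(1.0)

    def test_missing_or_mistagged_snapshot_rejected(self):
        args = (np.array([0.0]), np.array([0]), np.array([0]))
        good_resp = snap("input", "response", [1.0])
        good_fb = snap("input", "feedback", [1.0])
        y_resp = snap("striatum_go", "response", [0.0])
        y_fb = snap("striatum_go", "feedback", [1.0])
        with pytest.raises(ValueError):
            apply_striatal_update(*args, None, good_fb, y_resp, y_fb, LP)
        with pytest.raises(ValueError):
            apply_striatal_update(*args, good_fb, good_fb, y_resp, y_fb, LP)

    def test_burst_and_dip_directionality(self):
        """Raised feedback activity potentiates active synapses; a dip
        (feedback activity suppressed) depresses them."""
        pre = np.arange(4)
        post = np.arange(4)
        w = np.full(4, 0.5)
        x_resp = snap("input", "response", [0.6] * 4)
        x_fb = snap("input", "feedback", [0.6] * 4)
        y_resp = snap("striatum_go", "response", [0.3] * 4)
        burst = snap("striatum_go", "feedback", [0.8] * 4)
        dip = snap("striatum_go", "feedback", [0.0] * 4)
        up = apply_striatal_update(w, pre, post, x_resp, x_fb, y_resp, burst, LP)
        down = apply_striatal_update(w, pre, post, x_resp, x_fb, y_resp, dip, LP)
        assert np.all(up >= w)
        assert np.all(down <= w)


class TestCorticalUpdate:
    def test_silent_postsynapse_no_change(self):
        w = np.array([0.3, 0.4])
        out = apply_cortical_update(
            w, np.array([0, 1]), np.array([0, 1]),
            snap("input", "feedback", [0.9, 0.9]),
            snap("pmc", "feedback", [0.0, 0.0]),
            LP,
        )
        assert np.array_equal(out, w)

    def test_single_step_from_zero(self):
        out = apply_cortical_update(
            np.array([0.0]), np.array([0]), np.array([0]),
            snap("input", "feedback", [1.0]), snap("pmc", "feedback", [1.0]),
            LP,
        )
        assert out[0] == pytest.approx(LP.eps_cortical, abs=1e-15)

    def test_converges_monotonically_to_presynaptic_activation(self):
        lp = LearningParams(eps_cortical=0.05)
        w = np.array([0.0])
        xp = snap("input", "feedback", [0.8])
        yp = snap("pmc", "feedback", [1.0])
        prev = 0.0
        for _ in range(400):
            w = apply_cortical_update(w, np.array([0]), np.array([0]),
                                      xp, yp, lp)
            assert w[0] >= prev - 1e-15
            prev = w[0]
        assert w[0] == pytest.approx(0.8, abs=1e-3)

    def test_response_snapshot_rejected(self):
        with pytest.raises(ValueError):
            apply_cortical_update(
                np.array([0.0]), np.array([0]), np.array([0]),
                snap("input", "response", [1.0]),
                snap("pmc", "feedback", [1.0]),
                LP,
            )


class TestBoundedness:
    def test_weights_stay_in_unit_interval_under_random_sequences(self):
        """>= 10^4 randomized updates never push a weight outside [0, 1]."""
        rng = np.random.default_rng(2024)
        n_syn = 50
        pre = rng.integers(0, 10, n_syn)
        post = rng.integers(0, 10, n_syn)
        w = rng.uniform(0, 1, n_syn)
        for _ in range(250):                     # 250 x 50 = 12500 cases
            lp = LearningParams(
                k_hebb=float(rng.uniform(0, 1)),
                eps_ltp=float(rng.uniform(0, 1)),
                eps_ltd=float(rng.uniform(0, 1)),
            )
            w = apply_striatal_update(
                w, pre, post,
                snap("input", "response", rng.uniform(0, 1, 10)),
                snap("input", "feedback", rng.uniform(0, 1, 10)),
                snap("striatum_go", "response", rng.uniform(0, 1, 10)),
                snap("striatum_go", "feedback", rng.uniform(0, 1, 10)),
                lp,
            )
            assert w.min() >= 0.0 and w.max() <= 1.0

    @settings(derandomize=True, max_examples=100)
    @given(w=unit, xm=unit, xp=unit, ym=unit, yp=unit, k=unit)
    def test_single_update_bounded(self, w, xm, xp, ym, yp, k):
        lp = LearningParams(k_hebb=k, eps_ltp=1.0, eps_ltd=1.0)
        out = apply_striatal_update(
            np.array([w]), np.array([0]), np.array([0]),
            snap("input", "response", [xm]), snap("input", "feedback", [xp]),
            snap("striatum_go", "response", [ym]),
            snap("striatum_go", "feedback", [yp]),
            lp,
        )
        assert 0.0 <= out[0] <= 1.0

    def test_snapshot_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            snap("input", "response", [1.2])
        with pytest.raises(ValueError):
            snap("input", "feedback", [-0.1])
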