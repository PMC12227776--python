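"""Costs, learning rules (against central finite differences),
gradient blocking, feedback construction, and the training loop."""

import numpy as np
import pytest

from laminar.circuit import (
    MicrocircuitWeights,
    StepActivations,
    forward_step,
)
from laminar.plasticity import (
    FeedbackSpec,
    LearningConfig,
    grad_upstream,
    grad_w_l23_l5,
    grad_w_l4_l23,
    grad_w_thal_l5,
    l5_error_signal,
    l23_error_signal,
    make_feedback,
    plasticity_curve,
    predictive_cost,
    raw_gradients,
    reconstruction_cost,
    train,
)

CFG = LearningConfig(lambda_p=0.7, lambda_r=1.3, eta=1e-3)


def finite_difference(weights, name, x_prev, x_t, itd, cost_fn, eps=1e-6):
    """Central finite differences of ``cost_fn`` w.r.t. one weight matrix."""
    W = getattr(weights, name)
    fd = np.zeros_like(W)
    it = np.nditer(W, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = W[i]
        W[i] = orig + eps
        cp = cost_fn(forward_step(x_prev, x_t, itd, weights))
        W[i] = orig - eps
        cm = cost_fn(forward_step(x_prev, x_t, itd, weights))
        W[i] = orig
        fd[i] = (cp - cm) / (2 * eps)
    return fd


def cost_pred(a):
    return CFG.lambda_p * predictive_cost(a)


def cost_recon(a):
    return CFG.lambda_r * reconstruction_cost(a)


def cost_total(a):
    return cost_pred(a) + cost_recon(a)


class TestCosts:
    def test_trivial_values(self, random_step):
        a, _ = random_step
        perfect = StepActivations(
            **{**a.__dict__, "zhat_l5": a.z_l5.copy(), "xhat": a.x_t.copy()}
        )
        assert predictive_cost(perfect) == 0.0
        assert reconstruction_cost(perfect) == 0.0

        half = StepActivations(
            **{
                **a.__dict__,
                "zhat_l5": np.array([1.0, 0, 0, 0]),
                "z_l5": np.zeros(4),
                "x_t": np.array([1.0, 0, 0, 0, 0, 0]),
                "xhat": np.zeros(6),
            }
        )
        assert half.zhat_l5 is not None
        assert predictive_cost(half) == pytest.approx(0.5)
        assert reconstruction_cost(half) == pytest.approx(0.5)

    def test_matches_half_squared_norm_oracle(self, random_step):
        a, _ = random_step
        assert predictive_cost(a) == pytest.approx(
            0.5 * np.linalg.norm(a.zhat_l5 - a.z_l5) ** 2, abs=1e-12
        )
        assert reconstruction_cost(a) == pytest.approx(
            0.5 * np.linalg.norm(a.x_t - a.xhat) ** 2, abs=1e-12
        )


class TestGradients:
    """Every analytic gradient agrees with central finite differences on
    random small instances (symmetric feedback)."""

    @pytest.mark.parametrize(
        "name, cost_fn",
        [
            ("W_l23_l5", cost_pred),
            ("W_l4_l23", cost_pred),
            ("W_thal_l4", cost_pred),
            ("W_td_l23", cost_pred),
            ("W_thal_l5", cost_total),
            ("W_decoder", cost_recon),
        ],
    )
    def test_matches_finite_differences(self, small_weights, rng, name, cost_fn):
        x_prev, x_t, itd = rng.random(6), rng.random(6), rng.random(3)
        a = forward_step(x_prev, x_t, itd, small_weights)
        g = raw_gradients(a, small_weights, CFG)[name]
        fd = finite_difference(small_weights, name, x_prev, x_t, itd, cost_fn)
        rel = np.abs(g - fd).max() / np.abs(fd).max()
        assert rel <= 1e-5

    def test_public_updates_scale_with_eta(self, random_step, small_weights):
        a, _ = random_step
        cfg2 = LearningConfig(lambda_p=0.7, lambda_r=1.3, eta=2e-3)
        assert np.allclose(
            grad_w_l23_l5(a, small_weights, cfg2),
            2.0 * grad_w_l23_l5(a, small_weights, CFG),
        )
        assert np.allclose(
            grad_w_thal_l5(a, small_weights, cfg2),
            2.0 * grad_w_thal_l5(a, small_weights, CFG),
        )

    def test_literal_form_drops_sigmoid_derivative(self, random_step, small_weights):
        """The optional literal thalamus->L5 rule omits the sigma' factor
        and therefore does not match the true gradient."""
        a, (x_prev, x_t, itd) = random_step
        lit = LearningConfig(lambda_p=0.7, lambda_r=1.3, literal_eq9=True)
        g_lit = raw_gradients(a, small_weights, lit)["W_thal_l5"]
        fd = finite_difference(small_weights, "W_thal_l5", x_prev, x_t, itd, cost_total)
        sd5 = a.z_l5 * (1 - a.z_l5)
        assert np.allclose(g_lit * sd5[:, None], fd, rtol=1e-4)
        assert not np.allclose(g_lit, fd, rtol=1e-2)

    def test_error_signals_match_finite_differences(self, small_weights, rng):
        """dC/dz_l5 and dC/dz_l23 by perturbing activations directly."""
        x_prev, x_t, itd = rng.random(6), rng.random(6), rng.random(3)
        a = forward_step(x_prev, x_t, itd, small_weights)
        w = small_weights
        e5 = l5_error_signal(a, w, CFG)

        def c_of_z5(z5):
            zhat = a.zhat_l5
            xhat = w.W_decoder @ z5
            return CFG.lambda_p * 0.5 * np.sum((zhat - z5) ** 2) + CFG.lambda_r * 0.5 * np.sum(
                (a.x_t - xhat) ** 2
            )

        eps = 1e-6
        for i in range(4):
            z = a.z_l5.copy()
            z[i] += eps
            cp = c_of_z5(z)
            z[i] -= 2 * eps
            cm = c_of_z5(z)
            assert e5[i] == pytest.approx((cp - cm) / (2 * eps), rel=1e-5)

        # L2/3: predictive cost with z_l5 recomputed through the L5 drive
        from scipy.special import expit

        e23 = l23_error_signal(a, w, CFG)

        def c_of_z23(z23):
            zhat = w.W_l23_l5 @ z23
            z5 = expit(w.alpha * (w.W_l23_l5 @ z23) + w.W_thal_l5 @ x_t)
            return CFG.lambda_p * 0.5 * np.sum((zhat - z5) ** 2)

        for j in range(7):
            z = a.z_l23.copy()
            z[j] += eps
            cp = c_of_z23(z)
            z[j] -= 2 * eps
            cm = c_of_z23(z)
            assert e23[j] == pytest.approx((cp - cm) / (2 * eps), rel=1e-4, abs=1e-10)

    def test_l23_error_reduces_to_transpose_at_alpha_zero(self, rng):
        w = MicrocircuitWeights.initialize(6, 5, 7, 4, 3, alpha=1e-300, seed=1)
        a = forward_step(rng.random(6), rng.random(6), rng.random(3), w)
        e = CFG.lambda_p * (a.zhat_l5 - a.z_l5)
        assert np.allclose(l23_error_signal(a, w, CFG), w.W_l23_l5.T @ e, atol=1e-12)

    def test_l5_error_negative_under_overprediction(self, small_weights, random_step):
        """When the prediction exceeds L5 activity and the reconstruction
        term is off, the L5 error signal is strictly negative."""
        a, _ = random_step
        boosted = StepActivations(
            **{**a.__dict__, "zhat_l5": a.z_l5 + 0.5}
        )
        cfg = LearningConfig(lambda_p=1.0, lambda_r=0.0)
        assert np.all(l5_error_signal(boosted, small_weights, cfg) < 0)


class TestBlockingAndFeedback:
    def test_decoder_perturbation_never_alters_l23_path_updates(
        self, small_weights, random_step
    ):
        a, _ = random_step
        g1 = raw_gradients(a, small_weights, CFG)
        small_weights.W_decoder += 0.37
        a2 = StepActivations(
            **{**a.__dict__, "xhat": small_weights.W_decoder @ a.z_l5}
        )
        g2 = raw_gradients(a2, small_weights, CFG)
        for name in ("W_l23_l5", "W_l4_l23", "W_thal_l4", "W_td_l23"):
            assert np.array_equal(g1[name], g2[name])

    def test_no_feedback_zeroes_upstream_updates(self, random_step, small_weights):
        a, _ = random_step
        make_feedback(small_weights, FeedbackSpec("none"))
        assert np.all(grad_w_l4_l23(a, small_weights, CFG) == 0.0)
        ups = grad_upstream(a, small_weights, CFG)
        assert np.all(ups["W_thal_l4"] == 0.0)
        assert np.all(ups["W_td_l23"] == 0.0)
        assert not np.all(ups["W_decoder"] == 0.0)
        make_feedback(small_weights, FeedbackSpec("symmetric"))

    def test_random_feedback_update_is_seeded_and_repeatable(
        self, random_step, small_weights
    ):
        a, _ = random_step
        spec = FeedbackSpec("random", mask_seed=5)
        g1 = grad_w_l4_l23(a, small_weights, CFG, feedback=spec)
        g2 = grad_w_l4_l23(a, small_weights, CFG, feedback=spec)
        assert np.array_equal(g1, g2)
        g3 = grad_w_l4_l23(a, small_weights, CFG, feedback=FeedbackSpec("random", mask_seed=6))
        assert not np.array_equal(g1, g3)
        make_feedback(small_weights, FeedbackSpec("symmetric"))

    def test_feedback_mask_fraction_within_binomial_bound(self):
        w = MicrocircuitWeights.initialize(4, 3, 40, 25, 2, seed=0)
        make_feedback(w, FeedbackSpec("symmetric", p_connectivity=0.5, mask_seed=1))
        n = w.feedback_mask.size
        frac = w.feedback_mask.mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_connectivity_extremes(self, small_weights):
        make_feedback(small_weights, FeedbackSpec("symmetric", p_connectivity=1.0))
        assert np.array_equal(small_weights.W_feedback, small_weights.W_l23_l5.T)
        make_feedback(small_weights, FeedbackSpec("symmetric", p_connectivity=0.0))
        assert np.all(small_weights.W_feedback == 0.0)
        make_feedback(small_weights, FeedbackSpec("symmetric"))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            FeedbackSpec("symmetric", p_connectivity=1.5)


class TestTraining:
    @staticmethod
    def _stream(rng, n=100):
        for _ in range(n):
            yield rng.random(6), rng.random(6), rng.random(3)

    def test_equal_seeds_give_identical_weights(self, rng):
        outs = []
        for _ in range(2):
            w = MicrocircuitWeights.initialize(6, 5, 7, 4, 3, seed=2)
            make_feedback(w, FeedbackSpec("symmetric"))
            r = np.random.default_rng(7)
            train(w, self._stream(r, 50), LearningConfig())
            outs.append(w)
        for name in outs[0].TRAINABLE:
            assert np.array_equal(getattr(outs[0], name), getattr(outs[1], name))

    def test_cost_decreases_on_repeated_input(self, rng):
        w = MicrocircuitWeights.initialize(6, 5, 7, 4, 3, seed=2)
        make_feedback(w, FeedbackSpec("symmetric"))
        x_prev, x_t, itd = rng.random(6), rng.random(6), rng.random(3)
        res = train(
            w, ((x_prev, x_t, itd) for _ in range(100)),
            LearningConfig(eta=1e-2), record_every=1,
        )
        c = res.costs["c_total"].to_numpy()
        assert c[-1] < c[0]
        # monotone up to optimizer noise: overwhelmingly decreasing steps
        assert np.mean(np.diff(c) <= 1e-9) > 0.9

    def test_no_feedback_leaves_upstream_matrices_invariant(self, rng):
        w = MicrocircuitWeights.initialize(6, 5, 7, 4, 3, seed=2)
        make_feedback(w, FeedbackSpec("none"))
        before = {n: getattr(w, n).copy() for n in ("W_l4_l23", "W_thal_l4", "W_td_l23")}
        train(w, self._stream(rng, 60), LearningConfig())
        for name, W in before.items():
            assert np.array_equal(W, getattr(w, name))

    def test_divergence_aborts_with_diagnostic(self, rng):
        w = MicrocircuitWeights.initialize(6, 5, 7, 4, 3, seed=2)
        make_feedback(w, FeedbackSpec("symmetric"))
        w.W_decoder *= 1e200
        with pytest.raises(RuntimeError, match="diverged"):
            train(w, self._stream(rng, 50), LearningConfig(optimizer="sgd", eta=1e150),
                  record_every=1)

    def test_nonneg_projection_keeps_matrices_nonnegative(self, rng):
        w = MicrocircuitWeights.initialize(6, 5, 7, 4, 3, seed=2)
        for n in ("W_thal_l4", "W_thal_l5"):
            setattr(w, n, np.abs(getattr(w, n)))
        make_feedback(w, FeedbackSpec("symmetric"))
        train(w, self._stream(rng, 80), LearningConfig(),
              nonneg=("W_thal_l4", "W_thal_l5"))
        assert np.all(w.W_thal_l4 >= 0)
        assert np.all(w.W_thal_l5 >= 0)


class TestPlasticityCurve:
    def test_depression_to_potentiation_switch(self):
        table, slope = plasticity_curve(n_samples=300, seed=0)
        assert slope > 0
        low = table[table.z_l5 < 0.3]["mean_update"].mean()
        high = table[table.z_l5 > 0.7]["mean_update"].mean()
        assert low < 0 < high

    def test_zero_error_gives_zero_update(self, small_weights, random_step):
        a, _ = random_step
        exact = StepActivations(**{**a.__dict__, "zhat_l5": a.z_l5.copy()})
        assert np.all(grad_w_l23_l5(exact, small_weights, CFG) == 0.0)

    def test_update_linear_in_learning_rate(self):
        t1, _ = plasticity_curve(n_samples=50, seed=3, eta=1e-3)
        t2, _ = plasticity_curve(n_samples=50, seed=3, eta=2e-3)
        assert np.allclose(2 * t1["mean_update"], t2["mean_update"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            plasticity_curve(n_samples=5)
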