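"""Loss terms, sparse pathway layer, attention and latent primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radiosurv.autodiff import Tensor
from radiosurv.datatypes import SurvivalLabels
from radiosurv.layers import (
    Adam,
    MultiHeadAttention,
    SparsePathwayLayer,
    apply_mask_constraint,
    multi_head_attention,
    scaled_dot_attention,
)
from radiosurv.losses import (
    CapacitySchedule,
    capacity_regularizer,
    cox_loss_t,
    cox_neg_log_partial_likelihood,
    kl_gaussian,
    l2_penalty,
    mse_loss,
    reparameterize,
    sparse_pathway_forward,
)


# ---------------------------------------------------------------------------
# sparse pathway layer
# ---------------------------------------------------------------------------

class TestSparsePathwayForward:
    def test_all_ones_mask_equals_dense(self, rng):
        m, q, n = 5, 3, 4
        W0 = rng.standard_normal((m, m))
        b0 = rng.standard_normal(m)
        W = rng.standard_normal((m, q))
        b = rng.standard_normal(q)
        g0 = rng.standard_normal((n, m))
        dense = np.maximum(np.maximum(g0 @ W0 + b0, 0) @ W + b, 0)
        out = sparse_pathway_forward(g0, W0, b0, W, np.ones((m, q)), b)
        assert np.allclose(out, dense)

    def test_fully_masked_zero_output(self, rng):
        m, q = 4, 2
        out = sparse_pathway_forward(
            rng.standard_normal(m), rng.standard_normal((m, m)),
            np.zeros(m), rng.standard_normal((m, q)), np.zeros((m, q)),
            np.zeros(q))
        assert np.all(out == 0)

    def test_hand_evaluated_case(self):
        # m=2, q=1, W0=I, b0=0, g0=(1,2), W=((3),(4)), A=((1),(0)), b=0
        out = sparse_pathway_forward([1.0, 2.0], np.eye(2), np.zeros(2),
                                     [[3.0], [4.0]], [[1.0], [0.0]], [0.0])
        assert out[0] == pytest.approx(3.0)

    def test_masked_weight_changes_do_not_affect_output(self, rng):
        m, q = 6, 2
        A = (rng.uniform(size=(m, q)) < 0.5).astype(float)
        A[0, 0] = 1.0  # keep at least one live connection
        layer = SparsePathwayLayer(A, rng)
        x = rng.standard_normal((3, m))
        base = layer(Tensor(x)).data.copy()
        layer.W.data = layer.W.data + (1 - A) * 100.0
        assert np.array_equal(layer(Tensor(x)).data, base)


class TestMaskConstraint:
    def test_all_ones_identity(self, rng):
        W = rng.standard_normal((3, 2))
        assert np.array_equal(apply_mask_constraint(W, np.ones((3, 2))), W)

    def test_elementwise(self):
        out = apply_mask_constraint([[1.0, 2.0], [3.0, 4.0]],
                                    [[1.0, 0.0], [0.0, 1.0]])
        assert out.tolist() == [[1.0, 0.0], [0.0, 4.0]]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_mask_constraint(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_masked_weights_exactly_zero_after_optimizer_steps(self, rng):
        m, q = 8, 3
        A = (rng.uniform(size=(m, q)) < 0.5).astype(float)
        A[:, A.sum(axis=0) == 0] = 1.0
        layer = SparsePathwayLayer(A, rng)
        opt = Adam(layer.parameters(), lr=1e-2,
                   constraints=layer.constraints())
        x = rng.standard_normal((10, m))
        target = rng.standard_normal((10, q))
        for _ in range(100):
            layer.zero_grad()
            loss = ((layer(Tensor(x)) - Tensor(target)) ** 2).mean()
            loss.backward()
            opt.step()
        assert np.all(layer.W.data[A == 0] == 0.0)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

class TestScaledDotAttention:
    def test_zero_queries_average_values(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 3)), V)
        assert np.allclose(out, 0.5)

    def test_single_key_returns_value(self, rng):
        Q = rng.standard_normal((1, 4))
        K = rng.standard_normal((1, 4))
        V = rng.standard_normal((1, 5))
        assert np.allclose(scaled_dot_attention(Q, K, V), V)

    def test_matches_direct_matrix_evaluation(self, rng):
        Q, K = rng.standard_normal((3, 2)), rng.standard_normal((4, 2))
        V = rng.standard_normal((4, 5))
        scores = Q @ K.T / np.sqrt(2)
        weights = np.exp(scores) / np.exp(scores).sum(axis=1, keepdims=True)
        assert np.allclose(scaled_dot_attention(Q, K, V), weights @ V)

    def test_rows_sum_to_one_and_convex_hull(self, rng):
        Q, K = rng.standard_normal((5, 3)), rng.standard_normal((6, 3))
        V = rng.standard_normal((6, 2))
        out = scaled_dot_attention(Q, K, V)
        assert np.all(out.min(axis=0) >= V.min(axis=0) - 1e-9)
        assert np.all(out.max(axis=0) <= V.max(axis=0) + 1e-9)

    def test_dim_mismatch_errors(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)),
                                 np.zeros((2, 2)))


class TestMultiHeadAttention:
    def test_single_head_identity_projections_reduce(self, rng):
        d = 3
        Q, K = rng.standard_normal((4, d)), rng.standard_normal((5, d))
        V = rng.standard_normal((5, d))
        out = multi_head_attention(Q, K, V, [np.eye(d)], [np.eye(d)],
                                   [np.eye(d)], np.eye(d))
        assert np.allclose(out, scaled_dot_attention(Q, K, V))

    def test_swapping_query_modality_changes_output(self, rng):
        attn = MultiHeadAttention(4, 2, rng)
        a = Tensor(rng.standard_normal((1, 2, 4)))
        b = Tensor(rng.standard_normal((1, 2, 4)))
        out_ab = attn(a, b, b).data
        out_ba = attn(b, a, a).data
        assert not np.allclose(out_ab, out_ba)

    def test_duplicated_heads_with_averaging_output_projection(self, rng):
        # two identical heads + averaging W^O reproduce the single head
        d = 3
        Wq, Wk, Wv = (rng.standard_normal((d, d)) for _ in range(3))
        Q, K = rng.standard_normal((4, d)), rng.standard_normal((5, d))
        V = rng.standard_normal((5, d))
        single = multi_head_attention(Q, K, V, [Wq], [Wk], [Wv], np.eye(d))
        Wo = np.vstack([np.eye(d) * 0.5, np.eye(d) * 0.5])
        double = multi_head_attention(Q, K, V, [Wq, Wq], [Wk, Wk],
                                      [Wv, Wv], Wo)
        assert np.allclose(double, single)


# ---------------------------------------------------------------------------
# latent primitives
# ---------------------------------------------------------------------------

class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        assert np.allclose(reparameterize([1.0, 2.0], [0.5, 2.0],
                                          [0.0, 0.0]), [1.0, 2.0])

    def test_standard_normal_passthrough(self, rng):
        noise = rng.standard_normal(4)
        assert np.allclose(reparameterize(np.zeros(4), np.ones(4), noise),
                           noise)

    def test_elementwise_arithmetic(self):
        z = reparameterize([1.0, 2.0], [2.0, 3.0], [1.0, -1.0])
        assert z.tolist() == [3.0, -1.0]

    def test_nonpositive_sigma_errors(self):
        with pytest.raises(ValueError):
            reparameterize([0.0], [0.0], [1.0])


class TestKLGaussian:
    def test_prior_equals_posterior_is_zero(self):
        assert kl_gaussian(np.zeros(3), np.ones(3)) == pytest.approx(0.0)

    def test_closed_form_unit_mean(self):
        assert kl_gaussian(np.array([1.0]), np.array([1.0])) == \
            pytest.approx(0.5)

    def test_nonnegative_everywhere(self, rng):
        for _ in range(20):
            mu = rng.standard_normal(4)
            sigma = rng.uniform(0.2, 3.0, 4)
            assert kl_gaussian(mu, sigma) >= 0.0


class TestCapacityRegularizer:
    def test_zero_at_zero_capacity_zero_kl(self):
        assert capacity_regularizer(0.0, 0, CapacitySchedule()) == 0.0

    def test_zero_when_kl_meets_capacity(self):
        sched = CapacitySchedule()
        assert capacity_regularizer(25.0, int(1e5), sched) == \
            pytest.approx(0.0)

    def test_plug_in_arithmetic(self):
        sched = CapacitySchedule()
        # C(5e4) = 12.5; 0.005 * 1000 * |14.5 - 12.5| = 10
        assert capacity_regularizer(14.5, 50000, sched) == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def brute_force_cox(pi, time, event):
    """Risk-set enumeration without log-sum-exp (oracle)."""
    total = 0.0
    for i in range(len(pi)):
        if event[i] == 1:
            denom = sum(np.exp(pi[j]) for j in range(len(pi))
                        if time[j] >= time[i])
            total += pi[i] - np.log(denom)
    return -total


class TestCoxLoss:
    def test_two_sample_hand_case(self):
        labels = SurvivalLabels([1.0, 2.0], [1, 1])
        loss = cox_neg_log_partial_likelihood(np.zeros(2), labels)
        assert loss == pytest.approx(np.log(2.0), abs=1e-12)

    def test_single_event_is_zero(self):
        labels = SurvivalLabels([4.0], [1])
        assert cox_neg_log_partial_likelihood(np.array([1.7]), labels) == \
            pytest.approx(0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-5, 5))
    def test_location_invariance(self, shift):
        labels = SurvivalLabels([3.0, 1.0, 4.0, 2.0], [1, 1, 0, 1])
        pi = np.array([0.3, -1.2, 0.8, 0.1])
        base = cox_neg_log_partial_likelihood(pi, labels)
        shifted = cox_neg_log_partial_likelihood(pi + shift, labels)
        assert shifted == pytest.approx(base, abs=1e-8)

    def test_matches_brute_force_on_random_instances_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 21))
            time = rng.integers(1, 8, n).astype(float)  # ties guaranteed
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            pi = rng.standard_normal(n) * 2
            labels = SurvivalLabels(time, event)
            mine = cox_neg_log_partial_likelihood(pi, labels)
            assert mine == pytest.approx(brute_force_cox(pi, time, event),
                                         abs=1e-8)
            tensor = cox_loss_t(Tensor(pi), labels)
            assert float(tensor.data) == pytest.approx(mine, abs=1e-8)

    def test_matches_lifelines_partial_likelihood(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        n = 60
        x = rng.standard_normal(n)
        time = rng.exponential(10, n) + rng.uniform(0, 1e-4, n)  # untied
        event = (rng.uniform(size=n) > 0.25).astype(int)
        df = pd.DataFrame({"x": x, "T": time, "E": event})
        cph = CoxPHFitter().fit(df, "T", "E")
        pi = x * cph.params_["x"]
        labels = SurvivalLabels(time, event)
        assert cox_neg_log_partial_likelihood(pi, labels) == \
            pytest.approx(-cph.log_likelihood_, rel=1e-6)

    def test_gradient_sums_to_zero(self, rng):
        # score identity of the partial likelihood
        n = 15
        labels = SurvivalLabels(rng.exponential(5, n) + 0.01,
                                rng.integers(0, 2, n))
        if labels.event.sum() == 0:
            labels.event[0] = 1
        pi = Tensor(rng.standard_normal(n), requires_grad=True)
        cox_loss_t(pi, labels).backward()
        assert abs(pi.grad.sum()) < 1e-10

    def test_no_events_errors(self):
        labels = SurvivalLabels([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError):
            cox_neg_log_partial_likelihood(np.zeros(2), labels)

    def test_nonfinite_scores_error(self):
        labels = SurvivalLabels([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            cox_neg_log_partial_likelihood(np.array([np.inf, 0.0]), labels)


# ---------------------------------------------------------------------------
# simple terms
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,xhat,expected", [
    ([1.0, 2.0], [1.0, 2.0], 0.0),
    ([0.0, 0.0], [1.0, 1.0], 1.0),
    ([1.0, 2.0, 3.0], [1.0, 1.0, 5.0], 5.0 / 3.0),
])
def test_mse_loss_values(x, xhat, expected):
    assert mse_loss(x, xhat) == pytest.approx(expected)


def test_mse_shape_mismatch():
    with pytest.raises(ValueError):
        mse_loss([1.0], [1.0, 2.0])


@pytest.mark.parametrize("weights,lam,expected", [
    ([np.array([1.0, 2.0])], 0.0, 0.0),
    ([np.array([1.0, -2.0])], 1.0, 5.0),
    ([np.array([0.5, 0.5, 0.5])], 2.0, 1.5),
])
def test_l2_penalty_values(weights, lam, expected):
    assert l2_penalty(weights, lam) == pytest.approx(expected)
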