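"""Prototype-expanded head: expansion, margins, loss, gradients."""

import math

import numpy as np
import pytest

from veinfed.head import (
    MarginParams,
    expand_weight_matrix,
    init_weight_matrix,
    loss_and_grads,
    margins_from_quality,
    prototype_margin_loss,
    similarity,
    target_logit,
)


def _unit_rows(rng, n, d):
    e = rng.normal(size=(n, d))
    return e / np.linalg.norm(e, axis=1, keepdims=True)


def _random_instance(rng, d=8, n_local=4, n_proto=3, batch=5, scale=16.0):
    w = init_weight_matrix(rng, d, n_local)
    blocks = []
    if n_proto:
        blocks = [(0, init_weight_matrix(rng, d, n_proto),
                   list(range(100, 100 + n_proto)))]
    exp = expand_weight_matrix(w, list(range(n_local)), 1, blocks)
    emb = _unit_rows(rng, batch, d)
    labels = rng.integers(0, n_local, batch)
    q_hat = rng.uniform(-0.9, 0.9, batch)
    params = MarginParams(margin=0.4, scale=scale)
    return exp, emb, labels, q_hat, params


def _oracle_loss(exp, emb, labels, q_hat, params):
    """Independent scalar-loop log-sum-exp cross-entropy oracle."""
    wn = exp.matrix()
    total = 0.0
    for i in range(emb.shape[0]):
        y = exp.label_to_column(np.array([labels[i]]))[0]
        logits = []
        for j in range(wn.shape[1]):
            cos = float(emb[i] @ wn[:, j])
            if j == y:
                theta = math.acos(max(-1 + 1e-7, min(1 - 1e-7, cos)))
                g_angle = -params.margin * q_hat[i]
                g_add = params.margin * q_hat[i] + params.margin
                ang = min(math.pi, max(0.0, theta + g_angle))
                logits.append(params.scale * (math.cos(ang) - g_add))
            elif (not exp.is_local[j]) and exp.col_label[j] == labels[i]:
                continue  # own-class prototype column excluded
            else:
                logits.append(params.scale * cos)
        m = max(logits)
        lse = m + math.log(sum(math.exp(v - m) for v in logits))
        y_logit = None
        # recompute the target logit position: it is the first appended
        # entry at index of y among kept columns
        kept = [j for j in range(wn.shape[1])
                if not ((not exp.is_local[j]) and exp.col_label[j] == labels[i])]
        y_logit = logits[kept.index(y)]
        total += lse - y_logit
    return total / emb.shape[0]


class TestExpandWeightMatrix:
    def test_single_client_reduction(self):
        rng = np.random.default_rng(0)
        w = init_weight_matrix(rng, 8, 5)
        exp = expand_weight_matrix(w, list(range(5)), 0, [])
        np.testing.assert_array_equal(exp.matrix().shape, (8, 5))
        assert exp.is_local.all()
        np.testing.assert_allclose(
            exp.matrix(), w / np.linalg.norm(w, axis=0, keepdims=True)
        )

    def test_block_order_and_trainable_flags(self):
        rng = np.random.default_rng(1)
        d = 6
        w = init_weight_matrix(rng, d, 5)  # client 1, width 5
        p0 = init_weight_matrix(rng, d, 3)
        p2 = init_weight_matrix(rng, d, 2)
        exp = expand_weight_matrix(
            w, [10, 11, 12, 13, 14], 1,
            [(2, p2, [30, 31]), (0, p0, [20, 21, 22])],
        )
        assert exp.n_columns == 10
        np.testing.assert_array_equal(exp.col_client[:3], 0)
        np.testing.assert_array_equal(exp.col_client[3:8], 1)
        np.testing.assert_array_equal(exp.col_client[8:], 2)
        assert exp.local_start == 3
        assert exp.is_local[3:8].all() and not exp.is_local[:3].any()
        np.testing.assert_array_equal(exp.matrix()[:, :3], p0)
        np.testing.assert_array_equal(exp.matrix()[:, 8:], p2)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        w = init_weight_matrix(rng, 8, 3)
        bad = init_weight_matrix(rng, 6, 2)
        with pytest.raises(ValueError, match="row dim"):
            expand_weight_matrix(w, [0, 1, 2], 1, [(0, bad, [5, 6])])

    def test_duplicate_key_rejected(self):
        rng = np.random.default_rng(3)
        w = init_weight_matrix(rng, 8, 2)
        p = init_weight_matrix(rng, 8, 2)
        with pytest.raises(ValueError, match="duplicate"):
            expand_weight_matrix(w, [0, 1], 1, [(0, p, [5, 5])])


class TestSimilarity:
    def test_identity_orthogonal_and_range(self):
        rng = np.random.default_rng(4)
        d = 8
        w = np.eye(d)[:, :3]
        exp = expand_weight_matrix(w, [0, 1, 2], 0, [])
        emb = np.zeros((2, d))
        emb[0, 0] = 1.0  # equals column 0
        emb[1, 3] = 1.0  # orthogonal to all columns
        s = similarity(emb, exp)
        assert s[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(s[1], 0.0, atol=1e-12)
        e4 = _unit_rows(rng, 4, d)
        exp10 = expand_weight_matrix(init_weight_matrix(rng, d, 10),
                                     list(range(10)), 0, [])
        s4 = similarity(e4, exp10)
        assert s4.shape == (4, 10)
        assert (np.abs(s4) <= 1 + 1e-12).all()


class TestMargins:
    @pytest.mark.parametrize(
        "q_hat,expected",
        [(0.0, (0.0, 0.4)), (-1.0, (0.4, 0.0)), (1.0, (-0.4, 0.8))],
    )
    def test_quality_to_margin_map(self, q_hat, expected):
        g_angle, g_add = margins_from_quality(q_hat, 0.4)
        assert (g_angle, g_add) == pytest.approx(expected)

    def test_target_logit_neutral_quality(self):
        p = MarginParams(margin=0.4, scale=64.0)
        assert target_logit(0.9, 0.0, p) == pytest.approx(64 * (0.9 - 0.4))

    def test_zero_margin_is_plain_scaled_cosine(self):
        p = MarginParams(margin=0.0, scale=32.0)
        for cos in [-0.7, 0.0, 0.9]:
            assert target_logit(cos, 0.3, p) == pytest.approx(32 * cos, abs=1e-5)

    def test_pure_angular_margin_case(self):
        # Q-hat = -1: g_angle = m, g_add = 0 -> s cos(theta + m)
        p = MarginParams(margin=0.4, scale=16.0)
        theta = math.radians(60)
        expected = 16.0 * math.cos(theta + 0.4)
        assert target_logit(math.cos(theta), -1.0, p) == pytest.approx(expected)

    def test_literal_form_switch(self):
        p = MarginParams(margin=0.4, scale=10.0, literal_form=True)
        # affine reading: s * (cos + g_angle - g_add)
        assert target_logit(0.5, 0.5, p) == pytest.approx(
            10 * (0.5 + (-0.2) - 0.6)
        )


class TestLoss:
    def test_single_column_loss_is_zero(self):
        rng = np.random.default_rng(5)
        w = init_weight_matrix(rng, 8, 1)
        exp = expand_weight_matrix(w, [3], 0, [])
        emb = _unit_rows(rng, 2, 8)
        loss, _ = prototype_margin_loss(
            similarity(emb, exp), exp.label_to_column(np.array([3, 3])),
            np.zeros(2), MarginParams(), exp,
        )
        assert loss == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        exp, emb, labels, q_hat, params = _random_instance(
            rng, n_local=rng.integers(2, 6), n_proto=rng.integers(0, 5),
            batch=rng.integers(1, 8),
        )
        loss, _ = prototype_margin_loss(
            similarity(emb, exp), exp.label_to_column(labels), q_hat, params,
            exp,
        )
        assert loss == pytest.approx(_oracle_loss(exp, emb, labels, q_hat,
                                                  params), rel=1e-9)

    def test_empty_prototype_set_reduces_to_plain_margin_loss(self):
        rng = np.random.default_rng(7)
        exp_p, emb, labels, q_hat, params = _random_instance(rng, n_proto=0)
        exp_same = expand_weight_matrix(
            exp_p.w_local, exp_p.local_labels, 1, []
        )
        a, _ = prototype_margin_loss(similarity(emb, exp_p),
                                     exp_p.label_to_column(labels), q_hat,
                                     params, exp_p)
        b, _ = prototype_margin_loss(similarity(emb, exp_same),
                                     exp_same.label_to_column(labels), q_hat,
                                     params, exp_same)
        assert a == pytest.approx(b)

    def test_adding_prototype_column_never_decreases_loss(self):
        rng = np.random.default_rng(8)
        w = init_weight_matrix(rng, 8, 4)
        emb = _unit_rows(rng, 5, 8)
        labels = np.array([0, 1, 2, 3, 0])
        q = np.zeros(5)
        params = MarginParams(margin=0.4, scale=16.0)
        base = expand_weight_matrix(w, [0, 1, 2, 3], 1, [])
        grown = expand_weight_matrix(
            w, [0, 1, 2, 3], 1, [(0, init_weight_matrix(rng, 8, 1), [99])]
        )
        l0, _ = prototype_margin_loss(similarity(emb, base),
                                      base.label_to_column(labels), q, params,
                                      base)
        l1, _ = prototype_margin_loss(similarity(emb, grown),
                                      grown.label_to_column(labels), q, params,
                                      grown)
        assert l1 >= l0

    def test_monotone_in_target_cosine(self):
        rng = np.random.default_rng(9)
        exp, emb, labels, q_hat, params = _random_instance(rng, batch=1)
        y = exp.label_to_column(labels)[0]
        sim = similarity(emb, exp)
        losses = []
        for cos_y in np.linspace(-0.8, 0.8, 9):
            s = sim.copy()
            s[0, y] = cos_y
            losses.append(
                prototype_margin_loss(s, np.array([y]), q_hat[:1], params,
                                      exp)[0]
            )
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_loss_nonnegative_and_positive_with_competition(self):
        rng = np.random.default_rng(10)
        exp, emb, labels, q_hat, params = _random_instance(rng)
        loss, _ = prototype_margin_loss(similarity(emb, exp),
                                        exp.label_to_column(labels),
                                        np.zeros_like(q_hat),
                                        MarginParams(margin=0.0, scale=16.0),
                                        exp)
        assert loss > 0.0

    def test_prototype_target_rejected(self):
        rng = np.random.default_rng(11)
        exp, emb, labels, q_hat, params = _random_instance(rng)
        proto_col = int(np.nonzero(~exp.is_local)[0][0])
        with pytest.raises(ValueError, match="prototype column"):
            prototype_margin_loss(similarity(emb, exp),
                                  np.array([proto_col] * len(labels)), q_hat,
                                  params, exp)

    def test_out_of_range_quality_rejected(self):
        rng = np.random.default_rng(12)
        exp, emb, labels, q_hat, params = _random_instance(rng)
        with pytest.raises(ValueError, match="q_hat"):
            prototype_margin_loss(similarity(emb, exp),
                                  exp.label_to_column(labels),
                                  np.full_like(q_hat, 1.5), params, exp)


class TestGradients:
    @pytest.mark.parametrize("seed", range(4))
    def test_analytic_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        exp, emb, labels, q_hat, params = _random_instance(rng, d=6,
                                                           batch=3)
        targets = exp.label_to_column(labels)
        loss, d_emb, d_w = loss_and_grads(emb, exp, targets, q_hat, params)

        def loss_of(e, w):
            ex = expand_weight_matrix(w, exp.local_labels, exp.client_id,
                                      [(0, exp.proto_cols,
                                        [int(l) for l in
                                         exp.col_label[~exp.is_local]])]
                                      if exp.proto_cols.shape[1] else [])
            return prototype_margin_loss(similarity(e, ex), targets, q_hat,
                                         params, ex, return_grad=False)[0]

        eps = 1e-6
        for i in range(emb.shape[0]):
            for j in range(emb.shape[1]):
                ep, em = emb.copy(), emb.copy()
                ep[i, j] += eps
                em[i, j] -= eps
                num = (loss_of(ep, exp.w_local) - loss_of(em, exp.w_local)) / (2 * eps)
                assert abs(num - d_emb[i, j]) / max(1e-4, abs(num)) < 1e-4
        w = exp.w_local
        for i in range(w.shape[0]):
            for j in range(w.shape[1]):
                wp, wm = w.copy(), w.copy()
                wp[i, j] += eps
                wm[i, j] -= eps
                num = (loss_of(emb, wp) - loss_of(emb, wm)) / (2 * eps)
                assert abs(num - d_w[i, j]) / max(1e-4, abs(num)) < 1e-4

    def test_frozen_prototype_columns_receive_no_update(self):
        rng = np.random.default_rng(3)
        exp, emb, labels, q_hat, params = _random_instance(rng)
        before = exp.proto_cols.copy()
        loss_and_grads(emb, exp, exp.label_to_column(labels), q_hat, params)
        np.testing.assert_array_equal(exp.proto_cols, before)
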