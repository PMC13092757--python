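"""Graph attention, fusion, alignment loss, focal loss and pair scoring."""

import numpy as np
import pytest

from drpgraph.autodiff import Parameter, Tensor
from drpgraph.objective import (GATEncoder, GATHead, PairScorer,
                                alignment_loss, attention_mask, focal_loss,
                                fuse_embeddings, fuse_views, gat_encode,
                                score_pairs, std_anchor, total_loss)

from conftest import finite_difference


def brute_force_gat_layer(feats, mask, heads, combine):
    """Per-node softmax/weighted-sum evaluation, one neighbour at a time."""
    n = feats.shape[0]
    outs = []
    for head in heads:
        w = head.weight.data
        a_src = head.att_src.data.ravel()
        a_dst = head.att_dst.data.ravel()
        wt = feats @ w
        out = np.zeros_like(wt)
        for i in range(n):
            nbrs = [j for j in range(n) if mask[i, j]]
            logits = []
            for j in nbrs:
                e = a_src @ wt[i] + a_dst @ wt[j]
                logits.append(e if e > 0 else 0.2 * e)
            logits = np.array(logits)
            alpha = np.exp(logits - logits.max())
            alpha /= alpha.sum()
            out[i] = sum(a * wt[j] for a, j in zip(alpha, nbrs))
        outs.append(out)
    if combine == "concat":
        return np.concatenate([np.maximum(o, 0.0) for o in outs], axis=1)
    return np.maximum(np.mean(outs, axis=0), 0.0)


class TestGAT:
    def test_isolated_node_attends_only_to_itself(self):
        rng = np.random.default_rng(0)
        head = GATHead(4, 4, rng)
        feats = Tensor(rng.standard_normal((3, 4)))
        mask = np.eye(3, dtype=bool)
        alpha, wt = head.attention(feats, mask)
        np.testing.assert_allclose(np.diag(alpha.data), 1.0)
        np.testing.assert_allclose(head(feats, mask).data, wt.data)

    def test_identical_neighbours_share_attention_equally(self):
        rng = np.random.default_rng(1)
        head = GATHead(3, 3, rng)
        feats = np.zeros((3, 3))
        feats[1] = feats[2] = rng.standard_normal(3)  # two identical neighbours
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 1] = mask[0, 2] = True  # node 0 attends only to them
        mask[1, 1] = mask[2, 2] = True
        alpha, _ = head.attention(Tensor(feats), mask)
        assert alpha.data[0, 1] == pytest.approx(0.5)
        assert alpha.data[0, 2] == pytest.approx(0.5)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        enc = GATEncoder(6, 3, rng)
        feats = Tensor(rng.standard_normal((7, 6)))
        mask = attention_mask([rng.random((7, 7)) < 0.3], 7)
        for layer in (enc.hidden, enc.out):
            for head in layer.heads:
                alpha, _ = head.attention(feats, mask)
                np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, k, seed):
        rng = np.random.default_rng(seed)
        f = 6
        enc = GATEncoder(f, k, rng)
        feats = rng.standard_normal((6, f))
        adj = (rng.random((6, 6)) < 0.4).astype(float)
        mask = attention_mask([adj], 6)
        hidden = brute_force_gat_layer(feats, mask, enc.hidden.heads, "concat")
        expected = brute_force_gat_layer(hidden, mask, enc.out.heads, "mean")
        got = gat_encode(feats, adj, enc)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_gradients_flow_through_attention(self):
        rng = np.random.default_rng(3)
        enc = GATEncoder(4, 2, rng)
        feats = Tensor(rng.standard_normal((5, 4)))
        mask = attention_mask([rng.random((5, 5)) < 0.5], 5)

        def loss():
            return enc(feats, mask).pow(2.0).mean()

        for p in enc.parameters():
            p.grad = None
        loss().backward()
        numeric = finite_difference(lambda: loss().data.item(), enc.parameters())
        for p, num in zip(enc.parameters(), numeric):
            np.testing.assert_allclose(p.grad, num, rtol=1e-4, atol=1e-6)


class TestFusion:
    def test_all_ones_h_returns_t(self):
        t = np.random.default_rng(0).standard_normal((4, 3))
        np.testing.assert_array_equal(fuse_embeddings(t, np.ones((4, 3))).data, t)

    def test_two_identical_views_mean_equals_either(self):
        rng = np.random.default_rng(1)
        t = Tensor(rng.standard_normal((4, 3)))
        h = Tensor(rng.standard_normal((4, 3)))
        x1, x2, x = fuse_views(t, t, h)
        np.testing.assert_allclose(x.data, x1.data)

    def test_elementwise_product_example(self):
        x = fuse_embeddings(np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]))
        np.testing.assert_array_equal(x.data, [[3.0, 8.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_embeddings(np.zeros((2, 3)), np.zeros((3, 2)))


class TestAlignmentLoss:
    def test_zero_when_views_identical_and_stds_on_anchor(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 4))
        x = (x - x.mean(axis=0)) / x.std(axis=0)  # per-dim std exactly 1
        loss = alignment_loss(x, x.copy(), phi_target=1.0)
        assert abs(loss.data.item()) < 1e-9

    def test_omega1_scales_distance_term_linearly(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.standard_normal((6, 4)), rng.standard_normal((6, 4))
        base = alignment_loss(x1, x2, phi_target=1.0, omega1=1.0, omega2=0.0)
        doubled = alignment_loss(x1, x2, phi_target=1.0, omega1=2.0, omega2=0.0)
        assert doubled.data.item() == pytest.approx(2 * base.data.item())

    def test_hand_computed_value_on_3x2_fixture(self):
        x1 = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        x2 = np.array([[1.0, 1.0], [2.0, 4.0], [5.0, 8.0]])
        phi = 1.0
        dist = np.mean(np.linalg.norm(x1 - x2, axis=1))
        s1, s2 = x1.std(axis=0), x2.std(axis=0)
        expected = dist + np.sum((s1 - phi) ** 2) + np.sum((s2 - phi) ** 2)
        got = alignment_loss(x1, x2, phi_target=phi).data.item()
        assert got == pytest.approx(expected, abs=1e-6)

    def test_invariant_to_common_row_permutation(self):
        rng = np.random.default_rng(2)
        x1, x2 = rng.standard_normal((8, 3)), rng.standard_normal((8, 3))
        perm = rng.permutation(8)
        a = alignment_loss(x1, x2, phi_target=0.8).data.item()
        b = alignment_loss(x1[perm], x2[perm], phi_target=0.8).data.item()
        assert a == pytest.approx(b)

    def test_std_anchor_is_mean_of_per_dim_stds(self):
        h = np.random.default_rng(3).standard_normal((20, 5))
        assert std_anchor(h) == pytest.approx(h.std(axis=0).mean())


class TestFocalLoss:
    def test_gamma_zero_alpha_one_is_cross_entropy(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=1000)
        y = (rng.random(1000) < 0.3).astype(float)
        fl = focal_loss(p, y, alpha_t=1.0, gamma=0.0).data.item()
        ce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert fl == pytest.approx(ce, abs=1e-9)

    def test_closed_form_single_sample(self):
        val = focal_loss(np.array([0.5]), np.array([1.0]),
                         alpha_t=0.25, gamma=2.0).data.item()
        assert val == pytest.approx(0.25 * 0.25 * np.log(2), abs=1e-9)

    def test_confident_correct_prediction_vanishes(self):
        val = focal_loss(np.array([1.0 - 1e-9]), np.array([1.0])).data.item()
        assert val < 1e-6

    def test_boundary_probabilities_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            val = focal_loss(np.array([1.0]), np.array([0.0])).data.item()
        assert np.isfinite(val)


class TestTotalLoss:
    def test_sum_examples(self):
        assert total_loss(Tensor(0.0), Tensor(0.0)).data.item() == 0.0
        assert total_loss(Tensor(0.5), Tensor(0.25)).data.item() == 0.75

    def test_nonfinite_term_identified(self):
        with pytest.raises(ValueError, match="L2"):
            total_loss(Tensor(1.0), Tensor(np.nan))
        with pytest.raises(ValueError, match="L1"):
            total_loss(Tensor(np.inf), Tensor(1.0))

    def test_gradient_is_sum_of_per_term_gradients(self):
        rng = np.random.default_rng(4)
        w = Parameter(rng.standard_normal((2, 2)))
        x1 = Tensor(rng.standard_normal((2, 2)))
        x2 = Tensor(rng.standard_normal((2, 2)))
        y = np.array([1.0, 0.0])

        def l1():
            return alignment_loss(x1 @ w, x2 @ w, phi_target=1.0)

        def l2():
            return focal_loss((x1 @ w).mean(axis=1).sigmoid(), y)

        w.grad = None
        total_loss(l1(), l2()).backward()
        g_total = w.grad.copy()
        w.grad = None
        l1().backward()
        g1 = w.grad.copy()
        w.grad = None
        l2().backward()
        g2 = w.grad.copy()
        np.testing.assert_allclose(g_total, g1 + g2, atol=1e-12)
        numeric = finite_difference(
            lambda: total_loss(l1(), l2()).data.item(), [w])[0]
        np.testing.assert_allclose(g_total, numeric, rtol=1e-4, atol=1e-6)


class TestPairScorer:
    def test_scores_bounded_and_deterministic(self):
        rng = np.random.default_rng(0)
        scorer = PairScorer(4, rng)
        x = rng.standard_normal((6, 4))
        pairs = [(0, 3), (1, 4), (0, 3)]
        p = score_pairs(x, pairs, scorer)
        assert np.all((p > 0) & (p < 1))
        assert p[0] == p[2]  # identical query, identical score

    def test_unknown_node_rejected(self):
        scorer = PairScorer(4, np.random.default_rng(1))
        with pytest.raises(IndexError):
            score_pairs(np.zeros((3, 4)), [(0, 99)], scorer)
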