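"""Gated attention, pooling, evidence selection, losses, and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammil import model as M


def scalar_gated_attention(Hp, V, U, w):
    """Independent scalar-loop evaluation of the gated attention weights."""
    K = Hp.shape[0]
    raw = np.zeros(K)
    for k in range(K):
        gate = np.zeros(V.shape[0])
        for l in range(V.shape[0]):
            t = np.tanh(sum(V[l, m] * Hp[k, m] for m in range(Hp.shape[1])))
            s = 1.0 / (1.0 + np.exp(-sum(U[l, m] * Hp[k, m] for m in range(Hp.shape[1]))))
            gate[l] = t * s
        raw[k] = sum(w[l] * gate[l] for l in range(V.shape[0]))
    e = np.exp(raw - raw.max())
    return raw, e / e.sum()


class TestGatedAttention:
    def test_singleton_bag(self):
        st_ = M.gated_attention(np.array([[1.0, 2.0]]), np.eye(2), np.eye(2), np.ones(2))
        assert st_.a == pytest.approx([1.0])

    def test_identical_rows_uniform_weights(self):
        Hp = np.tile([[0.3, -0.7, 1.1]], (5, 1))
        rng = np.random.default_rng(0)
        st_ = M.gated_attention(Hp, rng.normal(size=(4, 3)), rng.normal(size=(4, 3)),
                                rng.normal(size=4))
        np.testing.assert_allclose(st_.a, np.full(5, 0.2), atol=1e-12)

    def test_scalar_worked_example(self):
        # L = M' = 1, w = 1, V = 1, U = 10, patches h = (2, 0)
        st_ = M.gated_attention(np.array([[2.0], [0.0]]), np.array([[1.0]]),
                                np.array([[10.0]]), np.array([1.0]))
        raw0 = np.tanh(2.0) / (1.0 + np.exp(-20.0))
        assert st_.raw_scores == pytest.approx([raw0, 0.0], abs=1e-4)
        assert st_.a == pytest.approx([0.7239, 0.2761], abs=1e-4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        K=st.integers(1, 5), L=st.integers(1, 4), Mp=st.integers(1, 4),
        seed=st.integers(0, 10_000),
    )
    def test_matches_scalar_loop(self, K, L, Mp, seed):
        rng = np.random.default_rng(seed)
        Hp = rng.normal(size=(K, Mp))
        V, U, w = rng.normal(size=(L, Mp)), rng.normal(size=(L, Mp)), rng.normal(size=L)
        st_ = M.gated_attention(Hp, V, U, w)
        raw, a = scalar_gated_attention(Hp, V, U, w)
        np.testing.assert_allclose(st_.raw_scores, raw, atol=1e-6)
        np.testing.assert_allclose(st_.a, a, atol=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(K=st.integers(1, 50), seed=st.integers(0, 10_000))
    def test_weights_are_probability_vector(self, K, seed):
        rng = np.random.default_rng(seed)
        st_ = M.gated_attention(rng.normal(size=(K, 3)), rng.normal(size=(4, 3)),
                                rng.normal(size=(4, 3)), rng.normal(size=4))
        assert st_.a.min() >= 0
        assert st_.a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_softmax_shift_invariance(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=8)
        a1 = M._softmax(raw)
        a2 = M._softmax(raw + 123.456)
        np.testing.assert_allclose(a1, a2, atol=1e-12)


class TestPooling:
    def test_one_hot_selects_row(self):
        Hp = np.arange(12.0).reshape(4, 3)
        a = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_allclose(M.pool_bag(a, Hp), Hp[2])

    def test_uniform_is_row_mean(self):
        Hp = np.random.default_rng(0).normal(size=(6, 4))
        np.testing.assert_allclose(M.pool_bag(np.full(6, 1 / 6), Hp), Hp.mean(axis=0))

    def test_linear_combination_arithmetic(self):
        Hp = np.zeros((2, 4))
        Hp[0, 0], Hp[1, 1] = 3.0, 3.0
        np.testing.assert_allclose(M.pool_bag([2 / 3, 1 / 3], Hp), [2.0, 1.0, 0.0, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(K=st.integers(2, 20), seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, K, seed):
        rng = np.random.default_rng(seed)
        Hp, a = rng.normal(size=(K, 5)), rng.dirichlet(np.ones(K))
        perm = rng.permutation(K)
        np.testing.assert_allclose(M.pool_bag(a, Hp), M.pool_bag(a[perm], Hp[perm]),
                                   atol=1e-12)


class TestReduceAndClassify:
    def test_reduction_shape_and_rectification(self):
        rng = np.random.default_rng(0)
        H = rng.normal(size=(3, 8))
        out = M.reduce_features(H, rng.normal(size=(8, 16)), np.zeros(16))
        assert out.shape == (3, 16) and (out >= 0).all()
        assert M.reduce_features(H[:1], np.zeros((8, 16)), np.zeros(16)).sum() == 0.0

    def test_zero_classifier_outputs_half(self):
        p = M.init_params(4, 8, 8, 8, seed=0)
        p.Wb1[:], p.bb1[:], p.wb2[:], p.bb2[:] = 0, 0, 0, 0
        assert M.classify_bag(np.ones(8), p) == pytest.approx(0.5)

    @pytest.mark.parametrize("score,expected", [(0.7, 1), (0.3, 0), (0.5, 0)])
    def test_default_decision_rule_is_strict(self, score, expected):
        assert int(score > 0.5) == expected


class TestEvidenceSelection:
    def test_full_partition_at_k8_K16(self):
        scores = np.random.default_rng(0).normal(size=16)
        ev = M.select_evidence(scores, k=8)
        assert sorted(ev.indices.tolist()) == list(range(16))
        assert set(ev.positive_idx) & set(ev.negative_idx) == set()

    def test_small_bag_clamps_to_half(self):
        ev = M.select_evidence(np.arange(10.0), k=8)
        assert ev.k_eff == 5
        assert sorted(ev.positive_idx) == [5, 6, 7, 8, 9]

    def test_argmax_argmin_example(self):
        ev = M.select_evidence(np.array([0.9, 0.8, 0.1, 0.05]), k=1)
        assert ev.positive_idx.tolist() == [0] and ev.negative_idx.tolist() == [3]

    def test_ties_break_to_lower_index(self):
        ev = M.select_evidence(np.array([0.5, 0.5, 0.1, 0.1]), k=1)
        assert ev.positive_idx.tolist() == [0] and ev.negative_idx.tolist() == [2]

    def test_singleton_bag_rejected(self):
        with pytest.raises(ValueError):
            M.select_evidence(np.array([1.0]), k=8)

    def test_pseudo_labels_are_cluster_memberships(self):
        ev = M.select_evidence(np.arange(6.0), k=2)
        assert ev.pseudo_labels.tolist() == [1, 1, 0, 0]


class TestLosses:
    def test_uniform_instance_classifier_gives_ln2(self):
        p = M.init_params(4, 8, 8, 8, seed=0)
        p.Wi1[:], p.bi1[:], p.Wi2[:], p.bi2[:] = 0, 0, 0, 0
        loss = M.instance_loss(np.ones((4, 8)), [1, 1, 0, 0], p)
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_mean_negative_log_probability(self):
        # direct evaluation: probabilities 0.9 and 0.8 on the correct class
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert expected == pytest.approx(0.1643, abs=1e-4)
        p = M.init_params(2, 2, 2, 2, seed=0)
        p.Wi1[:] = np.eye(2); p.bi1[:] = 0
        p.Wi2[:] = np.array([[0.0, 0.0], [0.0, 0.0]]); p.bi2[:] = 0
        # logits chosen so softmax gives exactly (0.9, 0.8) on the true class
        p.Wi2[0, 1] = np.log(0.9 / 0.1)
        p.Wi2[1, 0] = np.log(0.8 / 0.2)
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert M.instance_loss(X, [1, 0], p) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "bag,inst,expected", [(1.0, 0.0, 0.7), (0.0, 1.0, 0.3), (0.5, 0.2, 0.41)]
    )
    def test_total_loss_mixing(self, bag, inst, expected):
        assert M.total_loss(bag, inst) == pytest.approx(expected)

    def test_negative_losses_rejected(self):
        with pytest.raises(ValueError):
            M.total_loss(-0.1, 0.2)


class TestGradients:
    @pytest.mark.parametrize("y", [0, 1])
    def test_backward_matches_finite_differences(self, y):
        rng = np.random.default_rng(42)
        p = M.init_params(5, reduced_dim=7, attention_dim=6, hidden_dim=4, seed=1)
        H = rng.normal(size=(9, 5))
        out = M.forward_bag(p, H, y, k_evidence=2)
        grads = M.backward_bag(p, out["cache"])
        eps = 1e-6
        for name, arr in p.as_dict().items():
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                old = arr[ix]
                arr[ix] = old + eps
                lp = M.forward_bag(p, H, y, k_evidence=2)["loss"]
                arr[ix] = old - eps
                lm = M.forward_bag(p, H, y, k_evidence=2)["loss"]
                arr[ix] = old
                num[ix] = (lp - lm) / (2 * eps)
            scale = np.max(np.abs(num)) + 1e-12
            np.testing.assert_allclose(grads[name], num, atol=1e-6 * max(scale, 1.0),
                                       err_msg=name)

    def test_forward_is_deterministic_in_eval_mode(self):
        rng = np.random.default_rng(0)
        p = M.init_params(6, 8, 8, 8, seed=3)
        H = rng.normal(size=(20, 6))
        a = M.forward_bag(p, H, 1, k_evidence=3)
        b = M.forward_bag(p, H, 1, k_evidence=3)
        assert a["loss"] == b["loss"] and a["prob"] == b["prob"]

    def test_large_bag_attention_still_normalised(self):
        rng = np.random.default_rng(0)
        p = M.init_params(4, 8, 8, 8, seed=0)
        out = M.forward_bag(p, rng.normal(size=(10_000, 4)))
        assert out["a"].sum() == pytest.approx(1.0, abs=1e-6)


class TestCheckpoint:
    def test_round_trip_is_bit_exact(self, tmp_path):
        p = M.init_params(6, 12, 10, 8, seed=5)
        meta = {"extractor": "tiny-conv", "k_evidence": 8}
        norm = {"norm_mean": np.arange(6.0), "norm_std": np.ones(6)}
        M.save_checkpoint(tmp_path / "ckpt", p, meta, norm)
        q, meta2, norm2 = M.load_checkpoint(tmp_path / "ckpt")
        for name, arr in p.as_dict().items():
            assert np.array_equal(arr, getattr(q, name)), name
        assert meta2["extractor"] == "tiny-conv"
        np.testing.assert_array_equal(norm2["norm_mean"], norm["norm_mean"])
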