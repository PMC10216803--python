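"""Fold splitting, oversampling, the SGD loop, early stopping, transfer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammil import model as M
from mammil.experiments import bags_from_cases
from mammil.extractors import TinyConvExtractor
from mammil.training import (
    AttentionMIL,
    TrainConfig,
    lr_at_epoch,
    make_folds,
    sampling_weights,
    should_stop,
    transfer_init,
)


def random_patient_labels(rng, n):
    return {f"p{i}": int(rng.integers(2)) for i in range(n)}


class TestMakeFolds:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(n=st.integers(12, 120), seed=st.integers(0, 5000))
    def test_disjoint_covering_patient_partition(self, n, seed):
        labels = random_patient_labels(np.random.default_rng(seed), n)
        folds = make_folds(labels, n_folds=5, seed=seed)
        all_pids = set(labels)
        test_union = set()
        for f in folds:
            tr, va, te = set(f.train_patients), set(f.val_patients), set(f.test_patients)
            assert tr | va | te == all_pids
            assert not (tr & va or tr & te or va & te)
            assert not (test_union & te)  # test folds disjoint across folds
            test_union |= te
        assert test_union == all_pids

    def test_split_proportions_at_cohort_scale(self):
        rng = np.random.default_rng(0)
        labels = {f"p{i}": int(rng.integers(2)) for i in range(789)}
        f = make_folds(labels, n_folds=5, seed=42)[0]
        assert abs(len(f.test_patients) - 158) <= 2
        assert abs(len(f.val_patients) - 79) <= 2
        assert abs(len(f.train_patients) - 552) <= 3

    def test_folds_are_class_stratified(self):
        labels = {f"p{i}": (i % 4 == 0) for i in range(200)}  # 25% positives
        for f in make_folds(labels, n_folds=5, seed=1):
            frac = np.mean([labels[p] for p in f.test_patients])
            assert abs(frac - 0.25) < 0.08

    def test_same_seed_identical_splits(self):
        labels = random_patient_labels(np.random.default_rng(3), 60)
        assert make_folds(labels, seed=9) == make_folds(labels, seed=9)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            make_folds({"a": 0, "b": 1}, n_folds=5)


class TestSamplingWeights:
    def test_balanced_classes_uniform(self):
        w = sampling_weights([0] * 100 + [1] * 100)
        np.testing.assert_allclose(w, np.full(200, 1 / 200))

    def test_minority_gets_proportional_boost(self):
        w = sampling_weights([0] * 150 + [1] * 50)
        assert w[-1] / w[0] == pytest.approx(3.0)

    def test_class_mass_is_half_each(self):
        labels = [0] * 37 + [1] * 163
        w = sampling_weights(labels)
        assert w[: 37].sum() == pytest.approx(0.5)
        assert w.sum() == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sampling_weights([1, 1, 1])

    def test_empirical_balance_over_draws(self):
        labels = np.array([0] * 160 + [1] * 40)
        w = sampling_weights(labels)
        draws = np.random.default_rng(0).choice(len(labels), size=10_000, p=w)
        freq = labels[draws].mean()
        assert abs(freq - 0.5) < 0.02


class TestSchedule:
    @pytest.mark.parametrize("epoch,lr", [(1, 0.001), (11, 0.0009), (25, 0.00081)])
    def test_step_decay_values(self, epoch, lr):
        assert lr_at_epoch(epoch, TrainConfig()) == pytest.approx(lr)

    def test_flat_validation_stops_at_21(self):
        cfg = TrainConfig()  # min 20, patience 20
        stops = [e for e in range(1, 101) if should_stop(e, best_epoch=1, cfg=cfg)]
        assert stops[0] == 21

    def test_never_stops_before_min_epochs(self):
        cfg = TrainConfig(min_epochs=20, patience=5)
        assert not any(should_stop(e, 1, cfg) for e in range(1, 20))

    def test_never_runs_past_max_epochs(self):
        cfg = TrainConfig(max_epochs=30)
        assert should_stop(30, 30, cfg)


def _tiny_fit(cases, cfg, **kwargs):
    bags, labels, _ = bags_from_cases(cases)
    split = int(0.75 * len(bags))
    model = AttentionMIL(
        bags[:split], labels[:split], extractor=TinyConvExtractor(), config=cfg
    )
    return model, model.fit(bags[split:], labels[split:], **kwargs)


class TestTrainingLoop:
    def test_update_counts_follow_accumulation_rule(self, phantom_cases, monkeypatch):
        calls = []
        orig = AttentionMIL._sgd_step

        def counting(self, *a, **k):
            calls.append(a[3])  # the group-size argument of _sgd_step
            return orig(self, *a, **k)

        monkeypatch.setattr(AttentionMIL, "_sgd_step", counting)
        cfg = TrainConfig(min_epochs=1, max_epochs=1, patience=1, seed=0)
        bags, labels, _ = bags_from_cases(phantom_cases[:20])
        # 16 training bags -> exactly 2 updates of 8
        model = AttentionMIL(bags[:16], labels[:16], extractor=TinyConvExtractor(), config=cfg)
        model.fit(bags[16:], labels[16:])
        assert calls == [8, 8]
        # 20 training bags -> 3 updates (8 + 8 + 4), remainder still updates
        calls.clear()
        model = AttentionMIL(bags[:20], labels[:20], extractor=TinyConvExtractor(), config=cfg)
        model.fit(bags[:4], labels[:4])
        assert calls == [8, 8, 4]

    def test_fixed_seed_reproduces_run_exactly(self, phantom_cases):
        cfg = TrainConfig(min_epochs=2, max_epochs=2, patience=1, seed=11)
        _, res1 = _tiny_fit(phantom_cases, cfg)
        _, res2 = _tiny_fit(phantom_cases, cfg)
        pd.testing.assert_frame_equal(res1.history, res2.history)
        for name, arr in res1.params.as_dict().items():
            np.testing.assert_array_equal(arr, getattr(res2.params, name))

    def test_history_and_summary_shape(self, phantom_cases):
        cfg = TrainConfig(min_epochs=2, max_epochs=2, patience=1, seed=0)
        _, res = _tiny_fit(phantom_cases, cfg)
        assert list(res.history.columns) == ["epoch", "lr", "train_loss", "val_loss", "val_auc"]
        assert len(res.history) == 2
        assert "gated-attention MIL" in res.summary()

    def test_checkpoint_save_load_round_trip(self, phantom_cases, tmp_path):
        cfg = TrainConfig(min_epochs=1, max_epochs=1, patience=1, seed=0)
        _, res = _tiny_fit(phantom_cases, cfg)
        res.save(tmp_path / "ckpt")
        params, meta, norm = M.load_checkpoint(tmp_path / "ckpt")
        for name, arr in res.params.as_dict().items():
            np.testing.assert_array_equal(arr, getattr(params, name))
        assert meta["k_evidence"] == 8
        assert "norm_mean" in norm

    def test_augmented_training_runs_and_differs(self, phantom_cases):
        from mammil.bagging import AugmentationPolicy

        bags, labels, _ = bags_from_cases(phantom_cases[:16])
        cfg = TrainConfig(min_epochs=1, max_epochs=1, patience=1, seed=5)
        plain = AttentionMIL(bags[:12], labels[:12], extractor=TinyConvExtractor(), config=cfg)
        res_plain = plain.fit(bags[12:], labels[12:])
        aug = AttentionMIL(
            bags[:12], labels[:12], extractor=TinyConvExtractor(), config=cfg,
            augmentation=AugmentationPolicy(),
        )
        res_aug = aug.fit(bags[12:], labels[12:])
        assert res_plain.history["train_loss"][0] != res_aug.history["train_loss"][0]


class TestTransfer:
    def test_identity_without_training(self):
        src = M.init_params(8, 16, 12, 8, seed=1)
        tgt = M.init_params(8, 16, 12, 8, seed=2)
        out = transfer_init(tgt, src)
        for name, arr in src.as_dict().items():
            np.testing.assert_array_equal(arr, getattr(out, name))

    def test_incompatible_shape_fails_atomically(self):
        src = M.init_params(8, 16, 12, 8, seed=1)
        tgt = M.init_params(8, 16, 10, 8, seed=2)  # different attention dim
        before = {n: a.copy() for n, a in tgt.as_dict().items()}
        with pytest.raises(ValueError, match="V"):
            transfer_init(tgt, src)
        for name, arr in tgt.as_dict().items():
            np.testing.assert_array_equal(arr, before[name])

    def test_transfer_lowers_initial_validation_loss(self, phantom_cases):
        """Weights fitted on one phantom domain transfer usefully to another."""
        from mammil.synthetic import PhantomSpec, generate_dataset

        cfg = TrainConfig(min_epochs=8, max_epochs=8, patience=1, seed=0,
                          reduced_dim=64, attention_dim=64, hidden_dim=64)
        model, res = _tiny_fit(phantom_cases, cfg)
        target = generate_dataset(PhantomSpec(n_patients=16, seed=99))
        bags, labels, _ = bags_from_cases(target)
        feats = [model._features(b) for b in bags]

        def val_loss(params):
            eps = 1e-12
            probs = np.array([M.forward_bag(params, F)["prob"] for F in feats])
            return -np.mean(labels * np.log(probs + eps) + (1 - labels) * np.log(1 - probs + eps))

        transferred = val_loss(res.params)
        random_losses = [
            val_loss(M.init_params(32, 64, 64, 64, seed=s)) for s in range(5)
        ]
        assert transferred <= np.mean(random_losses) + 0.05


class TestNumericalGuards:
    def test_non_finite_features_raise_with_patch_index(self):
        p = M.init_params(4, 8, 8, 8, seed=0)
        H = np.ones((3, 4))
        H[1] = np.inf
        with pytest.raises(FloatingPointError, match="patch 1"):
            M.forward_bag(p, H, 1)
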