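"""Model fitting: patient-wise cross-validation, class-balanced sampling,
and the SGD training loop with gradient accumulation and early stopping.

The public surface follows the model/results idiom: :class:`AttentionMIL`
is built from bags (+ labels), ``fit()`` runs the optimisation and returns
an :class:`MILResults` holding the best-validation parameters, the epoch
history, and prediction / attention / summary methods.

Training regime (defaults in :class:`TrainConfig`): SGD with momentum 0.9,
lr 0.001 stepped by gamma = 0.9 every 10 epochs, L2 weight decay 0.001 on
weight matrices, batch size 1 with gradients accumulated over 8 bags per
parameter update (the final short group of an epoch still updates), weighted
random oversampling to balance classes, at least 20 and at most 100 epochs
with 20-epoch patience on the validation criterion, and the 0.7 / 0.3
bag / instance loss mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as M
from .bagging import AugmentationPolicy, Bag, Patch, augment_instance
from .evaluation import roc_auc
from .extractors import extract_features
from .imaging import Label


@dataclass
class TrainConfig:
    """Hyperparameters of the optimisation; defaults are the study regime."""

    lr: float = 0.001
    lr_gamma: float = 0.9
    lr_step_epochs: int = 10
    weight_decay: float = 0.001
    momentum: float = 0.9
    batch_size: int = 1
    accumulation_steps: int = 8
    min_epochs: int = 20
    max_epochs: int = 100
    patience: int = 20
    loss_weights: tuple[float, float] = (0.7, 0.3)
    k_evidence: int = 8
    dropout: float = 0.25
    seed: int = 42
    reduced_dim: int = 256
    attention_dim: int = 256
    hidden_dim: int = 256
    monitor: str = "val_loss"  # or "val_auc"

    def __post_init__(self) -> None:
        if abs(sum(self.loss_weights) - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to 1")
        for name in ("lr", "lr_gamma", "weight_decay", "momentum", "accumulation_steps",
                     "min_epochs", "max_epochs", "patience", "dropout"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.monitor not in ("val_loss", "val_auc"):
            raise ValueError(f"unknown monitor '{self.monitor}'")


@dataclass
class FoldSplit:
    """Patient-level train/validation/test assignment for one CV fold."""

    fold_id: int
    train_patients: tuple[str, ...]
    val_patients: tuple[str, ...]
    test_patients: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train_patients), set(self.val_patients), set(self.test_patients)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError(f"fold {self.fold_id}: subsets overlap")


def make_folds(
    patient_labels: dict[str, Label | int],
    n_folds: int = 5,
    seed: int = 42,
) -> list[FoldSplit]:
    """Stratified patient-wise k-fold splits with a 70/10/20 structure.

    Patients are shuffled once per class with ``seed`` and dealt into
    ``n_folds`` near-equal, class-balanced test folds (disjoint across
    folds, covering every patient). For each fold the remaining patients
    are split 7:1 into train and validation, again per class, so every
    image of a patient lands in exactly one subset.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(patient_labels) < n_folds:
        raise ValueError(f"{len(patient_labels)} patients cannot fill {n_folds} folds")

    def _bin(lab) -> int:
        return lab.binary if isinstance(lab, Label) else int(lab)

    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for pid in sorted(patient_labels):
        by_class.setdefault(_bin(patient_labels[pid]), []).append(pid)
    chunks: dict[int, list[list[str]]] = {}
    for cls, pids in sorted(by_class.items()):
        pids = list(pids)
        rng.shuffle(pids)
        chunks[cls] = [list(part) for part in np.array_split(pids, n_folds)]

    folds = []
    for f in range(n_folds):
        test, remaining = [], {}
        for cls in chunks:
            test.extend(chunks[cls][f])
            remaining[cls] = [p for i, part in enumerate(chunks[cls]) if i != f for p in part]
        train, val = [], []
        fold_rng = np.random.default_rng(np.random.SeedSequence([seed, f]))
        for cls, pids in sorted(remaining.items()):
            pids = list(pids)
            fold_rng.shuffle(pids)
            n_val = int(round(len(pids) / 8.0))  # 7:1 of the remaining 80% -> 70/10
            val.extend(pids[:n_val])
            train.extend(pids[n_val:])
        folds.append(
            FoldSplit(
                fold_id=f + 1,
                train_patients=tuple(sorted(train)),
                val_patients=tuple(sorted(val)),
                test_patients=tuple(sorted(test)),
            )
        )
    return folds


def sampling_weights(train_labels) -> np.ndarray:
    """Oversampling probabilities inversely proportional to class frequency.

    Each class receives total probability mass 1/2, so the expected draw is
    class-balanced regardless of the imbalance ratio.
    """
    ys = np.array([l.binary if isinstance(l, Label) else int(l) for l in train_labels])
    counts = np.bincount(ys, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present in the training set")
    w = 1.0 / counts[ys]
    return w / w.sum()


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Step-decayed learning rate: ``lr * gamma^floor((epoch-1)/step)``."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return cfg.lr * cfg.lr_gamma ** ((epoch - 1) // cfg.lr_step_epochs)


def should_stop(epoch: int, best_epoch: int, cfg: TrainConfig) -> bool:
    """Early-stopping rule, evaluated after each completed (1-based) epoch.

    Training halts at ``max_epochs``, or once at least ``min_epochs`` have
    run and ``patience`` epochs have passed since the best validation epoch.
    """
    if epoch >= cfg.max_epochs:
        return True
    return epoch >= cfg.min_epochs and epoch >= best_epoch + cfg.patience


def transfer_init(params_template: M.MILParams, source) -> M.MILParams:
    """Initialise every learnable parameter from a source checkpoint.

    ``source`` is a checkpoint path or an :class:`MILParams`. All-or-nothing:
    any missing or shape-mismatched parameter aborts the load with the
    offending name, leaving the template untouched.
    """
    if isinstance(source, (str, Path)):
        src, _, _ = M.load_checkpoint(source)
    else:
        src = source
    for name, tgt in params_template.as_dict().items():
        arr = getattr(src, name, None)
        if arr is None:
            raise ValueError(f"source checkpoint lacks parameter '{name}'")
        if arr.shape != tgt.shape:
            raise ValueError(
                f"parameter '{name}' shape mismatch: source {arr.shape} vs target {tgt.shape}"
            )
    return src.copy()


def _bag_label(bag: Bag, label) -> int:
    if label is not None:
        return label.binary if isinstance(label, Label) else int(label)
    return bag.label.binary


class AttentionMIL:
    """Clustering-constrained gated-attention MIL model over patch bags.

    Parameters
    ----------
    bags : list of Bag
        Training bags (one per case; a bag may span both views).
    labels : sequence of {0, 1} or Label, optional
        Defaults to each bag's inherited image label.
    extractor : callable
        Frozen patch-feature extractor (see :mod:`mammil.extractors`).
    config : TrainConfig
    augmentation : AugmentationPolicy, optional
        When given, training patches are re-augmented and re-encoded each
        draw; when None (default) features are extracted once and cached,
        which is exact for a frozen extractor and much faster.
    """

    def __init__(
        self,
        bags: list[Bag],
        labels=None,
        *,
        extractor,
        config: TrainConfig | None = None,
        augmentation: AugmentationPolicy | None = None,
    ):
        if not bags:
            raise ValueError("no training bags")
        self.bags = list(bags)
        self.labels = np.array(
            [_bag_label(b, None if labels is None else labels[i]) for i, b in enumerate(self.bags)]
        )
        self.extractor = extractor
        self.config = config or TrainConfig()
        self.augmentation = augmentation

    # -- helpers -------------------------------------------------------------

    def _features(self, bag: Bag) -> np.ndarray:
        return extract_features(bag, self.extractor)

    def _augmented_features(self, bag: Bag, rng: np.random.Generator) -> np.ndarray:
        patches = [augment_instance(p, self.augmentation, rng) for p in bag.patches]
        aug = Bag(
            patches=patches, label=bag.label, patch_size_px=bag.patch_size_px,
            overlap=bag.overlap, source_shape=bag.source_shape, patient_id=bag.patient_id,
        )
        return self._features(aug)

    def _calibrate_extractor(self, feats: list[np.ndarray]) -> None:
        ex = self.extractor
        if hasattr(ex, "calibrate") and getattr(ex, "norm_mean", None) is None:
            raw = np.vstack(feats)
            ex.calibrate(raw)
            for i, f in enumerate(feats):
                feats[i] = (f - ex.norm_mean) / ex.norm_std

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        val_bags: list[Bag] | None = None,
        val_labels=None,
        init: M.MILParams | str | Path | None = None,
        verbose: bool = False,
    ) -> "MILResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        init_seed, sampler_seed, dropout_seed, augment_seed = ss.spawn(4)
        rng_sampler = np.random.default_rng(sampler_seed)
        rng_dropout = np.random.default_rng(dropout_seed)
        rng_augment = np.random.default_rng(augment_seed)

        feats = [self._features(b) for b in self.bags]
        self._calibrate_extractor(feats)
        feature_dim = feats[0].shape[1]

        params = M.init_params(
            feature_dim, cfg.reduced_dim, cfg.attention_dim, cfg.hidden_dim,
            seed=np.random.default_rng(init_seed),
        )
        if init is not None:
            params = transfer_init(params, init)

        if val_bags:
            val_feats = [self._features(b) for b in val_bags]
            val_y = np.array(
                [_bag_label(b, None if val_labels is None else val_labels[i])
                 for i, b in enumerate(val_bags)]
            )
        else:
            val_feats, val_y = None, None

        weights = sampling_weights(self.labels)
        velocity = {n: np.zeros_like(v) for n, v in params.as_dict().items()}
        n_train = len(self.bags)
        history: list[dict] = []
        best = {"epoch": 0, "crit": np.inf, "params": params.copy()}

        for epoch in range(1, cfg.max_epochs + 1):
            lr = lr_at_epoch(epoch, cfg)
            order = rng_sampler.choice(n_train, size=n_train, replace=True, p=weights)
            accum = {n: np.zeros_like(v) for n, v in params.as_dict().items()}
            group, losses = 0, []
            for step, idx in enumerate(order):
                bag = self.bags[idx]
                H = (
                    self._augmented_features(bag, rng_augment)
                    if self.augmentation is not None
                    else feats[idx]
                )
                out = M.forward_bag(
                    params, H, int(self.labels[idx]),
                    k_evidence=cfg.k_evidence, loss_weights=cfg.loss_weights,
                    dropout=cfg.dropout, train=True, rng=rng_dropout,
                )
                if not np.isfinite(out["loss"]):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, step {step} (bag {bag.patient_id})"
                    )
                losses.append(out["loss"])
                grads = M.backward_bag(params, out["cache"])
                for n in accum:
                    accum[n] += grads[n]
                group += 1
                if group == cfg.accumulation_steps or step == n_train - 1:
                    self._sgd_step(params, velocity, accum, group, lr)
                    accum = {n: np.zeros_like(v) for n, v in params.as_dict().items()}
                    group = 0

            rec = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses))}
            if val_feats is not None:
                scores = np.array(
                    [M.forward_bag(params, F)["prob"] for F in val_feats]
                )
                eps = 1e-12
                rec["val_loss"] = float(
                    -np.mean(val_y * np.log(scores + eps) + (1 - val_y) * np.log(1 - scores + eps))
                )
                rec["val_auc"] = (
                    roc_auc(scores, val_y) if len(set(val_y.tolist())) == 2 else np.nan
                )
                crit = rec["val_loss"] if cfg.monitor == "val_loss" else -rec["val_auc"]
            else:
                rec["val_loss"], rec["val_auc"] = np.nan, np.nan
                crit = rec["train_loss"]
            history.append(rec)
            if verbose:
                print(
                    f"epoch {epoch:3d} lr {lr:.5f} train {rec['train_loss']:.4f} "
                    f"val {rec['val_loss']:.4f}"
                )
            if crit < best["crit"]:
                best = {"epoch": epoch, "crit": crit, "params": params.copy()}
            if should_stop(epoch, best["epoch"], cfg):
                break

        return MILResults(
            params=best["params"],
            config=cfg,
            extractor=self.extractor,
            history=pd.DataFrame(history),
            best_epoch=best["epoch"],
        )

    def _sgd_step(self, params, velocity, accum, group, lr) -> None:
        # per-sample gradients are summed between updates, as backward-pass
        # accumulation does at batch size 1; the remainder group of an epoch
        # therefore takes a proportionally smaller step
        cfg = self.config
        for n, p in params.as_dict().items():
            g = accum[n]
            if cfg.weight_decay and n in M.MILParams.DECAYED:
                g = g + cfg.weight_decay * p
            velocity[n] = cfg.momentum * velocity[n] + g
            p -= lr * velocity[n]


@dataclass
class MILResults:
    """Fitted MIL model: best-validation parameters plus diagnostics."""

    params: M.MILParams
    config: TrainConfig
    extractor: object
    history: pd.DataFrame
    best_epoch: int

    # -- inference -----------------------------------------------------------

    def _forward(self, bag: Bag) -> dict:
        H = extract_features(bag, self.extractor)
        return M.forward_bag(self.params, H)

    def predict_proba(self, bags: list[Bag]) -> np.ndarray:
        """Bag cancer probabilities in (0, 1)."""
        return np.array([self._forward(b)["prob"] for b in bags])

    def predict(self, bags: list[Bag], threshold: float = 0.5) -> np.ndarray:
        """Hard labels: cancer iff the score strictly exceeds the threshold."""
        return (self.predict_proba(bags) > threshold).astype(int)

    def attention(self, bag: Bag) -> M.AttentionState:
        """Per-patch attention weights for one bag."""
        out = self._forward(bag)
        return M.AttentionState(raw_scores=out["raw_scores"], a=out["a"])

    def render_heatmap(self, bag: Bag):
        """Attention heatmap over the bag's source image."""
        from .heatmap import render_heatmap

        return render_heatmap(bag, self.attention(bag), bag.source_shape)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        meta = {
            "extractor": getattr(getattr(self.extractor, "spec", None), "name", "unknown"),
            "feature_dim": self.params.feature_dim,
            "reduced_dim": self.params.reduced_dim,
            "attention_dim": self.params.attention_dim,
            "k_evidence": self.config.k_evidence,
            "best_epoch": self.best_epoch,
            "seed": self.config.seed,
            "threshold": 0.5,
        }
        norm = self.extractor.norm_state() if hasattr(self.extractor, "norm_state") else None
        return M.save_checkpoint(path, self.params, meta, norm)

    def summary(self) -> str:
        """Plain-text fitting summary in the spirit of a results table."""
        cfg, h = self.config, self.history
        lines = [
            "Clustering-constrained gated-attention MIL",
            "=" * 44,
            f"feature dim (M):      {self.params.feature_dim}",
            f"reduced dim (M'):     {self.params.reduced_dim}",
            f"attention dim (L):    {self.params.attention_dim}",
            f"evidence k:           {cfg.k_evidence}",
            f"loss mix (bag, inst): {cfg.loss_weights}",
            f"optimiser:            SGD lr={cfg.lr} momentum={cfg.momentum} "
            f"wd={cfg.weight_decay} accum={cfg.accumulation_steps}",
            f"epochs run:           {len(h)} (best @ {self.best_epoch})",
        ]
        if len(h):
            row = h.loc[h["epoch"] == self.best_epoch]
            if len(row):
                r = row.iloc[0]
                lines.append(
                    f"best val loss/auc:    {r['val_loss']:.4f} / {r['val_auc']:.4f}"
                )
        return "\n".join(lines)
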