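"""Patch feature extractors.

The MIL head is agnostic to where the K x M patch embeddings come from: any
callable mapping a stack of 3-channel square patches to a K x M matrix can
stand behind :class:`ExtractorSpec`. The package ships a small fixed-weight
convolutional extractor (two conv + pool stages, 32 features) so the whole
pipeline runs and is testable without pretrained weights; large ImageNet
backbones plug in through the same interface.

Extractors are frozen during MIL training — the same patch content always
yields the same feature row — mirroring the frozen normalisation statistics
of pretrained backbones. The tiny extractor additionally supports per-feature
standardisation whose statistics are calibrated once (typically on the
training split) and then frozen into the checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bagging import Bag
from .imaging import expand_channels


@dataclass(frozen=True)
class ExtractorSpec:
    """Declared identity and output dimension of a feature extractor."""

    name: str
    feature_dim: int
    frozen_norm_stats: bool = True

    def __post_init__(self) -> None:
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")


def _im2col(x: np.ndarray, ksize: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H-k+1, W-k+1, k*k*C) sliding windows (valid conv)."""
    n, h, w, c = x.shape
    oh, ow = h - ksize + 1, w - ksize + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, ksize, ksize, c), strides=(s0, s1, s2, s1, s2, s3)
    )
    return windows.reshape(n, oh, ow, ksize * ksize * c)


def _conv_relu(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid 2-D convolution (as correlation) + ReLU via im2col matmul."""
    k = int(np.sqrt(kernel.shape[0] // x.shape[-1]))
    cols = _im2col(x, k)
    out = cols @ kernel + bias
    np.maximum(out, 0.0, out=out)
    return out


def _maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2 max pooling with stride 2 (trailing odd row/col dropped)."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, : 2 * h2, : 2 * w2].reshape(n, h2, 2, w2, 2, c).max(axis=(2, 4))


class TinyConvExtractor:
    """Fixed random-weight conv net: 3->8 conv, pool, 8->32 conv, pool, GAP.

    Weights are He-initialised from a dedicated seed and never trained; the
    extractor acts as a deterministic random projection with enough spatial
    structure (two 3x3 convolution + max-pool stages) to separate bright,
    textured tissue patterns. Global average pooling over the last feature
    map yields the declared 32 features per patch.

    ``calibrate`` fixes per-feature standardisation statistics; until called
    (or after loading them from a checkpoint) features are returned raw.
    """

    KSIZE = 3
    CH1 = 8

    def __init__(self, feature_dim: int = 32, weight_seed: int = 7, name: str = "tiny-conv"):
        rng = np.random.default_rng(weight_seed)
        k, c1 = self.KSIZE, self.CH1
        fan1 = k * k * 3
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / fan1), size=(fan1, c1))
        self.b1 = np.zeros(c1)
        fan2 = k * k * c1
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / fan2), size=(fan2, feature_dim))
        self.b2 = np.zeros(feature_dim)
        self.spec = ExtractorSpec(name=name, feature_dim=feature_dim)
        self.norm_mean: np.ndarray | None = None
        self.norm_std: np.ndarray | None = None

    # -- feature computation -------------------------------------------------

    def _raw_features(self, stack: np.ndarray) -> np.ndarray:
        if stack.ndim == 3:  # single-channel patches: expand to 3 channels
            stack = np.repeat(stack[..., None], 3, axis=3)
        if stack.ndim != 4 or stack.shape[-1] != 3:
            raise ValueError(f"expected (K, P, P, 3) patches, got shape {stack.shape}")
        if stack.shape[1] != stack.shape[2]:
            raise ValueError("patches must be square")
        if stack.shape[1] < 2 * self.KSIZE:
            raise ValueError(
                f"patch size {stack.shape[1]} too small for two conv+pool stages"
            )
        x = _conv_relu(np.ascontiguousarray(stack, dtype=np.float64), self.w1, self.b1)
        x = _maxpool2(x)
        x = _conv_relu(x, self.w2, self.b2)
        x = _maxpool2(x)
        return x.mean(axis=(1, 2))

    def __call__(self, stack: np.ndarray) -> np.ndarray:
        feats = self._raw_features(stack)
        if self.norm_mean is not None:
            feats = (feats - self.norm_mean) / self.norm_std
        return feats

    # -- frozen normalisation statistics ------------------------------------

    def calibrate(self, feature_rows: np.ndarray) -> None:
        """Freeze per-feature mean/std from a reference feature matrix.

        ``feature_rows`` must be *raw* (uncalibrated) features, e.g. the
        concatenated training-split output of :meth:`_raw_features`.
        """
        rows = np.asarray(feature_rows, dtype=np.float64)
        self.norm_mean = rows.mean(axis=0)
        self.norm_std = np.maximum(rows.std(axis=0), 1e-8)

    def norm_state(self) -> dict[str, np.ndarray]:
        if self.norm_mean is None:
            return {}
        return {"norm_mean": self.norm_mean, "norm_std": self.norm_std}

    def load_norm_state(self, state: dict[str, np.ndarray]) -> None:
        if state:
            self.norm_mean = np.asarray(state["norm_mean"], dtype=np.float64)
            self.norm_std = np.asarray(state["norm_std"], dtype=np.float64)


def extract_features(bag: Bag, extractor, spec: ExtractorSpec | None = None) -> np.ndarray:
    """Encode every patch of a bag into the K x M feature matrix H.

    ``extractor`` is any callable on a (K, P, P[, 3]) stack; its declared
    dimension is checked against the output so a misdeclared spec fails
    loudly rather than corrupting downstream weight shapes.
    """
    spec = spec or getattr(extractor, "spec", None)
    stack = bag.stack_pixels()
    if stack.ndim == 3:
        stack = np.stack([expand_channels(p) for p in stack])
    feats = np.asarray(extractor(stack), dtype=np.float64)
    if feats.ndim != 2 or feats.shape[0] != len(bag):
        raise ValueError(f"extractor returned shape {feats.shape} for a bag of {len(bag)}")
    if spec is not None and feats.shape[1] != spec.feature_dim:
        raise ValueError(
            f"extractor '{spec.name}' declared {spec.feature_dim} features "
            f"but produced {feats.shape[1]}"
        )
    return feats
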