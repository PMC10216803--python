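"""Tiling an image into overlapping square patches and assembling the MIL bag.

The multiple-instance unit is the *bag*: the set of fixed-size square tiles
cut from one (possibly multimodal) image, starting at the top-left corner
with stride ``round((1 - overlap) * patch_size)`` per axis, filtered so
every kept tile contains at least 75% non-zero pixels (background tiles
carry no tissue and would only dilute attention). The bag inherits the
image-level label; no per-patch annotation exists anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .imaging import AnyImage, Label


@dataclass
class Patch:
    """One square tile; ``(row0, col0)`` is its top-left pixel in the source."""

    row0: int
    col0: int
    size_px: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != (self.size_px, self.size_px):
            raise ValueError(
                f"patch pixels {self.pixels.shape} do not match size {self.size_px}"
            )


@dataclass
class Bag:
    """Ordered set of foreground patches from one image, with its label."""

    patches: list[Patch]
    label: Label
    patch_size_px: int
    overlap: float
    source_shape: tuple[int, int]
    patient_id: str = ""

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def coords(self) -> np.ndarray:
        """K x 2 array of (row0, col0) patch origins."""
        return np.array([(p.row0, p.col0) for p in self.patches], dtype=int)

    def stack_pixels(self) -> np.ndarray:
        """K x P x P array of patch intensities."""
        return np.stack([p.pixels for p in self.patches])


class EmptyBagError(ValueError):
    """No patch survived the foreground filter for this image."""


def tile_stride(patch_size: int, overlap: float) -> int:
    """Stride between adjacent tiles: ``round((1 - overlap) * patch_size)``, >= 1."""
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must lie in [0, 1), got {overlap}")
    return max(1, int(round((1.0 - overlap) * patch_size)))


def tile_grid(rows: int, cols: int, patch_size: int, overlap: float) -> list[tuple[int, int]]:
    """Top-left coordinates of every fully contained tile, row-major.

    Positions run ``0, s, 2s, ...`` per axis while ``p + patch_size`` stays
    inside the image; tiles that would overhang the bottom/right edge are
    dropped so all patches share one size. An oversized patch yields an
    empty grid (with a warning from :func:`build_bag`).
    """
    stride = tile_stride(patch_size, overlap)
    row_starts = range(0, max(rows - patch_size, -1) + 1, stride)
    col_starts = range(0, max(cols - patch_size, -1) + 1, stride)
    return [(r, c) for r in row_starts for c in col_starts]


def foreground_fraction(pixels: np.ndarray) -> float:
    """Fraction of strictly positive pixels in a patch.

    Raw 0 maps to exactly 0.0 under the fixed-scale intensity mapping, so
    "non-zero" is evaluated with no epsilon.
    """
    pixels = np.asarray(pixels)
    return float(np.count_nonzero(pixels > 0)) / pixels.size


def build_bag(
    img: AnyImage,
    patch_size: int,
    overlap: float,
    threshold: float = 0.75,
) -> Bag:
    """Cut the tile grid and keep patches passing the foreground rule.

    The boundary is inclusive (``foreground_fraction >= threshold``). An
    image where nothing survives is rejected with :class:`EmptyBagError`
    carrying the patient id, so degenerate cases surface as diagnostics
    rather than empty bags downstream.
    """
    pixels = img.pixels
    rows, cols = pixels.shape[:2]
    grid = tile_grid(rows, cols, patch_size, overlap)
    patches = []
    for r, c in grid:
        tile = pixels[r : r + patch_size, c : c + patch_size]
        if foreground_fraction(tile) >= threshold:
            patches.append(Patch(row0=r, col0=c, size_px=patch_size, pixels=tile.copy()))
    if not patches:
        raise EmptyBagError(
            f"no patch of size {patch_size} passed the {threshold:.0%} foreground rule "
            f"for image {getattr(img, 'patient_id', '?')} of shape {rows}x{cols}"
        )
    return Bag(
        patches=patches,
        label=img.label,
        patch_size_px=patch_size,
        overlap=overlap,
        source_shape=(rows, cols),
        patient_id=getattr(img, "patient_id", ""),
    )


@dataclass
class AugmentationPolicy:
    """Instance-level training augmentations, applied sequentially.

    Order: one right-angle rotation drawn uniformly from ``rotation_angles``
    (probability 1), horizontal flip, vertical flip, then a random crop with
    area scale uniform in ``crop_scale`` resized back to the patch size.
    Validation and test patches are never augmented.
    """

    rotation_angles: tuple[int, ...] = (0, 90, 180, 270)
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    crop_scale: tuple[float, float] = (0.8, 1.0)
    crop_prob: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.hflip_prob, self.vflip_prob, self.crop_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 < self.crop_scale[0] <= self.crop_scale[1] <= 1.0:
            raise ValueError(f"invalid crop scale range {self.crop_scale}")


def augment_instance(
    patch: Patch, policy: AugmentationPolicy, rng: np.random.Generator
) -> Patch:
    """Apply the policy's transform chain to one training patch.

    Deterministic given the generator state; output shape and value range
    are unchanged. Must not be called on validation/test data (enforced by
    the trainer, which only augments the training stream).
    """
    out = patch.pixels
    k = int(rng.integers(len(policy.rotation_angles)))
    angle = policy.rotation_angles[k]
    if angle % 90 != 0:
        raise ValueError(f"only right-angle rotations are supported, got {angle}")
    if angle:
        out = np.rot90(out, k=angle // 90)
    if rng.random() < policy.hflip_prob:
        out = out[:, ::-1]
    if rng.random() < policy.vflip_prob:
        out = out[::-1, :]
    if rng.random() < policy.crop_prob:
        scale = rng.uniform(*policy.crop_scale)
        size = patch.size_px
        side = max(1, int(round(size * np.sqrt(scale))))
        r0 = int(rng.integers(size - side + 1))
        c0 = int(rng.integers(size - side + 1))
        out = out[r0 : r0 + side, c0 : c0 + side]
        if side != size:
            out = _sk_resize(
                np.ascontiguousarray(out, dtype=np.float64),
                (size, size),
                order=1,
                mode="edge",
                anti_aliasing=False,
                preserve_range=True,
            )
    out = np.clip(np.ascontiguousarray(out, dtype=np.float64), 0.0, 1.0)
    return Patch(row0=patch.row0, col0=patch.col0, size_px=patch.size_px, pixels=out)
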