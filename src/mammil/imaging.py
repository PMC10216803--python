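"""Reading and geometric preparation of full-field digital mammograms.

A mammogram enters the pipeline as a single-channel pixel array (DICOM or
grayscale PNG), is linearly rescaled to [0, 1] by its bit-depth full-scale
value, oriented chest-wall-left, optionally stripped of the collimator
"edge" artifact band, optionally halved in resolution, and finally joined
with its sister projection (CC above MLO) into one multimodal image so a
single instance bag can span both views.

Conventions used throughout the package: arrays are row-major, indices are
0-based, and rectangular regions are half-open ``[r, r+h) x [c, c+w)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np


class Laterality(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class View(str, Enum):
    CC = "CC"
    MLO = "MLO"


class Label(str, Enum):
    CANCER = "cancer"
    NON_CANCER = "non_cancer"

    @property
    def binary(self) -> int:
        return 1 if self is Label.CANCER else 0


#: Full-scale raw value per supported bit depth.
FULL_SCALE = {8: 255, 12: 4095}


@dataclass
class Mammogram:
    """One projection of one breast, with pixels already scaled to [0, 1].

    Parameters
    ----------
    pixels : ndarray of shape (height_px, width_px)
        Intensities in [0, 1]; background is exactly 0.
    pixel_spacing_mm : float
        Physical size of one pixel side in millimetres (e.g. 0.085 for the
        Mammomat Inspiration FFDM detector).
    bit_depth : int
        Original raw depth, 8 or 12.
    """

    pixels: np.ndarray
    patient_id: str
    laterality: Laterality
    view: View
    pixel_spacing_mm: float
    bit_depth: int
    label: Label

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D pixel array, got ndim={self.pixels.ndim}")
        if self.bit_depth not in FULL_SCALE:
            raise ValueError(f"bit_depth must be 8 or 12, got {self.bit_depth}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"pixels must lie in [0, 1], observed range [{lo}, {hi}]")
        self.laterality = Laterality(self.laterality)
        self.view = View(self.view)
        self.label = Label(self.label)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MultimodalImage:
    """Vertical concatenation of a breast's CC (top) and MLO (bottom) views."""

    pixels: np.ndarray
    patient_id: str
    laterality: Laterality
    pixel_spacing_mm: float
    label: Label
    cc_rows: int
    mlo_rows: int
    resized: bool = False

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


AnyImage = Union[Mammogram, MultimodalImage]


def scale_to_unit(raw: np.ndarray, bit_depth: int) -> np.ndarray:
    """Linearly map raw integers to [0, 1] by the bit-depth full scale.

    The divisor is ``2**bit_depth - 1`` (4095 for 12-bit, 255 for 8-bit), not
    a per-image min-max: a fixed scale keeps intensities comparable across
    images and maps raw 0 to exactly 0.0, which the background/foreground
    rule of the bagging stage relies on.
    """
    if bit_depth not in FULL_SCALE:
        raise ValueError(f"bit_depth must be 8 or 12, got {bit_depth}")
    raw = np.asarray(raw)
    full = FULL_SCALE[bit_depth]
    peak = raw.max(initial=0)
    if peak > full:
        raise ValueError(
            f"raw value {int(peak)} exceeds full scale {full} for bit depth {bit_depth}"
        )
    if raw.min(initial=0) < 0:
        raise ValueError("raw pixel values must be non-negative")
    return raw.astype(np.float64) / float(full)


def _read_raw(path: Path) -> tuple[np.ndarray, float | None]:
    """Return (raw 2-D array, pixel spacing from the file if present)."""
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"}:
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise ValueError(f"{path}: multi-frame DICOM is not supported")
        if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") != "MONOCHROME2":
            raise ValueError(f"{path}: only MONOCHROME2 DICOM is supported")
        spacing = None
        if getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
        return np.asarray(arr), spacing
    # PNG (or any PIL-readable grayscale raster)
    from PIL import Image

    with Image.open(path) as im:
        if im.mode not in {"L", "I", "I;16", "I;16B"}:
            im = im.convert("I")
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    return arr, None


def load_image(
    path: str | Path,
    bit_depth: int,
    *,
    patient_id: str,
    laterality: Laterality | str,
    view: View | str,
    label: Label | str,
    pixel_spacing_mm: float = 0.085,
) -> Mammogram:
    """Read a DICOM or grayscale PNG mammogram and scale it to [0, 1].

    Raises
    ------
    OSError
        If the file is missing or cannot be decoded.
    ValueError
        If a raw value exceeds the declared bit depth's full scale.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"image file not found: {path}")
    raw, file_spacing = _read_raw(path)
    return Mammogram(
        pixels=scale_to_unit(raw, bit_depth),
        patient_id=str(patient_id),
        laterality=Laterality(laterality),
        view=View(view),
        pixel_spacing_mm=file_spacing or pixel_spacing_mm,
        bit_depth=bit_depth,
        label=Label(label),
    )


def expand_channels(pixels: np.ndarray) -> np.ndarray:
    """Repeat a single-channel array to 3 identical channels (H, W, 3)."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D array, got shape {pixels.shape}")
    return np.repeat(pixels[:, :, None], 3, axis=2)


def chest_wall_side(pixels: np.ndarray, band_frac: float = 0.05) -> Laterality | None:
    """Locate the chest-wall edge: the vertical edge with the brighter band.

    Compares mean intensity of the outermost ``band_frac`` column bands
    (at least one column each). Returns None when the two bands are equally
    bright within relative tolerance 1e-6.
    """
    cols = pixels.shape[1]
    band = max(1, int(round(band_frac * cols)))
    left = float(pixels[:, :band].mean())
    right = float(pixels[:, -band:].mean())
    scale = max(abs(left), abs(right), 1e-300)
    if abs(left - right) / scale < 1e-6:
        return None
    return Laterality.LEFT if left > right else Laterality.RIGHT


def orient_chest_wall(img: Mammogram, target_side: Laterality | str = Laterality.LEFT) -> Mammogram:
    """Flip the image horizontally so the chest wall lies on ``target_side``.

    The anatomical laterality metadata is preserved; only pixel geometry is
    normalised. If the two edges are equally bright a warning is issued and
    the image is returned unflipped.
    """
    target_side = Laterality(target_side)
    side = chest_wall_side(img.pixels)
    if side is None:
        warnings.warn(
            f"{img.patient_id}/{img.view.value}: chest-wall side is ambiguous "
            "(both edge bands equally bright); image left unflipped",
            stacklevel=2,
        )
        return img
    if side == target_side:
        return img
    return replace(img, pixels=img.pixels[:, ::-1].copy())


def remove_edge_artifact(
    img: AnyImage, band_px: int = 20, chest_side: Laterality | str = Laterality.LEFT
) -> AnyImage:
    """Delete the ``band_px`` columns adjacent to the chest-wall edge.

    This removes the high-intensity collimator-misalignment bar that can
    spuriously correlate with the image label. ``band_px = 0`` is the
    identity; the band must be narrower than the image.
    """
    if band_px < 0 or band_px >= img.pixels.shape[1]:
        raise ValueError(
            f"band_px must satisfy 0 <= band_px < width ({img.pixels.shape[1]}), got {band_px}"
        )
    if band_px == 0:
        return img
    if Laterality(chest_side) is Laterality.LEFT:
        cropped = img.pixels[:, band_px:].copy()
    else:
        cropped = img.pixels[:, :-band_px].copy()
    return replace(img, pixels=cropped)


def resize_half(img: AnyImage) -> AnyImage:
    """Halve both image dimensions by 2x2 block averaging.

    Output dimensions are ``floor(input / 2)`` per axis (any odd trailing row
    or column is dropped); a constant image stays constant and values remain
    in [0, 1]. Pixel spacing doubles.
    """
    h, w = img.pixels.shape
    if h < 2 or w < 2:
        raise ValueError(f"cannot halve a degenerate image of shape {(h, w)}")
    h2, w2 = h // 2, w // 2
    blocks = img.pixels[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2)
    halved = blocks.mean(axis=(1, 3))
    kwargs = {"pixels": halved, "pixel_spacing_mm": img.pixel_spacing_mm * 2}
    if isinstance(img, MultimodalImage):
        kwargs.update(resized=True, cc_rows=img.cc_rows // 2, mlo_rows=img.mlo_rows // 2)
    return replace(img, **kwargs)


def concat_views(cc: Mammogram, mlo: Mammogram) -> MultimodalImage:
    """Stack a breast's CC view on top of its MLO view into one image.

    Both views must belong to the same patient and breast and share a label.
    If artifact cropping left the two views with different widths, the
    narrower one is padded with zero columns on the right (the non-chest-wall
    side under the chest-wall-left convention).
    """
    if cc.view is not View.CC or mlo.view is not View.MLO:
        raise ValueError(f"expected (CC, MLO) in that order, got ({cc.view}, {mlo.view})")
    if cc.patient_id != mlo.patient_id or cc.laterality != mlo.laterality:
        raise ValueError(
            "views belong to different patients/breasts: "
            f"{cc.patient_id}/{cc.laterality.value} vs {mlo.patient_id}/{mlo.laterality.value}"
        )
    if cc.label != mlo.label:
        raise ValueError("CC and MLO carry different labels")
    width = max(cc.width_px, mlo.width_px)

    def _pad(p: np.ndarray) -> np.ndarray:
        if p.shape[1] == width:
            return p
        return np.pad(p, ((0, 0), (0, width - p.shape[1])))

    stacked = np.vstack([_pad(cc.pixels), _pad(mlo.pixels)])
    return MultimodalImage(
        pixels=stacked,
        patient_id=cc.patient_id,
        laterality=cc.laterality,
        pixel_spacing_mm=cc.pixel_spacing_mm,
        label=cc.label,
        cc_rows=cc.height_px,
        mlo_rows=mlo.height_px,
    )
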