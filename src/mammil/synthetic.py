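"""Synthetic phantom mammograms with known ground truth.

Each phantom patient gets a CC and an MLO view: a smooth, noisy half-ellipse
of "breast" tissue flush with the chest-wall (left) edge on an exactly-zero
background. Cancer cases carry one or more radially decaying bright lesion
discs placed independently per view (the same physical lesion projects to
different positions in the two projections); their pixel masks are recorded
so localisation can be scored. Optionally a full-height high-intensity band
at the chest-wall edge emulates the collimator "edge" artifact, drawn with
class-conditional probabilities so an artifact-label correlation — and the
shortcut learning it invites — can be reproduced and then ablated.

The default desk-scale geometry (256 x 192 px, patch 64, overlap 0.5)
preserves the full pipeline's geometric logic — tiling, the 75% foreground
rule, CC+MLO row concatenation — at a size where training runs in seconds;
full FFDM dimensions are supported but not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import Label, Laterality, Mammogram, MultimodalImage, View, concat_views, remove_edge_artifact


@dataclass
class PhantomSpec:
    """Study-condition knobs of the phantom generator (all ranges inclusive)."""

    n_patients: int = 100
    image_shape: tuple[int, int] = (256, 192)
    cancer_fraction: float = 0.5
    # lesion model: bright discs with quadratic radial falloff
    lesion_radius_px: tuple[int, int] = (6, 14)
    lesion_intensity_lift: tuple[float, float] = (0.25, 0.45)
    lesion_count: tuple[int, int] = (1, 3)
    lesions_enabled: bool = True
    # breast model: half-ellipse axes as fractions of the image dimensions
    breast_row_axis_frac: tuple[float, float] = (0.36, 0.48)
    breast_col_axis_frac: tuple[float, float] = (0.55, 0.85)
    base_intensity: tuple[float, float] = (0.35, 0.50)
    noise_std: float = 0.05
    # chest-wall edge artifact
    artifact_prob_cancer: float = 0.0
    artifact_prob_noncancer: float = 0.0
    artifact_band_px: int = 20
    artifact_intensity: float = 0.95
    pixel_spacing_mm: float = 0.085
    seed: int = 42

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0 or self.n_patients <= 0:
            raise ValueError("image shape and patient count must be positive")
        for p in (self.cancer_fraction, self.artifact_prob_cancer, self.artifact_prob_noncancer):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        min_row_axis = self.breast_row_axis_frac[0] * rows
        min_col_axis = self.breast_col_axis_frac[0] * cols
        if self.lesions_enabled and self.lesion_radius_px[1] * 2 >= min(min_row_axis, min_col_axis):
            raise ValueError(
                f"lesion radius up to {self.lesion_radius_px[1]} px cannot fit inside "
                f"the smallest breast (axes >= {min_row_axis:.0f} x {min_col_axis:.0f} px)"
            )
        if not 0 <= self.artifact_band_px < cols:
            raise ValueError("artifact band must be narrower than the image")


@dataclass
class PhantomCase:
    """One synthetic patient: both views, label, lesion masks, artifact flag."""

    patient_id: str
    label: Label
    cc: Mammogram
    mlo: Mammogram
    lesion_mask_cc: np.ndarray
    lesion_mask_mlo: np.ndarray
    has_artifact: bool


def _render_view(
    spec: PhantomSpec, rng: np.random.Generator, cancer: bool, artifact: bool
) -> tuple[np.ndarray, np.ndarray]:
    """One view's pixel array in [0, 1] plus its binary lesion mask."""
    rows, cols = spec.image_shape
    rc = rows / 2.0 + rng.uniform(-0.05, 0.05) * rows
    ar = rng.uniform(*spec.breast_row_axis_frac) * rows
    ac = rng.uniform(*spec.breast_col_axis_frac) * cols
    rr, cc = np.mgrid[0:rows, 0:cols]
    ellipse = ((rr - rc) / ar) ** 2 + (cc / ac) ** 2
    breast = ellipse <= 1.0

    img = np.zeros((rows, cols))
    base = rng.uniform(*spec.base_intensity)
    tissue = base + rng.normal(0.0, spec.noise_std, size=(rows, cols))
    img[breast] = np.clip(tissue[breast], 0.02, 1.0)  # strictly positive foreground

    mask = np.zeros((rows, cols), dtype=bool)
    if cancer and spec.lesions_enabled:
        n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
        for _ in range(n_lesions):
            radius = int(rng.integers(spec.lesion_radius_px[0], spec.lesion_radius_px[1] + 1))
            lift = rng.uniform(*spec.lesion_intensity_lift)
            for _attempt in range(200):
                r0 = int(rng.integers(radius, rows - radius))
                c0 = int(rng.integers(radius, cols - radius))
                disc_extent = ((np.array([r0 - radius, r0 + radius]) - rc) / ar) ** 2
                if max(disc_extent + (max(c0 - radius, 0) / ac) ** 2) > 1.0:
                    continue
                corner = (
                    ((np.array([r0 - radius, r0 + radius])[:, None] - rc) / ar) ** 2
                    + ((np.array([max(c0 - radius, 0), c0 + radius])[None, :]) / ac) ** 2
                )
                if (corner <= 1.0).all():
                    break
            else:
                raise ValueError(
                    f"could not place a lesion of radius {radius} inside the breast"
                )
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
            disc = d2 <= radius**2
            falloff = np.zeros_like(img)
            falloff[disc] = lift * (1.0 - d2[disc] / float(radius**2))
            img = np.clip(img + falloff, 0.0, 1.0)
            mask |= disc

    if artifact and spec.artifact_band_px > 0:
        img[:, : spec.artifact_band_px] = spec.artifact_intensity
    return img, mask


def generate_dataset(spec: PhantomSpec) -> list[PhantomCase]:
    """Generate the full phantom cohort, reproducible from ``spec.seed``.

    Labels are assigned by rounding ``n_patients * cancer_fraction`` and
    shuffling; each patient then draws its two views (shared label and
    artifact flag, independent lesion placement) from a per-patient child
    seed, so the dataset is identical regardless of evaluation order.
    """
    root = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    n_cancer = int(round(spec.n_patients * spec.cancer_fraction))
    labels = np.array([1] * n_cancer + [0] * (spec.n_patients - n_cancer))
    label_rng.shuffle(labels)

    cases = []
    child_seeds = root.spawn(spec.n_patients + 1)[1:]
    for i, (lab, child) in enumerate(zip(labels, child_seeds)):
        rng = np.random.default_rng(child)
        cancer = bool(lab)
        p_art = spec.artifact_prob_cancer if cancer else spec.artifact_prob_noncancer
        artifact = bool(rng.random() < p_art)
        pid = f"P{i:04d}"
        label = Label.CANCER if cancer else Label.NON_CANCER
        views = {}
        masks = {}
        for view in (View.CC, View.MLO):
            pixels, mask = _render_view(spec, rng, cancer, artifact)
            views[view] = Mammogram(
                pixels=pixels,
                patient_id=pid,
                laterality=Laterality.LEFT,
                view=view,
                pixel_spacing_mm=spec.pixel_spacing_mm,
                bit_depth=12,
                label=label,
            )
            masks[view] = mask
        cases.append(
            PhantomCase(
                patient_id=pid,
                label=label,
                cc=views[View.CC],
                mlo=views[View.MLO],
                lesion_mask_cc=masks[View.CC],
                lesion_mask_mlo=masks[View.MLO],
                has_artifact=artifact,
            )
        )
    return cases


def strip_artifact(case: PhantomCase, band_px: int) -> PhantomCase:
    """Crop the chest-wall band from both views (and their lesion masks)."""
    return PhantomCase(
        patient_id=case.patient_id,
        label=case.label,
        cc=remove_edge_artifact(case.cc, band_px),
        mlo=remove_edge_artifact(case.mlo, band_px),
        lesion_mask_cc=case.lesion_mask_cc[:, band_px:].copy(),
        lesion_mask_mlo=case.lesion_mask_mlo[:, band_px:].copy(),
        has_artifact=False,
    )


def biased_pair(spec: PhantomSpec) -> tuple[list[PhantomCase], list[PhantomCase]]:
    """The same patient stream rendered with and without the edge artifact.

    The first dataset carries label-correlated artifacts per the spec's
    class-conditional probabilities; the second is the identical cohort
    after cropping the chest-wall band from every image, for the paired
    shortcut-learning experiment. Labels are identical across the pair.
    """
    if spec.artifact_prob_cancer == 0.0 and spec.artifact_prob_noncancer == 0.0:
        raise ValueError("biased_pair requires non-zero artifact probabilities")
    biased = generate_dataset(spec)
    clean = [strip_artifact(c, spec.artifact_band_px) for c in biased]
    return biased, clean


def multimodal_image(case: PhantomCase) -> MultimodalImage:
    """CC-over-MLO concatenation of one phantom case."""
    return concat_views(case.cc, case.mlo)


def multimodal_lesion_mask(case: PhantomCase) -> np.ndarray:
    """Lesion mask aligned with :func:`multimodal_image` (CC rows on top)."""
    return np.vstack([case.lesion_mask_cc, case.lesion_mask_mlo])


# ---------------------------------------------------------------------------
# on-disk round trip in the imaging module's input format


def write_dataset(cases: list[PhantomCase], outdir: str | Path, write_masks: bool = True) -> Path:
    """Write 16-bit PNGs (12-bit raw range) plus the labels CSV.

    Layout: ``<outdir>/images/<pid>_<view>.png``, binary lesion masks under
    ``<outdir>/masks/``, and ``<outdir>/labels.csv`` with columns
    patient_id, laterality, view, label, path.
    """
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    if write_masks:
        (outdir / "masks").mkdir(exist_ok=True)
    records = []
    for case in cases:
        for mam, mask in (
            (case.cc, case.lesion_mask_cc),
            (case.mlo, case.lesion_mask_mlo),
        ):
            name = f"{case.patient_id}_{mam.view.value}.png"
            raw = np.round(mam.pixels * 4095).astype(np.uint16)
            Image.fromarray(raw).save(outdir / "images" / name)
            if write_masks:
                Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(
                    outdir / "masks" / name
                )
            records.append(
                {
                    "patient_id": case.patient_id,
                    "laterality": mam.laterality.value,
                    "view": mam.view.value,
                    "label": mam.label.value,
                    "path": f"images/{name}",
                }
            )
    pd.DataFrame(records).to_csv(outdir / "labels.csv", index=False)
    return outdir


def read_dataset(root: str | Path, bit_depth: int = 12) -> list[PhantomCase]:
    """Load a :func:`write_dataset` directory back into phantom cases."""
    from PIL import Image

    from .imaging import load_image

    root = Path(root)
    table = pd.read_csv(root / "labels.csv")
    cases = []
    for pid, group in table.groupby("patient_id", sort=True):
        views = {}
        masks = {}
        for _, row in group.iterrows():
            mam = load_image(
                root / row["path"],
                bit_depth,
                patient_id=row["patient_id"],
                laterality=row["laterality"],
                view=row["view"],
                label=row["label"],
            )
            views[mam.view] = mam
            mask_path = root / "masks" / Path(row["path"]).name
            if mask_path.exists():
                masks[mam.view] = np.asarray(Image.open(mask_path)) > 0
            else:
                masks[mam.view] = np.zeros_like(mam.pixels, dtype=bool)
        if View.CC not in views or View.MLO not in views:
            raise ValueError(f"patient {pid} lacks a CC/MLO pair")
        cases.append(
            PhantomCase(
                patient_id=str(pid),
                label=views[View.CC].label,
                cc=views[View.CC],
                mlo=views[View.MLO],
                lesion_mask_cc=masks[View.CC],
                lesion_mask_mlo=masks[View.MLO],
                has_artifact=False,
            )
        )
    return cases
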