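"""End-to-end phantom experiments: lesion recovery and artifact-bias study.

These drive the full pipeline — phantom generation, multimodal
concatenation, bagging, training, evaluation, heatmap scoring — under the
package's desk-scale study conditions, and are what the acceptance script
and the deepest tests run.

The bias study mirrors the shortcut-learning analysis: when a bright
chest-wall edge band co-occurs with the cancer label (P(artifact|cancer)
high, P(artifact|non-cancer) low), the attention module latches onto the
band; cropping the band from every image redirects attention to tissue
with diagnostic value and improves generalisation to artifact-free data.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .bagging import Bag, build_bag
from .evaluation import MetricsReport, roc_auc
from .extractors import TinyConvExtractor
from .heatmap import edge_attention_mass, localization_score, render_heatmap
from .synthetic import PhantomCase, PhantomSpec, biased_pair, generate_dataset, multimodal_image, multimodal_lesion_mask
from .training import AttentionMIL, TrainConfig, make_folds


def bags_from_cases(
    cases: list[PhantomCase],
    patch_size: int = 64,
    overlap: float = 0.5,
    threshold: float = 0.75,
) -> tuple[list[Bag], np.ndarray, list[np.ndarray]]:
    """Multimodal (CC over MLO) bags, labels, and aligned lesion masks."""
    bags, labels, masks = [], [], []
    for case in cases:
        img = multimodal_image(case)
        bags.append(build_bag(img, patch_size, overlap, threshold))
        labels.append(case.label.binary)
        masks.append(multimodal_lesion_mask(case))
    return bags, np.array(labels), masks


def _split_indices(cases, fold):
    pids = {c.patient_id: i for i, c in enumerate(cases)}
    return (
        [pids[p] for p in fold.train_patients],
        [pids[p] for p in fold.val_patients],
        [pids[p] for p in fold.test_patients],
    )


def train_on_cases(
    cases: list[PhantomCase],
    train_seed: int,
    *,
    max_epochs: int = 30,
    patch_size: int = 64,
    overlap: float = 0.5,
    extractor: TinyConvExtractor | None = None,
    config: TrainConfig | None = None,
):
    """Fit on fold 1 of a 5-fold patient-wise split; return results + splits."""
    bags, labels, masks = bags_from_cases(cases, patch_size, overlap)
    fold = make_folds({c.patient_id: c.label for c in cases}, n_folds=5, seed=train_seed)[0]
    tr, va, te = _split_indices(cases, fold)
    cfg = config or TrainConfig(max_epochs=max_epochs, seed=train_seed)
    extractor = extractor or TinyConvExtractor()
    model = AttentionMIL(
        [bags[i] for i in tr], labels[tr], extractor=extractor, config=cfg
    )
    results = model.fit([bags[i] for i in va], labels[va])
    return results, bags, labels, masks, (tr, va, te)


def run_recovery(
    n_patients: int = 200,
    data_seed: int = 42,
    train_seed: int = 0,
    max_epochs: int = 30,
) -> dict:
    """Lesion-recovery study on the default unbiased phantom cohort.

    Trains the default desk-scale model and reports held-out test AUC and
    the mean inside/outside lesion attention ratio on cancer test cases.
    """
    spec = PhantomSpec(n_patients=n_patients, seed=data_seed)
    cases = generate_dataset(spec)
    results, bags, labels, masks, (tr, va, te) = train_on_cases(
        cases, train_seed, max_epochs=max_epochs
    )
    test_scores = results.predict_proba([bags[i] for i in te])
    test_auc = roc_auc(test_scores, labels[te])
    ratios = []
    for i in te:
        if labels[i] == 1 and masks[i].any():
            hm = render_heatmap(bags[i], results.attention(bags[i]), bags[i].source_shape)
            ratios.append(localization_score(hm, masks[i])[2])
    finite = [r for r in ratios if np.isfinite(r)]
    return {
        "test_auc": float(test_auc),
        "localization_ratio_mean": float(np.mean(ratios)) if ratios else np.nan,
        "localization_ratio_median": float(np.median(finite)) if finite else np.nan,
        "n_test": len(te),
        "n_cancer_test": len(ratios),
        "best_epoch": results.best_epoch,
        "results": results,
    }


def run_bias_study(
    n_patients: int = 200,
    data_seed: int = 42,
    train_seed: int = 0,
    max_epochs: int = 30,
    artifact_prob_cancer: float = 0.9,
    artifact_prob_noncancer: float = 0.1,
) -> dict:
    """Paired artifact-bias experiment.

    One model is trained on the artifact-biased rendering of the cohort and
    one on the identical cohort with the chest-wall band cropped. Reports
    mean edge-band attention mass (on artifact-carrying biased test images
    for the biased model; on the same cases' clean images for the clean
    model), each alongside the band's share of the image area, plus both
    models' AUC on the artifact-free test set.
    """
    spec = PhantomSpec(
        n_patients=n_patients,
        seed=data_seed,
        artifact_prob_cancer=artifact_prob_cancer,
        artifact_prob_noncancer=artifact_prob_noncancer,
    )
    biased_cases, clean_cases = biased_pair(spec)
    band = spec.artifact_band_px

    res_b, bags_b, labels, _, (tr, va, te) = train_on_cases(biased_cases, train_seed, max_epochs=max_epochs)
    res_c, bags_c, labels_c, _, _ = train_on_cases(clean_cases, train_seed, max_epochs=max_epochs)
    assert np.array_equal(labels, labels_c)  # same patient stream

    art_te = [i for i in te if biased_cases[i].has_artifact]
    mass_biased = [
        edge_attention_mass(
            render_heatmap(bags_b[i], res_b.attention(bags_b[i]), bags_b[i].source_shape),
            band,
        )
        for i in art_te
    ]
    mass_clean = [
        edge_attention_mass(
            render_heatmap(bags_c[i], res_c.attention(bags_c[i]), bags_c[i].source_shape),
            band,
        )
        for i in art_te
    ]
    auc_biased_model_clean_data = roc_auc(
        res_b.predict_proba([bags_c[i] for i in te]), labels[te]
    )
    auc_clean_model_clean_data = roc_auc(
        res_c.predict_proba([bags_c[i] for i in te]), labels[te]
    )
    width_biased = bags_b[te[0]].source_shape[1]
    width_clean = bags_c[te[0]].source_shape[1]
    return {
        "edge_mass_biased": float(np.mean(mass_biased)),
        "edge_mass_clean": float(np.mean(mass_clean)),
        "band_area_fraction_biased": band / width_biased,
        "band_area_fraction_clean": band / width_clean,
        "auc_biased_model": float(auc_biased_model_clean_data),
        "auc_clean_model": float(auc_clean_model_clean_data),
        "n_artifact_test": len(art_te),
    }
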