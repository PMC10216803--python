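# Methods

## Problem and model

`mammil` classifies full-field digital mammograms (FFDM) that carry only an
image-level label (cancer / non-cancer) and, as a by-product, localises the
evidence for that label. The supervision regime is multiple instance
learning (MIL): each case — one view, or the vertical concatenation of a
breast's CC and MLO views — is cut into K square patches ("instances") that
together form a "bag" inheriting the image label. No patch is ever labelled.

Each patch k is encoded by a frozen convolutional feature extractor into
h_k ∈ R^M, reduced by an FC + ReLU layer to h'_k ∈ R^256, and scored by a
gated attention network

    a_k = softmax_k( wᵀ ( tanh(V h'_k) ⊙ sigmoid(U h'_k) ) ),

with learnable w ∈ R^L, V, U ∈ R^{L×256} (L = 256 by default). The tanh
branch alone is close to linear on (−1, 1); the sigmoid gate restores
expressiveness, and the softmax makes the weights a probability vector so
bags of different sizes are comparable. The bag embedding is the attention
average B = Σ_k a_k h'_k, classified by an FC layer with 256 hidden units
and a sigmoid output into a probability; scores strictly above the
threshold (default 0.5) are called cancer.

Because positive bags typically contain few truly positive patches, the
attention is clustering-constrained: per bag, the k = 8 highest- and k = 8
lowest-scoring patches (clamped to ⌊K/2⌋ each for small bags, ties to the
lower patch index) form positive/negative evidence sets with pseudo-labels
1/0, and a shared two-way instance classifier (256 hidden units) is trained
on them with cross-entropy. The training objective is
0.7 · BCE(bag) + 0.3 · CCE(instances). At inference the per-patch weights
a_k are rendered into a heatmap: accumulated over each patch's square
footprint, averaged per pixel by coverage count, and min–max scaled over
covered pixels (background stays 0; a constant covered region maps to 1 so
a single-patch map remains visible).

## Preprocessing

Raw intensities are divided by the bit-depth full scale (2^12 − 1 or
2^8 − 1), never per-image min–max, so contrast is comparable across images
and raw 0 maps to exactly 0.0. Images are normalised chest-wall-left (the
brighter of the two outermost 5 % column bands marks the chest wall), and
single-channel data is repeated to 3 channels for CNN input. The collimator
"edge" artifact — a high-intensity vertical bar at the chest-wall edge — is
removed, when requested, by deleting a 20-pixel-wide column band at that
edge (band width configurable). Halving resolution uses 2×2 block
averaging with floor dimensions: it preserves constants, keeps values in
[0, 1], needs no interpolation seed, and doubles the pixel spacing.
CC + MLO fusion stacks the CC view on top of the MLO view row-wise
(3518 + 3518 = 7036 rows at 2800 columns for full-scale FFDM); width
mismatches after one-sided artifact cropping are resolved by zero-padding
the narrower view on the non-chest-wall side.

Tiling starts at the top-left corner with stride
round((1 − overlap) · patch_size) per axis; positions that would overhang
the image are dropped so all patches share one size. A patch joins the bag
iff at least 75 % of its pixels are strictly positive (inclusive boundary);
the rule is evaluated once at bag construction, before any augmentation.
An image where no patch survives is rejected with a diagnostic rather than
yielding an empty bag. Coordinates are row-major, 0-based, half-open.

Training-time augmentation operates per instance, in order: a uniformly
drawn right-angle rotation (p = 1), horizontal flip (p = 0.5), vertical
flip (p = 0.5), and a random crop with area scale uniform in [0.8, 1.0]
resized back to the patch size (p = 1). Validation and test patches are
never transformed.

## Training regime

SGD with momentum 0.9, learning rate 0.001 decayed by the constant factor
0.9 every 10 epochs, L2 weight decay 0.001 on weight matrices (biases
exempt, as is common practice), batch size 1, dropout 0.25 after the
attention module's FC layers (training only, inverted scaling). Gradients
are accumulated over 8 consecutive bags per parameter update — summed, as
backward-pass accumulation at batch size 1 does, which is what "imitating
batch size 8" amounts to in practice; the final short group of an epoch
still triggers an update with its proportionally smaller summed gradient.
Class imbalance is met with weighted random oversampling: each training
draw picks a bag with probability inversely proportional to its class
frequency, so the expected draw is class-balanced. Training runs at least
20 and at most 100 epochs with 20-epoch patience on the validation
criterion (validation loss by default, AUC optional; the best-validation
parameters are returned). Cross-validation is 5-fold, stratified by class
at the patient level, with every image of a patient confined to one subset;
each fold's non-test patients split 7 : 1 into train and validation,
giving the 70/10/20 structure. A single run seed drives independent
sub-streams (initialisation, sampler, dropout, augmentation) via spawned
seed sequences, so runs are exactly reproducible.

The whole network and its gradients are implemented in NumPy; the backward
pass is analytic, layer by layer, and is verified against central finite
differences to ~1e-6 in the test suite. Evidence-selection indices are
treated as constants in the backward pass (the sort is piecewise constant
in the scores). Feature extractors are frozen; with augmentation disabled
(the default) each bag's feature matrix is computed once and cached, which
is exact and makes desk-scale training run in seconds. The built-in
extractor is a fixed random-weight conv net (3→8 conv, 2×2 max-pool,
8→32 conv, pool, global average pooling; He-initialised from a dedicated
seed) whose per-feature standardisation statistics are calibrated once on
the training split and then frozen into the checkpoint — the analogue of
frozen BatchNorm statistics in a pretrained backbone. Large pretrained
CNNs plug in through the same extractor interface but are outside the test
scope. Checkpoints are a `.npz` of named parameter arrays (bit-exact round
trip) plus a JSON sidecar with architecture metadata. Transfer learning
re-uses a source checkpoint as the initialisation of a new fit;
the load is all-or-nothing with shape checking per parameter.

## Evaluation

Accuracy, precision, recall and F1 come from the confusion counts with the
strict rule "cancer iff score > threshold" (a score exactly at the
threshold is non-cancer). Zero-denominator metrics report 0 with a warning
so fold aggregation stays total. AUC-ROC is the Mann–Whitney pair
statistic with half credit for ties, computed with midranks. The operating
threshold can be chosen by maximising Youden's J = sensitivity +
specificity − 1 over midpoints of consecutive distinct scores (plus
predict-all/none sentinels), ties resolving to the smallest threshold.
Cross-validation results are reported as mean ± sample (n−1) standard
deviation, AUC to 3 decimals and percentage metrics to 1 decimal.

## Synthetic phantom cohort

The generator emulates the statistical structure the pipeline depends on,
not radiographic realism: a smooth noisy half-ellipse of tissue (base
intensity U[0.35, 0.50] per view, Gaussian texture σ = 0.05, clipped
strictly positive) flush with the chest-wall edge on an exactly-zero
background; for cancer cases 1–3 bright lesion discs with quadratic radial
falloff (radius 6–14 px, intensity lift U[0.25, 0.45]) placed independently
per view inside the breast, with pixel masks recorded; optionally a
full-height band of constant intensity 0.95 over the 20 chest-wall columns,
drawn per patient with class-conditional probabilities to reproduce an
artifact–label correlation. Default desk-scale geometry is 256 × 192 px
with patch 64 and overlap 0.5, which preserves every geometric mechanism
(tiling, the 75 % rule, row concatenation) at a size where a full training
run takes seconds; full FFDM dimensions are supported. Each patient draws
from a spawned child seed, so the cohort is reproducible and
order-independent. What passing tests on phantoms does *not* show:
robustness to real parenchymal texture, pectoral muscle, spiculated or
low-contrast lesions, or scanner variation — the phantom's lesions are
deliberately learnable so that recovery failures indicate pipeline defects
rather than task difficulty. With lesions disabled the two classes are
statistically identical, providing a null dataset for over-fitting checks.

## Study conditions and problem sizes

The bundled end-to-end studies run on 200-patient cohorts (default
generator seed), the built-in extractor, multimodal bags (patch 64,
overlap 0.5), and the default training regime capped at 30 epochs — sizes
chosen so a single fit takes ~20 s on one CPU core while leaving the
learning dynamics (attention sharpening after the bag loss starts to
saturate) clearly visible. The lesion-recovery study reports held-out test
AUC and the mean inside/outside lesion attention ratio on cancer test
cases. The bias study renders the same patient stream twice — once with
the artifact correlated with the label (P = 0.9 | cancer, 0.1 | non-cancer)
and once with the band cropped — and compares edge-band attention mass
(measured on artifact-carrying test cases) and generalisation to
artifact-free test data.

One geometric caveat discovered with the oracle analysis: because the
breast is flush with the chest-wall edge, covered pixels concentrate in the
band columns, so the edge-band attention mass of a *perfectly*
lesion-focused model is ~0.22 on clean phantoms — about 1.9× the band's
share of the image area (uniform attention gives ~0.20). Edge-mass readings
should therefore be compared against this coverage-weighted floor, not
against the raw band/width fraction; the bias study reports both the
masses and the band fractions so either comparison can be made.

## Known limitations

* The built-in extractor is a random projection: adequate for bright,
  locally contrasting phantom lesions, not for subtle real-world features.
* Heatmap resolution is bounded by patch size and overlap; localisation is
  coarse by construction.
* Augmented training bypasses the feature cache and is roughly an order of
  magnitude slower; it is exercised by tests but off by default.
* Binary classification only; no multi-class evidence branches.
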