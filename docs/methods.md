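# Methods

## Scope and model

`cytoscreen` implements a two-stage screening pipeline for cervical
liquid-based cytology: (i) nucleus detection and 3-class classification
on single-field images, and (ii) patient-level normal-vs-positive
classification from per-patient cell counts. Around stage (i) it
implements two annotation protocols — conventional (label everything,
train once: model T1) and active learning in the
pre-label-and-revise sense (train → auto-label the next batch → revise →
retrain: models A1…Ak) — with a simulated annotator and an explicit
effort ledger. Everything runs at desk scale on seeded synthetic data;
no GPU, network or external dataset is involved.

The taxonomy follows cytopathology practice: **yin** (normal squamous
nuclei: medium size, small nucleocytoplasmic ratio, pale), **yin-yang**
(suspected cells: slightly enlarged, deeply but evenly stained, neat
edges), **yang** (diseased cells: large, dark, irregular nuclei).
Because nearly all discriminative signal is nuclear and nuclei overlap
far less than cytoplasm, annotations are nucleus polygons only.

## Synthetic data generator

`synthcyto` draws each nucleus as an ellipse whose radius is perturbed
by random radial Fourier harmonics (orders 2–5) scaled by a per-class
irregularity parameter, filled at a per-class staining luminance with a
haematoxylin-like tint, over a pale cytoplasm-toned background with a
faint halo whose width tracks the nucleocytoplasmic-ratio proxy; mild
Gaussian blur and sensor noise finish the render. Defaults
(radius mean 7 / 10 / 14 px, luminance 150 / 110 / 70, irregularity
0.06 / 0.12 / 0.35 for yin / yin-yang / yang) encode the qualitative
class criteria: diseased nuclei are the largest, darkest and most
irregular. The default class mix (0.990, 0.006, 0.004) keeps the
abnormal:normal imbalance in the 1:100–1:1000 band.

Nuclei are placed by rejection sampling under a pairwise-IoU cap
(default 0: disjoint), using a bounding-circle prefilter so the exact
polygon test is rarely needed; a bounded number of attempts (600) turns
infeasible packings into an explicit error. All randomness flows from
one seed through splittable `SeedSequence` streams, so every artifact
(pixels, polygons, cohort tables) is bit-reproducible.

Cohorts assign exactly `round(prevalence × n_patients)` positive
patients; positives draw yang cells at `abnormal_cell_rate` (default
0.01) per cell, negatives draw none. Field geometry for cohorts is
sampled without rasterization (the annotations alone determine the
count features); pixels are rendered only where a detector actually
runs. Default cohort density (6 fields × 70 cells ≈ 420 cells/patient)
keeps the probability that a positive patient shows zero yang cells
near 1–2%, which is the irreducible error floor of count-based patient
classification at this scale.

What the generator does **not** emulate: overlapping/adherent cell
clusters, mucus, debris and scanner artifacts, staining batch effects,
and the within-class morphology continuum of real smears. Tests passing
on this generator therefore demonstrate the correctness and internal
consistency of the pipeline machinery — not clinical-grade performance
on real whole-slide images, where published figures depend on a deep
segmentation backbone and a real cohort.

## Revision oracle and cost ledger

The simulated pathologist greedily matches pre-labels to ground truth
at IoU 0.5. A matched pre-label with the correct class and contour IoU
≥ 0.95 is *accepted*: it is emitted in ground-truth geometry at zero
cost, modeling a reviewer who signs off on an adequate contour (and
making the perfect-oracle limit exact: fidelity = miss-add rate = 1
reproduces ground truth verbatim). Erroneous pre-labels are corrected
with probability `revision_fidelity` (one fix each, covering class
and/or contour), missed nuclei are drawn from scratch with probability
`miss_add_rate` (one draw each), spurious pre-labels are deleted (one
fix each). Costs default to 5 units per drawn polygon and 1 per fix — a
click-count proxy chosen because wall-clock labeling hours are not
reproducible; only cost *ratios* between protocols are interpreted.

## Annotation protocols

Both protocols hold out the same seeded test set. Conventional: one
training round on fully manual labels; cost = draw cost × annotation
count. Active: round 1 manual; round k > 1 pre-labels its batch with
model A(k−1), revises, and retrains warm-started from A(k−1) on all
revised data accumulated so far (cumulative mode is the default because
it produces the expected monotone improvement across rounds; a
batch-only flag exists since the alternative reading is defensible).
Splits are uniform random without stratification, matching a protocol
that samples images blindly. Batch sizes default to (100, 200, 150)
with a 50-image test set; the test suite and acceptance script scale
these to (14, 20, 16) + 10 on 60-field datasets, which preserves every
structural property being asserted while keeping a full 5-seed sweep
inside a few CPU-minutes.

## Detector backend

The reference backend is deliberately classical so that it is exactly
reproducible and fast: (1) foreground proposal by Otsu threshold on
inverted luminance, with a contrast floor (20 luminance units below the
field median) so blank fields yield nothing; (2) distance-transform
watershed (marker spacing 8 px ≈ a yin radius) to split touching blobs;
(3) per-blob features: area, equivalent diameter, mean and minimum
intensity, eccentricity, solidity, boundary roughness
(perimeter²/4π·area); (4) a multinomial logistic classifier fitted with
inverse-frequency class weights (capped at 100, majority class
normalized to 1). Training labels come from matching blobs to
ground-truth polygons at mask IoU ≥ 0.5. Detections carry the blob
contour, the full class-probability vector, and pass score-descending
NMS at IoU 0.5 (ties broken by blob order). Models serialize to a
single archive and reload to bit-identical predictions. The
train/detect/save/load contract is backend-agnostic; a CNN
segmentation model can be slotted in without touching the protocol,
evaluation or patient modules.

The weighted cross-entropy, region-proposal and mask losses are also
exposed as standalone functions (`cellnet.classification_loss`,
`rpn_loss`, `mask_loss`, `total_loss`) with the conventional
normalizations (λ = 1, N_cls = anchor count, N_reg = positive-anchor
count — none of these are dictated by the problem, so they are
documented defaults) and an ε = 1e-12 clamp inside logarithms.

## Evaluation conventions

- Matching: greedy one-to-one in descending detection score at IoU 0.5;
  unmatched truth enters a dedicated *missing* column; spurious
  detections are tallied separately (they enter AP as false positives
  but not the screening tallies, matching how published confusion
  tables in this setting omit a spurious row).
- Missing-as-predicted-negative: a missed cell is a false negative when
  its true class is in the positive set and a true negative otherwise.
  This single convention reproduces, to two decimals, all ten
  reproducible entries of the published T1/A3 performance table bundled
  in `evalkit` (both composite columns completely, and per-class yin
  sensitivity/accuracy). The two per-class yin "specificity" entries in
  that table (69.95, 66.37) are not specificities under any standard
  convention; they coincide exactly with the **NPV** of the yin tally,
  which `binary_metrics` also reports — the discrepancy is surfaced
  rather than matched.
- PR curves use the raw rectangle rule Σ(Rₙ−Rₙ₋₁)Pₙ over unique score
  thresholds, uninterpolated. The classification PR-AUC counts a
  detection as correct only if it is matched *and* carries the right
  class, with recall against all ground-truth nuclei.
- G-Mean is computed with the square root (√(recall·specificity)).
- Zero-denominator metrics are returned as `None` with a warning, never
  NaN.
- Friedman uses average ranks with the tie-corrected chi-square
  statistic; Wilcoxon signed-rank uses the exact null distribution for
  ≤ 25 nonzero pairs (zeros dropped) with Holm adjustment across pairs.

## Patient stage

The seven features are age, the three counts, `yang_ratio`,
`combined_yang`, `combined_yang_ratio`. Cross-validation is stratified
by outcome (with a 189/211 class balance, unstratified folds add
avoidable variance), folds are shared across methods so comparisons are
paired, and the operating point for accuracy-type metrics is a fixed
0.5 probability threshold (AUC is threshold-free). Gradient boosting
uses split-gain importances; hyperparameters are fixed, documented
defaults (RF: 300 trees; GBT: 200 trees, depth 3, learning rate 0.1;
SVM: RBF with Platt calibration) since nothing in the problem pins
them.

## Numerical and degenerate-input choices

Polygon rasterization uses the pixel-center even-odd rule (a pixel is
inside iff its center is strictly interior), which is brute-force
verifiable; mask-to-polygon tracing follows the 0.5-level contour so
convex blobs round-trip exactly. Augmentation applies exactly one of
three families per image (flip, mild affine within ±25° rotation /
0.8–1.2 scale / ±8° shear / ±10% translation, or contrast via gamma
0.7–1.4 / linear ±30%); affine-transformed polygons are kept verbatim
when fully inside the field, clipped otherwise, and dropped with a
logged warning below 20% surviving area. Single-class training sets
produce a constant-predictor model with a logged warning rather than an
error; classifiers with a single-class *patient* cohort raise, because
no meaningful CV exists.

## Known limitations

- The classical detector saturates on the synthetic separability regime
  and is not expected to transfer to real stained smears; it exists to
  exercise the protocol and evaluation machinery deterministically.
- The revision oracle models per-nucleus edits as independent
  Bernoulli events; real reviewer behaviour is correlated within an
  image and varies with fatigue and case difficulty.
- Patient-stage results on synthetic cohorts bound what the count
  features can do when the generator's assumptions hold; real-cohort
  performance additionally depends on detector errors compounding into
  the counts.
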