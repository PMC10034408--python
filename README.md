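# cytoscreen

Desk-scale tooling for two-stage, AI-assisted cervical cancer screening
from liquid-based cytology (ThinPrep/TCT) field images.

Routine cytology screening asks a pathologist to find a handful of
abnormal squamous cells among thousands of normal ones. The pipeline
implemented here mirrors the machine-assisted version of that workflow:

1. **Cell stage** — nuclei in each single-field image are detected,
   segmented and classified into three classes: normal (**yin**),
   suspected/ecological (**yin-yang**, slightly enlarged nuclei with
   deep but even staining) and diseased (**yang**, large, dark,
   irregular nuclei with high nucleocytoplasmic ratio).
2. **Patient stage** — the per-patient cell counts are reduced to seven
   features (age; the three class counts; `yang_ratio` = yang / total;
   `combined_yang` = yin-yang + yang and its ratio), and four classifier
   families (logistic regression, RBF SVM, random forest,
   gradient-boosted trees) predict normal vs. positive under stratified
   10-fold cross-validation.

Around the cell stage the package implements the **pre-label-and-revise
active-learning annotation protocol**: a small first batch is annotated
manually, a model is trained, the next batch is auto-labeled by the
model and merely *revised* by the annotator, and so on (models A1, A2,
A3 over batches of 100/200/150 by default), against the conventional
protocol in which every image is annotated from scratch before a single
model (T1) is trained. A simulated pathologist with configurable
fidelity replaces the human, and an explicit cost ledger (5 effort units
per polygon drawn, 1 per label/contour fix) replaces wall-clock labeling
hours, so the two protocols can be compared reproducibly.

Because no public image data accompanies this problem, a first-class
synthetic generator (`cytoscreen.synthcyto`) produces seeded cytology
fields — radially Fourier-perturbed elliptical nuclei with
class-conditional size, staining intensity and boundary irregularity on
a pale cytoplasm-toned background — together with exact polygon ground
truth, patient cohorts at a chosen prevalence, and the revision oracle.

## Core quantities

Detection quality is scored by greedy IoU-0.5 matching into a 3-class ×
(3 + missing) confusion matrix, and screening metrics are computed under
the *missing-as-predicted-negative* convention (a missed nucleus counts
as predicted negative):

- sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
  accuracy, PPV, NPV; F1 = 2PR/(P+R); G-Mean = √(sensitivity·specificity)
- PR-curve area by the uninterpolated rectangle rule
  AUC = Σₙ (Rₙ − Rₙ₋₁) Pₙ (no 11-point smoothing)
- mAP / mAR = unweighted class means of per-class AP (rectangle rule)
  and final recall at IoU 0.5
- Friedman rank tests and pairwise exact Wilcoxon signed-rank tests
  (Holm-adjusted) compare classifiers across shared CV folds.

The detection training losses are provided as standalone, unit-verified
components: the region-proposal loss
L = (1/N_cls) Σᵢ L_cls(pᵢ, pᵢ*) + (λ/N_reg) Σᵢ pᵢ* L_reg(tᵢ, tᵢ*)
with smooth-L1 regression gated on positive anchors, the class-weighted
cross-entropy L_cls = −Σ_c ω_c y_c log p_c used to counter the ~1:100 to
1:1000 normal:abnormal imbalance (inverse-frequency weights, capped),
and the average binary cross-entropy mask loss.

The default detector backend is a deterministic classical pipeline
(Otsu thresholding on inverted luminance → distance-transform watershed
→ per-blob morphology features → weighted multinomial logistic
classifier) behind a train/detect/save/load contract that a deep
backend can implement instead.

## Worked example

```python
from cytoscreen.synthcyto import SceneSpec, generate_field
from cytoscreen.cellnet import train_detector
from cytoscreen.annotio import LabelSet
from cytoscreen.evalkit import match_detections, binary_metrics

specs = [SceneSpec(n_cells=30, class_mix=(0.8, 0.1, 0.1), seed=s) for s in range(9)]
fields = [generate_field(s) for s in specs]
labelsets = [LabelSet(a[0].image_id, 256, 256, a) for _, a in fields]

model = train_detector([img for img, _ in fields[:8]], labelsets[:8], seed=0)
dets = model.detect(fields[8][0], labelsets[8].image_id)
_, cm = match_detections(labelsets[8], dets)
print(cm.counts)
print(binary_metrics(cm, ["yin-yang", "yang"]))
```

prints the held-out field's confusion matrix and abnormal-vs-normal
screening metrics — on this separable fixture the matrix is diagonal
and every metric is 100.0:

```
[[24  0  0  0]
 [ 0  2  0  0]
 [ 0  0  4  0]]
{'sensitivity': 100.0, 'specificity': 100.0, 'accuracy': 100.0,
 'ppv': 100.0, 'npv': 100.0}
```

The same pipeline is scriptable from the shell:

```bash
cytoscreen simulate --out data --seed 1 --n-images 100
cytoscreen run-protocol --data data --out runs --seed 1 --strategy both \
    --round-sizes 20,40,30 --test-size 10
cytoscreen diagnose --out dx --seed 1
```

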