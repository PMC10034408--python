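"""Nucleus detection and 3-class classification.

Two independent layers live here:

* the detection/segmentation training losses as standalone, unit-testable
  functions -- the region-proposal loss (binary objectness cross-entropy
  plus smooth-L1 box regression gated on positive anchors), the
  class-weighted categorical cross-entropy used to counter the extreme
  normal:abnormal imbalance, the average binary cross-entropy mask loss,
  and their sum;

* a pluggable detector backend.  The reference backend is a classical,
  fully deterministic pipeline suited to desk-scale synthetic fields:
  Otsu thresholding on inverted luminance proposes stained foreground,
  a distance-transform watershed splits touching nuclei, and a weighted
  multinomial logistic classifier assigns each blob to yin / yin-yang /
  yang from morphology features (area, equivalent diameter, stain
  intensity, eccentricity, solidity, boundary roughness).  A deep
  backend can be slotted in behind the same train/detect/save/load
  contract without touching any other module.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import feature, filters, measure, segmentation
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from cytoscreen.annotio import CLASSES, LabelSet, NucleusAnnotation, mask_to_polygon

logger = logging.getLogger(__name__)

_EPS = 1e-12  # clamp inside logs; probabilities of exactly 0 are warned about


# ---------------------------------------------------------------------------
# Loss components
# ---------------------------------------------------------------------------

def smooth_l1(x):
    """Robust smooth-L1: ``0.5 x^2`` for |x| < 1, ``|x| - 0.5`` otherwise.

    Continuous, nonnegative, quadratic near zero and linear in the tails.
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1.0, 0.5 * x * x, np.abs(x) - 0.5)
    return float(out) if out.ndim == 0 else out


def classification_loss(p: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """Class-weighted categorical cross-entropy, ``-sum_c w_c y_c log p_c``.

    ``p`` is a probability vector over the classes, ``y`` the one-hot
    truth, ``weights`` the strictly positive per-class weights used to
    up-weight the rare abnormal classes.  Zero iff p puts all mass on
    the true class; linear in the true class's weight.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("p must be a probability vector summing to 1")
    if not (np.isclose(y.sum(), 1.0) and set(np.unique(y)) <= {0.0, 1.0}):
        raise ValueError("y must be one-hot")
    if (weights <= 0).any():
        raise ValueError("class weights must be strictly positive")
    if p[y.astype(bool)] < _EPS:
        warnings.warn("true-class probability is ~0; clamping inside log", RuntimeWarning)
    return float(-(weights * y * np.log(np.clip(p, _EPS, 1.0))).sum())


def mask_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Average binary cross-entropy over mask pixels."""
    pred = np.clip(np.asarray(pred, dtype=float), _EPS, 1.0 - _EPS)
    truth = np.asarray(truth, dtype=float)
    return float(-np.mean(truth * np.log(pred) + (1.0 - truth) * np.log(1.0 - pred)))


def rpn_loss(
    p: np.ndarray,
    p_star: np.ndarray,
    t: np.ndarray,
    t_star: np.ndarray,
    lam: float = 1.0,
    n_cls: int | None = None,
    n_reg: int | None = None,
) -> tuple[float, float, float]:
    """Region-proposal loss: objectness cross-entropy + gated box regression.

    Parameters
    ----------
    p : per-anchor predicted object probability.
    p_star : per-anchor ground-truth indicator (1 positive, 0 negative).
    t, t_star : (n, 4) predicted and ground-truth box parameterizations.
    lam : balance weight between the two terms (default 1).
    n_cls, n_reg : normalizers; default to the anchor count and the
        positive-anchor count.

    Returns ``(cls_term, reg_term, total)`` where the regression sum runs
    only over positive anchors (``p_star`` gates it), each anchor
    contributing the smooth-L1 of its four coordinate residuals.
    """
    p = np.asarray(p, dtype=float)
    p_star = np.asarray(p_star, dtype=float)
    t = np.atleast_2d(np.asarray(t, dtype=float))
    t_star = np.atleast_2d(np.asarray(t_star, dtype=float))
    if not (len(p) == len(p_star) == len(t) == len(t_star)):
        raise ValueError("anchor arrays must have equal length")
    if not set(np.unique(p_star)) <= {0.0, 1.0}:
        raise ValueError("p_star entries must be 0 or 1")
    if n_cls is None:
        n_cls = len(p)
    if n_reg is None:
        n_reg = int(p_star.sum())
    if n_cls == 0 or n_reg == 0:
        raise ValueError("normalizers n_cls and n_reg must be nonzero")
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    l_cls = -(p_star * np.log(pc) + (1.0 - p_star) * np.log(1.0 - pc))
    l_reg = smooth_l1(t - t_star).sum(axis=1)
    cls_term = float(l_cls.sum() / n_cls)
    reg_term = float(lam * (p_star * l_reg).sum() / n_reg)
    return cls_term, reg_term, cls_term + reg_term


def total_loss(l_cls: float, l_reg: float, l_mask: float) -> float:
    """Total training loss: sum of classification, regression and mask terms."""
    return float(l_cls) + float(l_reg) + float(l_mask)


# ---------------------------------------------------------------------------
# Imbalance handling
# ---------------------------------------------------------------------------

def compute_class_weights(counts: Sequence[int], cap: float = 100.0) -> np.ndarray:
    """Inverse-frequency class weights, min-normalized to 1 and capped.

    ``w_c = min(cap, n_max / n_c)``: the majority class gets weight 1
    and rarer classes proportionally more, up to ``cap``.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts <= 0).any():
        raise ValueError(
            "every class needs a positive count; oversample the training set "
            "so all three classes are represented before weighting"
        )
    return np.minimum(counts.max() / counts, cap)


def oversample_positives(labelsets: Sequence, target_ratio: float = 0.5) -> list:
    """Replicate abnormal-containing images until they reach ``target_ratio``.

    An item is positive when its label set contains any yin-yang or yang
    annotation.  Items may be ``LabelSet`` or ``(image, LabelSet)``
    pairs.  Originals are all retained (in order); positive items are
    appended cyclically, deterministically, until the positive fraction
    is at least the target.
    """
    def _ls(item):
        return item[1] if isinstance(item, tuple) else item

    items = list(labelsets)
    positives = [
        it for it in items
        if any(a.cls in ("yin-yang", "yang") for a in _ls(it).annotations)
    ]
    if not positives:
        raise ValueError("no image contains abnormal cells; cannot oversample")
    if not 0 < target_ratio < 1:
        raise ValueError("target_ratio must be in (0, 1)")
    n, n_pos = len(items), len(positives)
    if n_pos / n >= target_ratio:
        return items
    # minimal k extra positive copies with (n_pos + k) / (n + k) >= target
    k = int(np.ceil((target_ratio * n - n_pos) / (1.0 - target_ratio)))
    out = items + [positives[i % n_pos] for i in range(k)]
    return out


# ---------------------------------------------------------------------------
# Detections and the detector backend
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Detection:
    """One predicted nucleus: polygon, class, and calibrated probabilities."""

    image_id: str
    polygon: np.ndarray
    cls: str
    probabilities: np.ndarray  # over CLASSES, sums to 1

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if not np.isclose(self.probabilities.sum(), 1.0, atol=1e-9):
            raise ValueError("class probabilities must sum to 1")

    @property
    def score(self) -> float:
        """Confidence of the predicted class (max of the vector)."""
        return float(self.probabilities.max())

    def shape(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.polygon).buffer(0)


@dataclass
class DetectorConfig:
    """Configuration of the classical reference detector."""

    min_area: int = 20              # px^2; smaller blobs are noise
    contrast_margin: float = 20.0   # blob must be this much darker than field
    peak_min_distance: int = 8      # watershed marker spacing (~yin radius)
    class_weight_cap: float = 100.0
    nms_iou: float = 0.5
    max_iter: int = 500
    regularization: float = 1.0     # inverse L2 strength of the classifier

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


_FEATURE_NAMES = (
    "area",
    "equivalent_diameter",
    "mean_intensity",
    "min_intensity",
    "eccentricity",
    "solidity",
    "roughness",
)


def _luminance(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return image[..., :3].astype(float).mean(axis=2)
    return image.astype(float)


def _segment_blobs(image: np.ndarray, config: DetectorConfig) -> np.ndarray:
    """Foreground proposal + watershed split; returns a label image."""
    lum = _luminance(image)
    background = float(np.median(lum))
    inverted = background - lum
    pos = inverted[inverted > 0]
    if pos.size < 50:
        return np.zeros(lum.shape, dtype=int)
    thr = filters.threshold_otsu(inverted)
    # require genuinely stained foreground, not sensor noise around Otsu
    thr = max(thr, config.contrast_margin)
    binmask = inverted > thr
    binmask = ndimage.binary_fill_holes(binmask)
    if not binmask.any():
        return np.zeros(lum.shape, dtype=int)
    distance = ndimage.distance_transform_edt(binmask)
    peaks = feature.peak_local_max(
        distance, min_distance=config.peak_min_distance, labels=binmask,
        exclude_border=False,
    )
    markers = np.zeros(lum.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return measure.label(binmask)
    labels = segmentation.watershed(-distance, markers, mask=binmask)
    return labels


def _blob_features(lum: np.ndarray, labels: np.ndarray, config: DetectorConfig):
    """Per-blob morphology features; returns (features, blob masks)."""
    feats, masks = [], []
    background = float(np.median(lum))
    for region in measure.regionprops(labels, intensity_image=lum):
        if region.area < config.min_area:
            continue
        if background - region.intensity_mean < config.contrast_margin:
            continue  # not meaningfully stained vs. the field
        perimeter = max(region.perimeter, 1.0)
        roughness = perimeter**2 / (4.0 * np.pi * region.area)
        feats.append(
            [
                region.area,
                region.equivalent_diameter_area,
                region.intensity_mean,
                region.intensity_min,
                region.eccentricity,
                region.solidity,
                roughness,
            ]
        )
        full = np.zeros(lum.shape, dtype=bool)
        rr0, cc0, rr1, cc1 = region.bbox
        full[rr0:rr1, cc0:cc1] = region.image
        masks.append(full)
    return np.asarray(feats, dtype=float), masks


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


class ReferenceDetector:
    """Classical nucleus detector fulfilling the backend contract.

    ``fit`` segments every training field, matches candidate blobs to
    ground-truth polygons at IoU >= 0.5, and trains a class-weighted
    multinomial logistic classifier on the matched blobs' morphology
    features.  ``detect`` segments a field, classifies each blob, and
    applies score-descending non-maximum suppression at IoU 0.5.
    Everything is deterministic given the seed.
    """

    def __init__(self, config: DetectorConfig | None = None):
        self.config = config or DetectorConfig()
        self.scaler_: StandardScaler | None = None
        self.classifier_: LogisticRegression | None = None
        self.classes_seen_: list[str] = []
        self.class_weights_: np.ndarray | None = None
        self.seed_: int | None = None

    # -- training ----------------------------------------------------------
    def _proposals(
        self, image: np.ndarray, key: str | None, cache: dict | None
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Segment candidate blobs, memoized per image id when a cache is given.

        The proposal stage is model-independent, so protocol loops that
        revisit the same fields across rounds can share one cache.
        """
        if cache is not None and key is not None and key in cache:
            return cache[key]
        lum = _luminance(image)
        labels = _segment_blobs(image, self.config)
        feats, masks = _blob_features(lum, labels, self.config)
        if cache is not None and key is not None:
            cache[key] = (feats, masks)
        return feats, masks

    def fit(
        self,
        images: Sequence[np.ndarray],
        labelsets: Sequence[LabelSet],
        seed: int = 0,
        warm_start_from: "ReferenceDetector | None" = None,
        cache: dict | None = None,
    ) -> "ReferenceDetector":
        X, y = [], []
        for image, ls in zip(images, labelsets):
            lum = _luminance(image)
            feats, masks = self._proposals(image, ls.image_id, cache)
            if len(feats) == 0:
                continue
            truth_masks = [
                (a.cls, _rasterize_cached(a, lum.shape)) for a in ls.annotations
            ]
            for f, m in zip(feats, masks):
                best_cls, best_iou = None, 0.5
                for cls, tmask in truth_masks:
                    iou = _mask_iou(m, tmask)
                    if iou >= best_iou:
                        best_cls, best_iou = cls, iou
                if best_cls is not None:
                    X.append(f)
                    y.append(best_cls)
        if not X:
            raise ValueError("no training blob matched any ground-truth nucleus")
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_seen_ = [c for c in CLASSES if c in set(y)]
        if len(self.classes_seen_) < len(CLASSES):
            logger.warning(
                "training data contains only classes %s; predictions are "
                "restricted to them", self.classes_seen_,
            )
        counts = np.array([(y == c).sum() for c in self.classes_seen_], dtype=float)
        self.class_weights_ = compute_class_weights(counts, cap=self.config.class_weight_cap)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        if len(self.classes_seen_) == 1:
            self.classifier_ = None  # degenerate: constant predictor
        else:
            weight_map = dict(zip(self.classes_seen_, self.class_weights_))
            clf = LogisticRegression(
                class_weight=weight_map,
                max_iter=self.config.max_iter,
                C=self.config.regularization,
                random_state=seed,
                warm_start=warm_start_from is not None,
            )
            if (
                warm_start_from is not None
                and warm_start_from.classifier_ is not None
                and list(warm_start_from.classifier_.classes_) == sorted(self.classes_seen_)
            ):
                clf.coef_ = warm_start_from.classifier_.coef_.copy()
                clf.intercept_ = warm_start_from.classifier_.intercept_.copy()
                clf.classes_ = warm_start_from.classifier_.classes_.copy()
            clf.fit(Xs, y)
            self.classifier_ = clf
        self.seed_ = seed
        return self

    # -- inference ---------------------------------------------------------
    def detect(
        self,
        image: np.ndarray,
        image_id: str = "image",
        cache: dict | None = None,
    ) -> list[Detection]:
        if self.scaler_ is None:
            raise RuntimeError("detector is untrained; call fit() first")
        feats, masks = self._proposals(image, image_id, cache)
        if len(feats) == 0:
            return []
        Xs = self.scaler_.transform(feats)
        probs = np.zeros((len(feats), len(CLASSES)))
        if self.classifier_ is None:
            probs[:, CLASSES.index(self.classes_seen_[0])] = 1.0
        else:
            raw = self.classifier_.predict_proba(Xs)
            for j, cls in enumerate(self.classifier_.classes_):
                probs[:, CLASSES.index(cls)] = raw[:, j]
        detections = []
        for i, m in enumerate(masks):
            poly = mask_to_polygon(m)
            ci = int(np.argmax(probs[i]))
            detections.append(
                Detection(
                    image_id=image_id,
                    polygon=poly,
                    cls=CLASSES[ci],
                    probabilities=probs[i] / probs[i].sum(),
                )
            )
        return _non_maximum_suppression(detections, self.config.nms_iou)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Save the fitted model as a single-file archive."""
        state = {
            "format": "cytoscreen-detector-v1",
            "config": self.config.__dict__,
            "config_digest": self.config.digest(),
            "scaler": self.scaler_,
            "classifier": self.classifier_,
            "classes_seen": self.classes_seen_,
            "class_weights": self.class_weights_,
            "seed": self.seed_,
        }
        Path(path).write_bytes(pickle.dumps(state))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceDetector":
        state = pickle.loads(Path(path).read_bytes())
        if state.get("format") != "cytoscreen-detector-v1":
            raise ValueError(f"{path} is not a cytoscreen detector archive")
        model = cls(DetectorConfig(**state["config"]))
        model.scaler_ = state["scaler"]
        model.classifier_ = state["classifier"]
        model.classes_seen_ = state["classes_seen"]
        model.class_weights_ = state["class_weights"]
        model.seed_ = state["seed"]
        return model


def _non_maximum_suppression(
    detections: list[Detection], iou_threshold: float
) -> list[Detection]:
    """Score-descending NMS; ties broken by original (blob) order."""
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].score, i))
    kept: list[int] = []
    shapes = [d.shape() for d in detections]
    for i in order:
        ok = True
        for j in kept:
            inter = shapes[i].intersection(shapes[j]).area
            union = shapes[i].area + shapes[j].area - inter
            if union > 0 and inter / union > iou_threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    return [detections[i] for i in sorted(kept)]


from cytoscreen.annotio import polygon_to_mask as _p2m  # noqa: E402


def _rasterize_cached(ann: NucleusAnnotation, shape: tuple[int, int]) -> np.ndarray:
    return _p2m(ann.polygon, shape)


def train_detector(
    images: Sequence[np.ndarray],
    labelsets: Sequence[LabelSet],
    config: DetectorConfig | None = None,
    seed: int = 0,
    warm_start_from: ReferenceDetector | None = None,
    cache: dict | None = None,
) -> ReferenceDetector:
    """Train the reference detector on labeled fields (seed-deterministic)."""
    return ReferenceDetector(config).fit(
        images, labelsets, seed=seed, warm_start_from=warm_start_from, cache=cache
    )
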