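"""Seeded synthetic cytology data: field images with ground-truth nucleus
polygons, patient cohorts, and a simulated pathologist for revision loops.

The generator emulates Feulgen-stained liquid-based cytology fields:
many pale normal nuclei (``yin``), occasional suspected cells
(``yin-yang``) with darker staining and slightly enlarged nuclei, and
rare diseased cells (``yang``) with large, dark, irregular nuclei.  The
abnormal:normal imbalance is on the order of 1:100 to 1:1000 by default.
Nuclei are drawn as radially Fourier-perturbed ellipses so that size,
staining intensity and boundary irregularity are separately controllable
per class; these are the qualitative criteria a cytopathologist uses.

All randomness flows from one explicit seed through splittable
``numpy.random.SeedSequence`` streams: identical specs give bit-identical
images, annotations and cohort tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon

from cytoscreen.annotio import CLASSES, LabelSet, NucleusAnnotation, polygon_to_mask


class PackingError(RuntimeError):
    """Raised when the requested nuclei cannot be packed into the field."""


@dataclass(frozen=True)
class ClassMorphology:
    """Per-class nucleus appearance parameters.

    radius_mean / radius_sd : nucleus radius in pixels (truncated normal).
    intensity_mean / intensity_sd : stain luminance 0-255, darker = more
        stained chromatin.
    irregularity : 0-1, scales the radial Fourier perturbation of the
        boundary (0 = smooth ellipse).
    nc_ratio : nucleocytoplasmic-ratio proxy in (0, 1); controls the
        faint cytoplasm halo drawn around the nucleus.
    """

    radius_mean: float
    radius_sd: float
    intensity_mean: float
    intensity_sd: float
    irregularity: float
    nc_ratio: float


#: Default class-conditional morphology.  Diseased (yang) nuclei are the
#: largest, darkest and most irregular; suspected (yin-yang) nuclei sit
#: between them and normal (yin) nuclei, with neat edges.
DEFAULT_MORPHOLOGY: dict[str, ClassMorphology] = {
    "yin": ClassMorphology(7.0, 1.2, 150.0, 12.0, 0.06, 0.25),
    "yin-yang": ClassMorphology(10.0, 1.6, 110.0, 12.0, 0.12, 0.45),
    "yang": ClassMorphology(14.0, 2.2, 70.0, 12.0, 0.35, 0.70),
}


@dataclass(frozen=True)
class SceneSpec:
    """Specification of one synthetic cytology field."""

    field_size: tuple[int, int] = (256, 256)  # (width, height)
    n_cells: int = 40
    class_mix: tuple[float, float, float] = (0.990, 0.006, 0.004)
    morphology: dict[str, ClassMorphology] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY)
    )
    overlap_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not math.isclose(sum(self.class_mix), 1.0, abs_tol=1e-9):
            raise ValueError("class_mix must sum to 1")
        if any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix entries must be nonnegative")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        m = self.morphology
        if not (m["yang"].radius_mean > m["yin-yang"].radius_mean > m["yin"].radius_mean):
            raise ValueError("mean radius must order yang > yin-yang > yin")
        if not m["yang"].intensity_mean < m["yin"].intensity_mean:
            raise ValueError("yang nuclei must stain darker than yin nuclei")
        for cls, morph in m.items():
            if morph.radius_mean <= 0 or morph.radius_sd < 0:
                raise ValueError(f"invalid radius distribution for {cls}")
            if not 0 <= morph.irregularity <= 1:
                raise ValueError(f"irregularity for {cls} must be in [0, 1]")
            if not 0 < morph.nc_ratio < 1:
                raise ValueError(f"nc_ratio for {cls} must be in (0, 1)")


_BACKGROUND_RGB = np.array([228.0, 219.0, 232.0])  # pale cytoplasm-toned field
_NUCLEUS_TINT = np.array([0.72, 0.55, 1.0])  # haematoxylin-like purple cast
_N_VERTICES = 28
_MAX_PLACEMENT_TRIES = 600


def _sample_nucleus_outline(
    rng: np.random.Generator, morph: ClassMorphology
) -> tuple[np.ndarray, float]:
    """Sample a centered nucleus outline; returns (vertices, max radius)."""
    r0 = max(2.0, rng.normal(morph.radius_mean, morph.radius_sd))
    aspect = rng.uniform(0.75, 1.0)
    phi = rng.uniform(0, 2 * np.pi)
    theta = np.linspace(0, 2 * np.pi, _N_VERTICES, endpoint=False)
    # radial Fourier perturbation, harmonics 2..5, scaled by irregularity
    perturb = np.zeros_like(theta)
    for k in range(2, 6):
        amp = morph.irregularity * rng.uniform(0.0, 0.12)
        perturb += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    radii = r0 * (1.0 + perturb)
    x = radii * np.cos(theta)
    y = radii * np.sin(theta) * aspect
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    pts = np.stack([x, y], axis=1) @ rot.T
    return pts, float(np.max(np.hypot(pts[:, 0], pts[:, 1])))


def generate_field(spec: SceneSpec) -> tuple[np.ndarray, list[NucleusAnnotation]]:
    """Render one synthetic field and its ground-truth annotations.

    Nuclei are placed by rejection sampling: a candidate is accepted when
    its polygon lies fully inside the field and its overlap with every
    placed nucleus does not exceed ``spec.overlap_fraction`` (pairwise
    IoU; with the default 0 the nuclei are disjoint).  A fast
    bounding-circle test prunes the exact polygon checks.

    Returns an (H, W, 3) uint8 RGB image and the annotation list; the
    same spec always yields bit-identical output.

    Raises
    ------
    PackingError
        if a nucleus cannot be placed after a bounded number of tries
        (field too small for ``n_cells`` at the stated radii).
    """
    spec.validate()
    width, height = spec.field_size
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    image_id = f"field-{spec.seed:08d}"

    classes = rng.choice(len(CLASSES), size=spec.n_cells, p=np.asarray(spec.class_mix))
    annotations: list[NucleusAnnotation] = []
    placed_centers: list[tuple[float, float]] = []
    placed_radii: list[float] = []
    placed_polys: list[ShapelyPolygon] = []
    intensities: list[float] = []
    halos: list[float] = []

    for ci in classes:
        cls = CLASSES[ci]
        morph = spec.morphology[cls]
        outline, rmax = _sample_nucleus_outline(rng, morph)
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            cx = rng.uniform(rmax + 1, width - rmax - 1)
            cy = rng.uniform(rmax + 1, height - rmax - 1)
            if placed_centers:
                centers = np.asarray(placed_centers)
                dists = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
                near = dists < (np.asarray(placed_radii) + rmax)
                if near.any():
                    if spec.overlap_fraction == 0.0:
                        continue
                    cand = ShapelyPolygon(outline + [cx, cy])
                    ok = True
                    for j in np.flatnonzero(near):
                        inter = cand.intersection(placed_polys[j]).area
                        union = cand.area + placed_polys[j].area - inter
                        if union > 0 and inter / union > spec.overlap_fraction:
                            ok = False
                            break
                    if not ok:
                        continue
            poly = outline + [cx, cy]
            placed_centers.append((cx, cy))
            placed_radii.append(rmax)
            placed_polys.append(ShapelyPolygon(poly))
            annotations.append(NucleusAnnotation(image_id=image_id, polygon=poly, cls=cls))
            intensities.append(float(np.clip(rng.normal(morph.intensity_mean, morph.intensity_sd), 15, 235)))
            halos.append(morph.nc_ratio)
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place nucleus {len(annotations) + 1}/{spec.n_cells} "
                f"(class {cls}) in a {width}x{height} field; reduce n_cells or radii"
            )

    # render: pale background, faint cytoplasm halos, stained nuclei
    img = np.ones((height, width, 3)) * _BACKGROUND_RGB
    for ann, inten, nc in zip(annotations, intensities, halos):
        mask = polygon_to_mask(ann.polygon, (height, width))
        halo_px = max(1, int(round((1.0 / max(nc, 0.05) - 1.0) * 2)))
        halo = ndimage.binary_dilation(mask, iterations=min(halo_px, 6)) & ~mask
        img[halo] = 0.65 * img[halo] + 0.35 * (_BACKGROUND_RGB - 18.0)
        img[mask] = inten * _NUCLEUS_TINT
    img = ndimage.gaussian_filter(img, sigma=(0.7, 0.7, 0))
    img += rng.normal(0.0, 3.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), annotations


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic patient cohort.

    ``abnormal_cell_rate`` is the per-cell probability of a diseased
    (yang) nucleus in positive patients; the default 0.01 keeps the
    abnormal:normal imbalance inside the 1:100-1:1000 band.  Negative
    patients carry zero yang cells; both groups carry a small rate of
    suspected (yin-yang) cells, elevated in positives.
    """

    n_patients: int = 400
    prevalence: float = 211 / 400
    fields_per_patient: int = 6
    cells_per_field: int = 70
    abnormal_cell_rate: float = 0.01
    suspected_rate_positive: float = 0.015
    suspected_rate_negative: float = 0.004
    age_mean: float = 45.0
    age_sd: float = 12.0
    field_size: tuple[int, int] = (256, 256)
    morphology: dict[str, ClassMorphology] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY)
    )
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if self.n_patients <= 0 or self.fields_per_patient <= 0:
            raise ValueError("n_patients and fields_per_patient must be positive")
        if self.abnormal_cell_rate <= 0:
            raise ValueError("positive patients need abnormal_cell_rate > 0")
        if self.abnormal_cell_rate + self.suspected_rate_positive >= 1:
            raise ValueError("abnormal + suspected rates must stay below 1")


@dataclass
class Cohort:
    """A generated cohort: patient table plus per-field annotations.

    ``patients`` has columns patient_id, age, label (0 normal /
    1 positive).  ``fields`` maps patient_id to a list of per-field
    ``(SceneSpec, list[NucleusAnnotation])`` pairs; images are rendered
    lazily via :func:`generate_field` only where a detector needs pixels.
    """

    spec: CohortSpec
    patients: pd.DataFrame
    fields: dict[str, list[tuple[SceneSpec, list[NucleusAnnotation]]]]

    def cell_counts(self) -> pd.DataFrame:
        """Ground-truth per-patient cell counts by class."""
        rows = []
        for pid, flds in self.fields.items():
            counts = {c: 0 for c in CLASSES}
            for _, anns in flds:
                for a in anns:
                    counts[a.cls] += 1
            rows.append({"patient_id": pid, **counts})
        return pd.DataFrame(rows).set_index("patient_id")


def generate_annotations(spec: SceneSpec, image_id: str | None = None) -> list[NucleusAnnotation]:
    """Sample a field's annotations without rendering pixels.

    Uses the same class-mix, morphology and disjoint-packing sampling as
    :func:`generate_field`; useful when only ground-truth geometry and
    class labels are needed (cohort statistics, count features).
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return _geometry_only_annotations(rng, spec, image_id or f"field-{spec.seed:08d}")


def _geometry_only_annotations(
    rng: np.random.Generator,
    spec: SceneSpec,
    image_id: str,
) -> list[NucleusAnnotation]:
    """Sample annotation geometry without rendering pixels (fast path)."""
    width, height = spec.field_size
    classes = rng.choice(len(CLASSES), size=spec.n_cells, p=np.asarray(spec.class_mix))
    anns: list[NucleusAnnotation] = []
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for ci in classes:
        cls = CLASSES[ci]
        outline, rmax = _sample_nucleus_outline(rng, spec.morphology[cls])
        for _ in range(_MAX_PLACEMENT_TRIES):
            cx = rng.uniform(rmax + 1, width - rmax - 1)
            cy = rng.uniform(rmax + 1, height - rmax - 1)
            if centers:
                carr = np.asarray(centers)
                if (np.hypot(carr[:, 0] - cx, carr[:, 1] - cy) < np.asarray(radii) + rmax).any():
                    continue
            centers.append((cx, cy))
            radii.append(rmax)
            anns.append(NucleusAnnotation(image_id=image_id, polygon=outline + [cx, cy], cls=cls))
            break
        else:
            raise PackingError(f"cohort field {image_id}: packing failed")
    return anns


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a seeded cohort of patients with per-field annotations.

    Exactly ``round(prevalence * n_patients)`` patients are positive;
    negative patients contain zero yang annotations.  Field annotation
    geometry is sampled directly (disjoint packing); call
    :func:`generate_field` on the stored per-field ``SceneSpec`` when
    rendered pixels are needed.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])

    n_pos = int(round(spec.prevalence * spec.n_patients))
    labels = np.zeros(spec.n_patients, dtype=int)
    labels[assign_rng.permutation(spec.n_patients)[:n_pos]] = 1
    ages = np.clip(
        assign_rng.normal(spec.age_mean, spec.age_sd, size=spec.n_patients), 21, 80
    ).round(0)

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(spec.n_patients)],
            "age": ages,
            "label": labels,
        }
    )

    fields: dict[str, list[tuple[SceneSpec, list[NucleusAnnotation]]]] = {}
    field_seeds = root.spawn(spec.n_patients)
    for i, row in patients.iterrows():
        rng = np.random.default_rng(field_seeds[i])
        if row["label"] == 1:
            mix = (
                1.0 - spec.suspected_rate_positive - spec.abnormal_cell_rate,
                spec.suspected_rate_positive,
                spec.abnormal_cell_rate,
            )
        else:
            mix = (1.0 - spec.suspected_rate_negative, spec.suspected_rate_negative, 0.0)
        plist = []
        for f in range(spec.fields_per_patient):
            fid = f"{row['patient_id']}-f{f:03d}"
            fspec = SceneSpec(
                field_size=spec.field_size,
                n_cells=spec.cells_per_field,
                class_mix=mix,
                morphology=spec.morphology,
                seed=int(rng.integers(2**31 - 1)),
            )
            plist.append((fspec, _geometry_only_annotations(rng, fspec, fid)))
        fields[row["patient_id"]] = plist
    return Cohort(spec=spec, patients=patients, fields=fields)


# ---------------------------------------------------------------------------
# Simulated pathologist (revision oracle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleSpec:
    """Behaviour of the simulated reviewing pathologist.

    revision_fidelity : probability each erroneous pre-label (wrong
        class, poor contour, or spurious) is corrected to ground truth.
    miss_add_rate : probability each missed nucleus is drawn from scratch.
    cost_draw / cost_fix : effort units per new polygon drawn and per
        label/contour correction -- a click-count proxy for the wall-clock
        labeling effort a human annotator would spend.
    contour_fix_iou : a matched pre-label whose mask IoU with truth falls
        below this needs a contour fix.
    """

    revision_fidelity: float = 1.0
    miss_add_rate: float = 1.0
    cost_draw: float = 5.0
    cost_fix: float = 1.0
    contour_fix_iou: float = 0.95
    match_iou: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("revision_fidelity", "miss_add_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cost_draw < 0 or self.cost_fix < 0:
            raise ValueError("costs must be nonnegative")


@dataclass
class RevisionCost:
    """Ledger of one revision pass, decomposed into draws and fixes."""

    n_prelabels: int = 0
    n_accepted: int = 0
    n_class_fixes: int = 0
    n_contour_fixes: int = 0
    n_spurious_removed: int = 0
    n_drawn: int = 0

    def total(self, spec: OracleSpec) -> float:
        fixes = self.n_class_fixes + self.n_contour_fixes + self.n_spurious_removed
        return spec.cost_draw * self.n_drawn + spec.cost_fix * fixes


def _polygon_iou(a: np.ndarray, b: np.ndarray) -> float:
    pa, pb = ShapelyPolygon(a).buffer(0), ShapelyPolygon(b).buffer(0)
    inter = pa.intersection(pb).area
    union = pa.area + pb.area - inter
    return inter / union if union > 0 else 0.0


def simulate_revision(
    truth: Sequence[NucleusAnnotation],
    prelabels: Sequence,
    spec: OracleSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[NucleusAnnotation], RevisionCost]:
    """Simulate a pathologist revising model pre-labels against truth.

    Pre-labels (anything with ``polygon`` and ``cls`` attributes) are
    greedily matched one-to-one to ground-truth nuclei at
    ``spec.match_iou``.  A matched pre-label with the right class and a
    contour IoU >= ``contour_fix_iou`` is accepted at zero cost and
    emitted in ground-truth geometry (the reviewer signs off on the
    nucleus); an erroneous one is corrected to truth with probability
    ``revision_fidelity`` (one fix each).  Each unmatched truth nucleus
    is drawn from scratch with probability ``miss_add_rate`` (one draw
    each); each spurious pre-label is removed with probability
    ``revision_fidelity`` (one fix each).

    With ``revision_fidelity = miss_add_rate = 1`` the revised set equals
    ground truth exactly, and the cost is zero iff the pre-labels already
    equal truth.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    truth = list(truth)
    prelabels = list(prelabels)
    if truth and prelabels:
        t_img = {a.image_id for a in truth}
        p_img = {getattr(p, "image_id") for p in prelabels}
        if t_img != p_img:
            raise ValueError(
                f"truth and prelabels refer to different images: {t_img} vs {p_img}"
            )

    # greedy best-IoU matching, pre-labels in given (score) order
    unmatched_truth = set(range(len(truth)))
    matches: list[tuple[int, int, float]] = []
    spurious: list[int] = []
    for pi, pre in enumerate(prelabels):
        best, best_iou = None, spec.match_iou
        for ti in unmatched_truth:
            iou = _polygon_iou(np.asarray(pre.polygon), truth[ti].polygon)
            if iou >= best_iou:
                best, best_iou = ti, iou
        if best is None:
            spurious.append(pi)
        else:
            unmatched_truth.discard(best)
            matches.append((pi, best, best_iou))

    cost = RevisionCost(n_prelabels=len(prelabels))
    revised: list[NucleusAnnotation] = []
    for pi, ti, iou in matches:
        pre = prelabels[pi]
        class_ok = pre.cls == truth[ti].cls
        contour_ok = iou >= spec.contour_fix_iou
        if class_ok and contour_ok:
            cost.n_accepted += 1
            revised.append(truth[ti])
        elif rng.random() < spec.revision_fidelity:
            if not class_ok:
                cost.n_class_fixes += 1
            if not contour_ok:
                cost.n_contour_fixes += 1
            revised.append(truth[ti])
        else:
            revised.append(
                NucleusAnnotation(
                    image_id=truth[ti].image_id,
                    polygon=np.asarray(pre.polygon),
                    cls=pre.cls,
                )
            )
    for ti in sorted(unmatched_truth):
        if rng.random() < spec.miss_add_rate:
            cost.n_drawn += 1
            revised.append(truth[ti])
    for pi in spurious:
        if rng.random() < spec.revision_fidelity:
            cost.n_spurious_removed += 1  # deleted, not kept
        else:
            pre = prelabels[pi]
            img_id = getattr(pre, "image_id", truth[0].image_id if truth else "")
            revised.append(
                NucleusAnnotation(image_id=img_id, polygon=np.asarray(pre.polygon), cls=pre.cls)
            )
    return revised, cost
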