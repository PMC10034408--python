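"""Annotation IO and geometry: LabelMe JSON, COCO export, polygon/mask
conversion, and the three-family training-image augmentation.

Coordinate convention: 0-based continuous pixel coordinates, x rightward
and y downward.  Pixel ``(row r, col c)`` occupies the unit square
``[c, c+1) x [r, r+1)`` with its center at ``(c + 0.5, r + 0.5)``.
Rasterization uses the pixel-center even-odd rule: a pixel belongs to a
polygon iff its center lies strictly inside the polygon.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.geometry import box as shapely_box
from skimage import measure, transform

logger = logging.getLogger(__name__)

#: Canonical nucleus class names, in category-id order (yin=1, yin-yang=2, yang=3).
CLASSES: tuple[str, str, str] = ("yin", "yin-yang", "yang")

_CLASS_ALIASES = {c.lower(): c for c in CLASSES}
_CLASS_ALIASES["yinyang"] = "yin-yang"
_CLASS_ALIASES["yin_yang"] = "yin-yang"


class AnnotationError(ValueError):
    """Raised for malformed annotations or annotation files."""


def normalize_class(name: str) -> str:
    """Map a class string to its canonical name, case-insensitively.

    Annotation files in the wild mix capitalizations ("Yin", "YANG");
    the three canonical names are ``yin``, ``yin-yang`` and ``yang``.
    """
    key = str(name).strip().lower()
    if key not in _CLASS_ALIASES:
        raise AnnotationError(
            f"unknown nucleus class {name!r}; expected one of {CLASSES}"
        )
    return _CLASS_ALIASES[key]


@dataclass(eq=False)
class NucleusAnnotation:
    """One labeled nucleus: a simple polygon plus its class."""

    image_id: str
    polygon: np.ndarray  # (n, 2) float array of (x, y) vertices
    cls: str

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise AnnotationError("polygon must be an (n, 2) array of vertices")
        if len(self.polygon) < 3:
            raise AnnotationError(
                f"polygon for image {self.image_id!r} has "
                f"{len(self.polygon)} vertices; at least 3 required"
            )
        self.cls = normalize_class(self.cls)
        if not self.shape().is_simple:
            raise AnnotationError(
                f"polygon for image {self.image_id!r} is self-intersecting"
            )

    def shape(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.polygon)

    def area(self) -> float:
        return self.shape().area

    def same_as(self, other: "NucleusAnnotation", tol: float = 0.0) -> bool:
        """Exact (or tol-close) equality of class and vertex list."""
        return (
            self.cls == other.cls
            and self.polygon.shape == other.polygon.shape
            and np.allclose(self.polygon, other.polygon, atol=tol, rtol=0.0)
        )


@dataclass(eq=False)
class LabelSet:
    """All nucleus annotations of one field image."""

    image_id: str
    width: int
    height: int
    annotations: list[NucleusAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            xs, ys = ann.polygon[:, 0], ann.polygon[:, 1]
            if xs.min() < 0 or ys.min() < 0 or xs.max() > self.width or ys.max() > self.height:
                raise AnnotationError(
                    f"annotation in image {self.image_id!r} extends outside "
                    f"the {self.width}x{self.height} field"
                )

    def __len__(self) -> int:
        return len(self.annotations)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for ann in self.annotations:
            counts[ann.cls] += 1
        return counts


# ---------------------------------------------------------------------------
# LabelMe-style JSON
# ---------------------------------------------------------------------------

def write_labelme(labelset: LabelSet, path: str | Path) -> None:
    """Write one LabelMe-style JSON file for an image's annotations."""
    payload = {
        "version": "cytoscreen",
        "imagePath": f"{labelset.image_id}.png",
        "imageHeight": labelset.height,
        "imageWidth": labelset.width,
        "shapes": [
            {
                "label": ann.cls,
                "points": ann.polygon.tolist(),
                "shape_type": "polygon",
            }
            for ann in labelset.annotations
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_labelme(path: str | Path) -> LabelSet:
    """Read a LabelMe-style polygon JSON file.

    Class strings are normalized case-insensitively; rectangle/point
    shapes are rejected; a polygon with fewer than 3 vertices is a
    parse error naming the offending shape.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: malformed JSON ({exc})") from exc
    try:
        image_id = str(Path(payload["imagePath"]).stem)
        height = int(payload["imageHeight"])
        width = int(payload["imageWidth"])
        shapes = payload["shapes"]
    except KeyError as exc:
        raise AnnotationError(f"{path}: missing required key {exc}") from exc
    annotations = []
    for i, shape in enumerate(shapes):
        if shape.get("shape_type", "polygon") != "polygon":
            raise AnnotationError(
                f"{path}: shape {i} has unsupported shape_type "
                f"{shape.get('shape_type')!r}; only polygons are supported"
            )
        points = np.asarray(shape["points"], dtype=float)
        if points.ndim != 2 or len(points) < 3:
            raise AnnotationError(
                f"{path}: shape {i} (label {shape.get('label')!r}) has "
                f"{0 if points.ndim != 2 else len(points)} vertices; "
                "a polygon needs at least 3"
            )
        annotations.append(
            NucleusAnnotation(image_id=image_id, polygon=points, cls=shape["label"])
        )
    return LabelSet(image_id=image_id, width=width, height=height, annotations=annotations)


# ---------------------------------------------------------------------------
# COCO-JSON export / import
# ---------------------------------------------------------------------------

def export_coco(labelsets: Sequence[LabelSet], path: str | Path) -> dict:
    """Export label sets to a COCO-style instance-segmentation JSON.

    Category ids are fixed (yin=1, yin-yang=2, yang=3); polygon
    segmentations are written verbatim as flat [x0, y0, x1, y1, ...]
    lists so geometry round-trips exactly.
    """
    seen: set[str] = set()
    for ls in labelsets:
        if ls.image_id in seen:
            raise AnnotationError(f"duplicate image id {ls.image_id!r} in COCO export")
        seen.add(ls.image_id)

    images = []
    annotations = []
    image_index = {}
    ann_id = 1
    for img_num, ls in enumerate(labelsets, start=1):
        image_index[ls.image_id] = img_num
        images.append(
            {
                "id": img_num,
                "file_name": f"{ls.image_id}.png",
                "width": ls.width,
                "height": ls.height,
            }
        )
        for ann in ls.annotations:
            xs, ys = ann.polygon[:, 0], ann.polygon[:, 1]
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_num,
                    "category_id": CLASSES.index(ann.cls) + 1,
                    "segmentation": [ann.polygon.ravel().tolist()],
                    "bbox": [
                        float(xs.min()),
                        float(ys.min()),
                        float(xs.max() - xs.min()),
                        float(ys.max() - ys.min()),
                    ],
                    "area": float(ann.area()),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": i + 1, "name": name, "supercategory": "nucleus"}
            for i, name in enumerate(CLASSES)
        ],
    }
    Path(path).write_text(json.dumps(doc))
    return doc


def import_coco(path: str | Path) -> list[LabelSet]:
    """Read back a COCO-JSON file written by :func:`export_coco`."""
    doc = json.loads(Path(path).read_text())
    cat_names = {c["id"]: normalize_class(c["name"]) for c in doc["categories"]}
    sets = {
        img["id"]: LabelSet(
            image_id=str(Path(img["file_name"]).stem),
            width=img["width"],
            height=img["height"],
        )
        for img in doc["images"]
    }
    for ann in doc["annotations"]:
        ls = sets[ann["image_id"]]
        poly = np.asarray(ann["segmentation"][0], dtype=float).reshape(-1, 2)
        ls.annotations.append(
            NucleusAnnotation(image_id=ls.image_id, polygon=poly, cls=cat_names[ann["category_id"]])
        )
    return list(sets.values())


# ---------------------------------------------------------------------------
# Polygon <-> mask
# ---------------------------------------------------------------------------

def polygon_to_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon with the pixel-center even-odd rule.

    Parameters
    ----------
    polygon : (n, 2) array of (x, y) vertices.
    shape : (height, width) of the output mask.

    Returns
    -------
    bool array of ``shape``; True exactly where the pixel center
    ``(c + 0.5, r + 0.5)`` falls strictly inside the polygon.
    """
    polygon = np.asarray(polygon, dtype=float)
    h, w = shape
    geom = ShapelyPolygon(polygon)
    mask = np.zeros((h, w), dtype=bool)
    # restrict the point-in-polygon test to the bounding box
    minx, miny, maxx, maxy = geom.bounds
    c0, c1 = max(0, int(np.floor(minx - 0.5))), min(w, int(np.ceil(maxx + 0.5)))
    r0, r1 = max(0, int(np.floor(miny - 0.5))), min(h, int(np.ceil(maxy + 0.5)))
    if c1 <= c0 or r1 <= r0:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(geom, cols + 0.5, rows + 0.5)
    mask[r0:r1, c0:c1] = inside
    return mask


def mask_to_polygon(mask: np.ndarray) -> np.ndarray:
    """Trace the boundary of a binary mask as an (n, 2) (x, y) polygon.

    The contour runs along the 0.5-level of the padded mask, i.e. halfway
    between inside and outside pixel centers, so rasterizing the returned
    polygon with :func:`polygon_to_mask` reproduces the mask for any
    4-connected blob.  The largest connected contour is returned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise AnnotationError("cannot extract a polygon from an empty mask")
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    # keep the outer contour of the largest blob (largest enclosed area)
    def _ring_area(c: np.ndarray) -> float:
        y, x = c[:, 0], c[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

    contour = max(contours, key=_ring_area)
    # (row, col) in padded index space -> (x, y) in pixel-corner coordinates:
    # padded index i corresponds to original pixel i-1, whose center is i-1+0.5.
    xy = np.stack([contour[:, 1] - 0.5, contour[:, 0] - 0.5], axis=1)
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return xy


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

#: The three augmentation families applied during training, one chosen
#: uniformly at random per image.
AUGMENT_FAMILIES = ("flip", "affine", "contrast")

# mild, label-preserving parameter ranges
_ROT_MAX_DEG = 25.0
_SCALE_RANGE = (0.8, 1.2)
_SHEAR_MAX_DEG = 8.0
_TRANSLATE_FRAC = 0.10
_GAMMA_RANGE = (0.7, 1.4)
_LINEAR_CONTRAST = 0.30
_MIN_CLIPPED_AREA_FRAC = 0.20


def _affine_matrix(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    """Random mild affine about the image center, as a 3x3 matrix."""
    theta = np.deg2rad(rng.uniform(-_ROT_MAX_DEG, _ROT_MAX_DEG))
    scale = rng.uniform(*_SCALE_RANGE)
    shear = np.deg2rad(rng.uniform(-_SHEAR_MAX_DEG, _SHEAR_MAX_DEG))
    tx = rng.uniform(-_TRANSLATE_FRAC, _TRANSLATE_FRAC) * width
    ty = rng.uniform(-_TRANSLATE_FRAC, _TRANSLATE_FRAC) * height
    cx, cy = width / 2.0, height / 2.0
    center = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    uncenter = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    core = transform.AffineTransform(
        scale=scale, rotation=theta, shear=shear, translation=(tx, ty)
    ).params
    return center @ core @ uncenter


def _transform_polygon(matrix: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    pts = np.column_stack([polygon, np.ones(len(polygon))])
    out = (matrix @ pts.T).T
    return out[:, :2] / out[:, 2:3]


def _clip_to_field(polygon: np.ndarray, width: int, height: int) -> np.ndarray | None:
    """Clip a polygon to the field; None if the kept area is too small."""
    xs, ys = polygon[:, 0], polygon[:, 1]
    if xs.min() >= 0 and ys.min() >= 0 and xs.max() <= width and ys.max() <= height:
        return polygon  # fully inside; keep vertices verbatim
    geom = ShapelyPolygon(polygon)
    clipped = geom.intersection(shapely_box(0, 0, width, height))
    if clipped.is_empty or clipped.area < _MIN_CLIPPED_AREA_FRAC * geom.area:
        return None
    if clipped.geom_type == "MultiPolygon":
        clipped = max(clipped.geoms, key=lambda g: g.area)
    coords = np.asarray(clipped.exterior.coords)[:-1]
    if len(coords) < 3:
        return None
    return coords


def augment(
    image: np.ndarray,
    labelset: LabelSet,
    seed: int | np.random.Generator,
    family: str | None = None,
) -> tuple[np.ndarray, LabelSet, dict]:
    """Apply one of three augmentation families to an image and its labels.

    Exactly one family -- flip/mirror, mild affine, or contrast change --
    is chosen uniformly from ``seed`` (or forced via ``family``).
    Geometric transforms are applied identically to every polygon;
    contrast changes leave the annotations untouched.  Polygons pushed
    (mostly) out of the field by an affine are clipped, and dropped with
    a logged warning when less than 20% of their area survives.

    Returns ``(image', labelset', info)`` where ``info`` records the
    family and sampled parameters (the affine matrix in particular).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if image.shape[0] != labelset.height or image.shape[1] != labelset.width:
        raise AnnotationError(
            f"image shape {image.shape[:2]} does not match label set "
            f"dimensions {(labelset.height, labelset.width)}"
        )
    if family is None:
        family = AUGMENT_FAMILIES[rng.integers(len(AUGMENT_FAMILIES))]
    if family not in AUGMENT_FAMILIES:
        raise ValueError(f"unknown augmentation family {family!r}")
    w, h = labelset.width, labelset.height
    info: dict = {"family": family}

    if family == "flip":
        horizontal = bool(rng.integers(2))
        info["axis"] = "horizontal" if horizontal else "vertical"
        if horizontal:
            out = image[:, ::-1].copy()
            polys = [np.column_stack([w - a.polygon[:, 0], a.polygon[:, 1]]) for a in labelset.annotations]
        else:
            out = image[::-1].copy()
            polys = [np.column_stack([a.polygon[:, 0], h - a.polygon[:, 1]]) for a in labelset.annotations]
        anns = [
            NucleusAnnotation(a.image_id, p, a.cls)
            for a, p in zip(labelset.annotations, polys)
        ]
        return out, LabelSet(labelset.image_id, w, h, anns), info

    if family == "affine":
        matrix = _affine_matrix(rng, w, h)
        info["matrix"] = matrix
        warped = transform.warp(
            image.astype(float), np.linalg.inv(matrix), order=1,
            mode="edge", preserve_range=True,
        )
        out = warped.astype(image.dtype)
        anns = []
        dropped = 0
        for a in labelset.annotations:
            poly = _transform_polygon(matrix, a.polygon)
            clipped = _clip_to_field(poly, w, h)
            if clipped is None:
                dropped += 1
                continue
            anns.append(NucleusAnnotation(a.image_id, clipped, a.cls))
        if dropped:
            logger.warning(
                "affine augmentation dropped %d annotation(s) pushed out of "
                "the field in image %s", dropped, labelset.image_id,
            )
            info["dropped"] = dropped
        return out, LabelSet(labelset.image_id, w, h, anns), info

    # contrast: annotations untouched
    img = image.astype(float)
    if rng.integers(2):
        gamma = rng.uniform(*_GAMMA_RANGE)
        info["gamma"] = gamma
        out = (255.0 * np.power(np.clip(img / 255.0, 0, 1), gamma))
    else:
        factor = 1.0 + rng.uniform(-_LINEAR_CONTRAST, _LINEAR_CONTRAST)
        info["factor"] = factor
        out = (img - 127.5) * factor + 127.5
    out = np.clip(out, 0, 255).astype(image.dtype)
    anns = [NucleusAnnotation(a.image_id, a.polygon.copy(), a.cls) for a in labelset.annotations]
    return out, LabelSet(labelset.image_id, w, h, anns), info
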