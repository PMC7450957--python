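"""Damage-segmentation strategies.

Three automatic strategies for marking chlorotic (mite-damaged) pixels are
implemented side by side so they can be compared on the same scans:

* a random-forest pixel classifier over multi-scale local image features
  (the interactive machine-learning strategy), with an uncertainty map to
  drive an annotate-where-uncertain retraining loop;
* a two-stage fixed-boundary colour threshold (rosette selection, then
  damage selection within it) on one of the R/G/B/H/S/I planes;
* a square-grid mean-colour test that marks tiles whose average colour is
  green-deficient, with a 9-level sensitivity ladder.

A fourth function emulates the manual reference protocol: overlaying a
square grid on an expert damage annotation and counting selected squares.
Counting whole squares can only over-cover the true lesion area, which is
the overestimation mechanism the automatic pipeline is meant to avoid.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.feature import structure_tensor, structure_tensor_eigenvalues
from sklearn.ensemble import RandomForestClassifier

from .imaging import RosetteMask, ScanImage

__all__ = [
    "ANNOTATION_CLASSES",
    "LabelSet",
    "PixelClassifier",
    "ThresholdRule",
    "GridRule",
    "MissingClassError",
    "UntrainedModelError",
    "extract_features",
    "train_pixel_classifier",
    "uncertainty_map",
    "classify_pixels",
    "damage_mask",
    "threshold_classify",
    "grid_classify",
    "manual_grid_emulate",
    "hsi_planes",
    "plane_values",
    "SENSITIVITY_CUTOFFS",
]

# Fixed class order; ties in arg-max resolve to the earlier class.
ANNOTATION_CLASSES = ("background", "healthy", "damaged")

DEFAULT_SCALES = (1.0, 2.0, 4.0, 8.0)
DEFAULT_N_TREES = 100

#: Strictly decreasing green-deficiency cutoffs for sensitivity levels 1..9.
SENSITIVITY_CUTOFFS = tuple(0.92 - 0.04 * s for s in range(9))


class MissingClassError(ValueError):
    """Raised when training labels do not cover every annotation class."""


class UntrainedModelError(ValueError):
    """Raised when prediction is requested from an unfitted classifier."""


@dataclasses.dataclass
class LabelSet:
    """Sparse pixel annotations: (row, col, class) triples."""

    rows: np.ndarray
    cols: np.ndarray
    classes: List[str]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if not (len(self.rows) == len(self.cols) == len(self.classes)):
            raise ValueError("rows, cols and classes must have equal length")
        for cls in self.classes:
            if cls not in ANNOTATION_CLASSES:
                raise ValueError(f"unknown class {cls!r}")
        seen = set(zip(self.rows.tolist(), self.cols.tolist()))
        if len(seen) != len(self.rows):
            raise ValueError("each pixel may be labelled at most once")

    def __len__(self) -> int:
        return len(self.rows)

    def validate_for(self, image: ScanImage) -> None:
        h, w = image.shape
        if len(self.rows) and (
            self.rows.min() < 0 or self.rows.max() >= h
            or self.cols.min() < 0 or self.cols.max() >= w
        ):
            raise ValueError("label coordinates fall outside the image")

    def extend(self, other: "LabelSet") -> "LabelSet":
        return LabelSet(
            rows=np.concatenate([self.rows, other.rows]),
            cols=np.concatenate([self.cols, other.cols]),
            classes=self.classes + other.classes,
        )


def extract_features(image: ScanImage, scales: Sequence[float] = DEFAULT_SCALES) -> np.ndarray:
    """Per-pixel feature stack: raw RGB plus 7 multi-scale texture features.

    At each smoothing scale sigma the features are the Gaussian-smoothed
    RGB channels, the gradient magnitude, the Laplacian of Gaussian and the
    two structure-tensor eigenvalues of the intensity channel — 3 + 7 per
    scale features in total, all deterministic.
    """
    if len(scales) < 1:
        raise ValueError("at least one scale is required")
    rgb = image.pixels.astype(np.float32)
    # float64 intensity keeps derivative filters numerically clean on
    # uniform regions
    gray = image.pixels.astype(np.float64).mean(axis=2)
    feats = [rgb[..., 0], rgb[..., 1], rgb[..., 2]]
    for s in scales:
        for ch in range(3):
            feats.append(ndi.gaussian_filter(rgb[..., ch], s))
        feats.append(ndi.gaussian_gradient_magnitude(gray, s))
        feats.append(ndi.gaussian_laplace(gray, s))
        A = structure_tensor(gray, sigma=s, order="rc", mode="reflect")
        l1, l2 = structure_tensor_eigenvalues(A)
        feats.append(l1)
        feats.append(l2)
    return np.stack(feats, axis=-1).astype(np.float32)


@dataclasses.dataclass
class PixelClassifier:
    """Trained random-forest pixel classifier with its feature recipe."""

    forest: RandomForestClassifier | None
    scales: Tuple[float, ...]
    classes: Tuple[str, ...]
    seed: int

    def require_trained(self) -> None:
        if self.forest is None or not hasattr(self.forest, "estimators_"):
            raise UntrainedModelError("classifier has not been trained")

    def save(self, path: str) -> None:
        joblib.dump(
            {"format": "mitedamage-pixel-classifier-v1",
             "forest": self.forest, "scales": self.scales,
             "classes": self.classes, "seed": self.seed},
            path,
        )

    @classmethod
    def load(cls, path: str) -> "PixelClassifier":
        blob = joblib.load(path)
        if blob.get("format") != "mitedamage-pixel-classifier-v1":
            raise ValueError(f"{path}: not a recognised classifier file")
        return cls(forest=blob["forest"], scales=tuple(blob["scales"]),
                   classes=tuple(blob["classes"]), seed=int(blob["seed"]))


def train_pixel_classifier(
    images: Sequence[ScanImage],
    labels: Sequence[LabelSet],
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    scales: Sequence[float] = DEFAULT_SCALES,
) -> PixelClassifier:
    """Fit the random forest on the labelled pixels of the given scans.

    Training-pixel bootstrapping happens inside the forest's per-tree
    bagging.  Every annotation class must be present in the pooled labels.
    """
    if len(images) != len(labels):
        raise ValueError("one LabelSet per image is required")
    X_parts, y_parts = [], []
    for image, lab in zip(images, labels):
        lab.validate_for(image)
        if len(lab) == 0:
            continue
        feats = extract_features(image, scales)
        X_parts.append(feats[lab.rows, lab.cols])
        y_parts.append(np.array([ANNOTATION_CLASSES.index(c) for c in lab.classes]))
    if not X_parts:
        raise MissingClassError(f"missing classes: {list(ANNOTATION_CLASSES)}")
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    present = set(int(v) for v in np.unique(y))
    absent = [ANNOTATION_CLASSES[i] for i in range(len(ANNOTATION_CLASSES)) if i not in present]
    if absent:
        raise MissingClassError(f"missing classes: {absent}")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    return PixelClassifier(
        forest=forest, scales=tuple(scales), classes=ANNOTATION_CLASSES, seed=seed
    )


def _predict_proba(model: PixelClassifier, image: ScanImage) -> np.ndarray:
    model.require_trained()
    feats = extract_features(image, model.scales)
    h, w, f = feats.shape
    raw = model.forest.predict_proba(feats.reshape(-1, f))
    # column order follows forest.classes_ (int codes); re-map to the fixed
    # class order so arg-max tie-breaking is deterministic
    proba = np.zeros((h * w, len(model.classes)), dtype=np.float64)
    for col, code in enumerate(model.forest.classes_):
        proba[:, int(code)] = raw[:, col]
    return proba.reshape(h, w, len(model.classes))


def classify_pixels(model: PixelClassifier, image: ScanImage) -> np.ndarray:
    """Arg-max class map over {background, healthy, damaged} (codes 0/1/2)."""
    proba = _predict_proba(model, image)
    return np.argmax(proba, axis=2).astype(np.uint8)


def damage_mask(model: PixelClassifier, image: ScanImage) -> np.ndarray:
    """Boolean mask of pixels the classifier calls damaged."""
    return classify_pixels(model, image) == ANNOTATION_CLASSES.index("damaged")


def uncertainty_map(model: PixelClassifier, image: ScanImage) -> np.ndarray:
    """Per-pixel uncertainty ``1 - (top probability - runner-up)`` in [0, 1].

    High-uncertainty pixels are where new annotation labels pay off most in
    the retraining loop.
    """
    proba = _predict_proba(model, image)
    part = np.sort(proba, axis=2)
    return 1.0 - (part[..., -1] - part[..., -2])


# ---------------------------------------------------------------------------
# Colour-plane thresholding
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ThresholdRule:
    """Fixed two-boundary selection on one colour plane.

    Planes: R/G/B in counts (0..255); H hue in degrees [0, 360); S
    saturation in [0, 1]; I intensity = mean(R, G, B) in counts.
    """

    plane: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.plane not in ("R", "G", "B", "H", "S", "I"):
            raise ValueError(f"plane must be one of R,G,B,H,S,I, got {self.plane!r}")
        if self.lower > self.upper:
            raise ValueError(f"lower ({self.lower}) must be <= upper ({self.upper})")


def hsi_planes(pixels: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard HSI conversion: I = mean(R,G,B); S = 1 - min/I; H geometric.

    H is in degrees [0, 360), 0 where the denominator degenerates (gray
    pixels); S is 0 where I is 0.
    """
    rgb = pixels.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    i = rgb.mean(axis=2)
    mn = rgb.min(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(i > 0, 1.0 - mn / np.where(i > 0, i, 1.0), 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.degrees(np.arccos(np.clip(np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0), -1, 1)))
    h = np.where(b <= g, theta, 360.0 - theta)
    h = np.where(den > 0, h, 0.0)
    return h, s, i


def plane_values(image: ScanImage, plane: str) -> np.ndarray:
    rgb = image.pixels.astype(np.float64)
    if plane == "R":
        return rgb[..., 0]
    if plane == "G":
        return rgb[..., 1]
    if plane == "B":
        return rgb[..., 2]
    h, s, i = hsi_planes(image.pixels)
    return {"H": h, "S": s, "I": i}[plane]


def threshold_classify(
    image: ScanImage, rosette_rule: ThresholdRule, damage_rule: ThresholdRule
) -> np.ndarray:
    """Two-stage fixed-boundary thresholding.

    Stage 1 selects rosette pixels whose ``rosette_rule`` plane value lies
    in [lower, upper]; stage 2 marks, within that selection, the pixels
    whose ``damage_rule`` plane value lies in its range.
    """
    v1 = plane_values(image, rosette_rule.plane)
    sel = (v1 >= rosette_rule.lower) & (v1 <= rosette_rule.upper)
    v2 = plane_values(image, damage_rule.plane)
    return sel & (v2 >= damage_rule.lower) & (v2 <= damage_rule.upper)


# ---------------------------------------------------------------------------
# Grid mean-colour classification
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GridRule:
    """Square-unit mean-colour rule: unit side in mm, sensitivity 1..9."""

    unit_size: float
    sensitivity: int

    def __post_init__(self) -> None:
        if not self.unit_size > 0:
            raise ValueError(f"unit_size must be > 0, got {self.unit_size}")
        if not 1 <= self.sensitivity <= len(SENSITIVITY_CUTOFFS):
            raise ValueError(
                f"sensitivity must be in 1..{len(SENSITIVITY_CUTOFFS)}, got {self.sensitivity}"
            )


def grid_classify(image: ScanImage, rosette: RosetteMask, rule: GridRule) -> np.ndarray:
    """Tile the scan into squares and mark the green-deficient ones.

    For each square that overlaps the rosette, the mean RGB of its rosette
    pixels is computed and the square is marked damaged when the
    green-deficiency score ``g = mean(R, B) / max(mean G, 1)`` exceeds the
    cutoff for the requested sensitivity; cutoffs decrease strictly with
    sensitivity, so marked sets are nested across levels.
    """
    unit_px = int(round(rule.unit_size * image.dpi / 25.4))
    if unit_px < 2:
        raise ValueError(
            f"grid unit of {rule.unit_size} mm is below 2 px at {image.dpi} dpi"
        )
    cutoff = SENSITIVITY_CUTOFFS[rule.sensitivity - 1]
    h, w = image.shape
    mask = np.zeros((h, w), dtype=bool)
    rgb = image.pixels.astype(np.float64)
    rm = rosette.mask
    for r0 in range(0, h, unit_px):
        for c0 in range(0, w, unit_px):
            tile_mask = rm[r0 : r0 + unit_px, c0 : c0 + unit_px]
            if not tile_mask.any():
                continue
            tile = rgb[r0 : r0 + unit_px, c0 : c0 + unit_px][tile_mask]
            mr, mg, mb = tile.mean(axis=0)
            g_score = 0.5 * (mr + mb) / max(mg, 1.0)
            if g_score > cutoff:
                mask[r0 : r0 + unit_px, c0 : c0 + unit_px] = True
    return mask & rm


# ---------------------------------------------------------------------------
# Manual-grid reference emulation
# ---------------------------------------------------------------------------


def manual_grid_emulate(
    truth_damage: np.ndarray,
    grid_size: float,
    rule: str = "any-overlap",
    dpi: float = 150.0,
) -> float:
    """Emulate the manual dot-grid protocol on a damage annotation.

    A grid of ``grid_size`` mm squares is laid over the mask; squares are
    selected either when they overlap at least one damaged pixel
    (``any-overlap``, the practice the reference protocol implies) or when
    more than half of their pixels are damaged (``majority``).  The
    returned area is ``selected squares x grid_size**2``.

    Under ``any-overlap`` the selected squares cover every damaged pixel,
    so the returned area is always >= the pixel-exact area — the built-in
    overestimation of whole-square counting.
    """
    if not grid_size > 0:
        raise ValueError(f"grid_size must be > 0, got {grid_size}")
    if rule not in ("any-overlap", "majority"):
        raise ValueError(f"rule must be 'any-overlap' or 'majority', got {rule!r}")
    mask = np.asarray(truth_damage, dtype=bool)
    if not mask.any():
        return 0.0
    g = grid_size * dpi / 25.4  # grid pitch in pixel units
    h, w = mask.shape
    n_rows = int(np.floor(h / g)) + 1
    n_cols = int(np.floor(w / g)) + 1
    rows, cols = np.nonzero(mask)
    if rule == "any-overlap":
        # each damaged pixel is the square [r, r+1) x [c, c+1); mark every
        # grid cell it geometrically overlaps
        eps = 1e-9
        k0r = np.floor(rows / g).astype(np.intp)
        k1r = np.floor((rows + 1 - eps) / g).astype(np.intp)
        k0c = np.floor(cols / g).astype(np.intp)
        k1c = np.floor((cols + 1 - eps) / g).astype(np.intp)
        cells = np.zeros((max(n_rows, k1r.max() + 1), max(n_cols, k1c.max() + 1)), dtype=bool)
        for dr in range(int((k1r - k0r).max()) + 1):
            rr = k0r + dr
            ok_r = rr <= k1r
            for dc in range(int((k1c - k0c).max()) + 1):
                cc = k0c + dc
                ok = ok_r & (cc <= k1c)
                cells[rr[ok], cc[ok]] = True
        count = int(cells.sum())
    else:
        # assign each pixel to the cell containing its centre, select cells
        # where damaged pixels outnumber half the cell's pixels
        all_r, all_c = np.mgrid[0:h, 0:w]
        cell_of = (
            np.floor((all_r + 0.5) / g).astype(np.intp) * n_cols
            + np.floor((all_c + 0.5) / g).astype(np.intp)
        )
        total = np.bincount(cell_of.ravel(), minlength=n_rows * n_cols)
        dam = np.bincount(cell_of[mask].ravel(), minlength=n_rows * n_cols)
        count = int(np.sum(dam > 0.5 * total))
    return count * grid_size ** 2
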