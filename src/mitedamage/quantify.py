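"""From damage masks to corrected mm² measurements.

Raw damage masks from any classifier contain two kinds of error: scattered
small-cluster noise, and systematic false detections on confounding tissue
(trichome specks, pale young leaves).  The first is removed with a
connected-component size filter whose threshold is calibrated as the mean
cluster size detected on uninfested control rosettes — anything a classifier
calls damage on a control is by definition a false detection.  The second
is handled after area measurement by the control correction: the mean
damage *fraction* observed on controls of the same group is subtracted,
scaled by each treated rosette's total area,

    x̄_c = Σ(DA_ci / TA_ci) / n        A_i = DA_ti − x̄_c · TA_ti

Non-positive corrected values (controls "more damaged" than the treated
plant) are kept as explicit missing records so downstream comparisons can
report the attrition instead of silently shrinking.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .imaging import RosetteMask, pixel_area_mm2

__all__ = [
    "RosetteMeasurement",
    "CorrectionModel",
    "CorrectedMeasurement",
    "ClusterCalibration",
    "NoClustersError",
    "cluster_filter",
    "select_cluster_threshold",
    "measure",
    "fit_correction",
    "apply_correction",
]


class NoClustersError(ValueError):
    """Raised when no control mask contains any cluster: nothing to calibrate."""


@dataclasses.dataclass(frozen=True)
class RosetteMeasurement:
    """One rosette's total area (TA) and uncorrected damaged area (DA), mm²."""

    rosette_id: str
    genotype: str
    treatment: str  # "control" | "infested"
    condition_id: str
    background: str
    total_area: float
    damage_area_uncorrected: float

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "infested"):
            raise ValueError(f"treatment must be control|infested, got {self.treatment!r}")
        if not self.total_area > 0:
            raise ValueError(f"total_area must be > 0, got {self.total_area}")
        if not 0 <= self.damage_area_uncorrected <= self.total_area:
            raise ValueError(
                f"damage area {self.damage_area_uncorrected} outside [0, total_area]"
            )


@dataclasses.dataclass(frozen=True)
class CorrectionModel:
    """Mean control damage fraction x̄_c for one (genotype, condition, background)."""

    mean_control_fraction: float
    n_controls: int
    genotype: str
    condition_id: str
    background: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_control_fraction <= 1.0:
            raise ValueError("mean_control_fraction must be in [0, 1]")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")


@dataclasses.dataclass(frozen=True)
class CorrectedMeasurement:
    """Corrected damage A_i, or an explicit missing record when A_i <= 0."""

    rosette_id: str
    corrected_area: Optional[float]
    status: str  # "ok" | "dropped_nonpositive"

    def __post_init__(self) -> None:
        ok = self.status == "ok"
        if ok != (self.corrected_area is not None and self.corrected_area > 0):
            raise ValueError("status 'ok' iff corrected_area > 0")


@dataclasses.dataclass
class ClusterCalibration:
    """Calibration result: threshold plus the cluster size-frequency table."""

    threshold: int
    sizes: np.ndarray
    size_counts: Dict[int, int]

    @property
    def n_clusters(self) -> int:
        return int(len(self.sizes))


def _label(mask: np.ndarray, connectivity: int) -> Tuple[np.ndarray, int]:
    if connectivity == 4:
        structure = ndi.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndi.generate_binary_structure(2, 2)
    else:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    return ndi.label(mask, structure=structure)


def cluster_filter(damage_mask: np.ndarray, min_size: int, connectivity: int = 8) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` pixels.

    Components with exactly ``min_size`` pixels are kept (sizes strictly
    *under* the threshold are disregarded); ``min_size`` 0 or 1 is the
    identity.
    """
    if min_size < 0:
        raise ValueError(f"min_size must be >= 0, got {min_size}")
    mask = np.asarray(damage_mask, dtype=bool)
    if min_size <= 1 or not mask.any():
        return mask.copy()
    labels, n = _label(mask, connectivity)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def select_cluster_threshold(
    control_masks: Sequence[np.ndarray], connectivity: int = 8
) -> ClusterCalibration:
    """Calibrate the noise threshold from control-rosette damage masks.

    Pools the connected-component sizes across all masks (every cluster on
    an uninfested control is a false detection) and returns their mean,
    rounded to the nearest integer, together with the size-frequency table.
    """
    all_sizes: List[int] = []
    for mask in control_masks:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            continue
        labels, n = _label(mask, connectivity)
        sizes = np.bincount(labels.ravel())[1:]
        all_sizes.extend(int(s) for s in sizes if s > 0)
    if not all_sizes:
        raise NoClustersError("nothing to calibrate: no clusters in any control mask")
    sizes = np.array(sorted(all_sizes))
    threshold = int(np.floor(sizes.mean() + 0.5))  # round half up
    return ClusterCalibration(
        threshold=threshold, sizes=sizes, size_counts=dict(sorted(Counter(all_sizes).items()))
    )


def measure(
    damage_mask: np.ndarray,
    rosette_mask: RosetteMask,
    dpi: float,
    rosette_id: str = "",
    genotype: str = "",
    treatment: str = "infested",
    condition_id: str = "",
    background: str = "white",
) -> RosetteMeasurement:
    """Convert masks to mm²; damage is clipped to the rosette mask."""
    damage = np.asarray(damage_mask, dtype=bool)
    if damage.shape != rosette_mask.mask.shape:
        raise ValueError("damage and rosette masks must have the same shape")
    if not rosette_mask.mask.any():
        raise ValueError("empty rosette mask")
    px = pixel_area_mm2(dpi)
    da = float((damage & rosette_mask.mask).sum()) * px
    ta = float(rosette_mask.mask.sum()) * px
    return RosetteMeasurement(
        rosette_id=rosette_id, genotype=genotype, treatment=treatment,
        condition_id=condition_id, background=background,
        total_area=ta, damage_area_uncorrected=da,
    )


def fit_correction(controls: Sequence[RosetteMeasurement]) -> CorrectionModel:
    """x̄_c = mean over control rosettes of DA_ci / TA_ci.

    All controls must belong to one (genotype, condition, background) group
    analysed under the same thresholds as their treated counterparts.
    """
    if len(controls) == 0:
        raise ValueError("empty control list")
    keys = {(m.genotype, m.condition_id, m.background) for m in controls}
    if len(keys) != 1:
        raise ValueError(f"controls span multiple groups: {sorted(keys)}")
    for m in controls:
        if m.treatment != "control":
            raise ValueError(f"{m.rosette_id}: treatment is {m.treatment!r}, not control")
    fractions = [m.damage_area_uncorrected / m.total_area for m in controls]
    genotype, condition_id, background = next(iter(keys))
    return CorrectionModel(
        mean_control_fraction=float(np.mean(fractions)),
        n_controls=len(controls),
        genotype=genotype, condition_id=condition_id, background=background,
    )


def apply_correction(model: CorrectionModel, treated: RosetteMeasurement) -> CorrectedMeasurement:
    """A_i = DA_ti − x̄_c · TA_ti; non-positive results become missing records."""
    if treated.treatment != "infested":
        raise ValueError(f"{treated.rosette_id}: treatment must be 'infested'")
    if (treated.genotype, treated.condition_id, treated.background) != (
        model.genotype, model.condition_id, model.background
    ):
        raise ValueError(
            f"{treated.rosette_id}: group does not match correction model "
            f"({model.genotype}, {model.condition_id}, {model.background})"
        )
    a = treated.damage_area_uncorrected - model.mean_control_fraction * treated.total_area
    if a <= 0:
        return CorrectedMeasurement(rosette_id=treated.rosette_id,
                                    corrected_area=None, status="dropped_nonpositive")
    return CorrectedMeasurement(rosette_id=treated.rosette_id,
                                corrected_area=float(a), status="ok")
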