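"""End-to-end cohort pipelines on synthetic scans.

One call runs the whole workflow the package exists for: generate a seeded
cohort, train (or configure) a damage classifier, segment each rosette,
filter cluster noise with a threshold calibrated on the controls, measure
areas, and apply the per-genotype control correction.  Results come back as
a tidy per-rosette DataFrame that also carries the ground truth, so the
same object feeds the agreement statistics and the accuracy checks.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import classify as cls
from . import quantify as qt
from . import synthetic as syn
from .imaging import segment_rosette

__all__ = [
    "default_cohort_specs",
    "DEFAULT_THRESHOLD_RULES",
    "PipelineResult",
    "run_ml_pipeline",
    "run_threshold_pipeline",
    "manual_grid_areas",
]

#: Damage fractions spanning the susceptibility spectrum emulated by the
#: default cohort: a resistant, an intermediate and a susceptible genotype.
DEFAULT_DAMAGE_FRACTIONS = {
    "resistant": 0.01,
    "intermediate": 0.015,
    "susceptible": 0.05,
}

#: Tuned two-stage threshold rules for the synthetic palette: rosette
#: pixels by intensity (excludes both backgrounds), damage by yellowish hue.
DEFAULT_THRESHOLD_RULES = (
    cls.ThresholdRule(plane="I", lower=25.0, upper=235.0),
    cls.ThresholdRule(plane="H", lower=0.0, upper=80.0),
)

MEASUREMENT_COLUMNS = [
    "rosette_id", "genotype", "treatment", "condition_id", "background",
    "total_area_mm2", "damage_area_uncorrected_mm2", "corrected_area_mm2",
    "status", "true_damage_area_mm2", "true_rosette_area_mm2",
]


def default_cohort_specs(radius_mm: float = 14.0) -> List[syn.PhenotypeSpec]:
    return [
        syn.PhenotypeSpec(genotype_label=name, damage_fraction=frac,
                          rosette_radius=radius_mm)
        for name, frac in DEFAULT_DAMAGE_FRACTIONS.items()
    ]


@dataclasses.dataclass
class PipelineResult:
    """Per-rosette table plus the calibration artefacts of one run."""

    measurements: pd.DataFrame
    cluster_threshold: int
    correction_models: Dict[str, qt.CorrectionModel]
    scans: List[syn.SyntheticScan]
    damage_masks: List[np.ndarray]
    model: Optional[cls.PixelClassifier] = None

    def to_csv(self, path: str) -> None:
        self.measurements.to_csv(path, index=False, float_format="%.6f")

    def treated(self, genotype: Optional[str] = None) -> pd.DataFrame:
        df = self.measurements[self.measurements.treatment == "infested"]
        if genotype is not None:
            df = df[df.genotype == genotype]
        return df


def _quantify_cohort(
    scans: Sequence[syn.SyntheticScan],
    raw_masks: Sequence[np.ndarray],
    condition_id: str,
    connectivity: int,
    min_cluster_size: Optional[int],
) -> "tuple[pd.DataFrame, int, Dict[str, qt.CorrectionModel], List[np.ndarray]]":
    # cluster threshold calibrated on the control masks unless fixed
    control_masks = [m for s, m in zip(scans, raw_masks) if s.treatment == "control"]
    if min_cluster_size is None:
        try:
            calib = qt.select_cluster_threshold(control_masks, connectivity=connectivity)
            threshold = calib.threshold
        except qt.NoClustersError:
            threshold = 0
    else:
        threshold = min_cluster_size

    measurements: List[qt.RosetteMeasurement] = []
    filtered: List[np.ndarray] = []
    for scan, raw in zip(scans, raw_masks):
        rosette = segment_rosette(scan.image)
        mask = qt.cluster_filter(raw, threshold, connectivity=connectivity)
        filtered.append(mask)
        measurements.append(
            qt.measure(
                mask, rosette, scan.image.dpi,
                rosette_id=scan.scan_id, genotype=scan.spec.genotype_label,
                treatment=scan.treatment, condition_id=condition_id,
                background=scan.image.background,
            )
        )

    # per-genotype control correction
    models: Dict[str, qt.CorrectionModel] = {}
    for genotype in sorted({m.genotype for m in measurements}):
        controls = [m for m in measurements if m.genotype == genotype and m.treatment == "control"]
        if controls:
            models[genotype] = qt.fit_correction(controls)

    rows = []
    for scan, m in zip(scans, measurements):
        corrected, status = np.nan, ""
        if m.treatment == "infested" and m.genotype in models:
            cm = qt.apply_correction(models[m.genotype], m)
            status = cm.status
            corrected = cm.corrected_area if cm.corrected_area is not None else np.nan
        rows.append({
            "rosette_id": m.rosette_id, "genotype": m.genotype,
            "treatment": m.treatment, "condition_id": m.condition_id,
            "background": m.background, "total_area_mm2": m.total_area,
            "damage_area_uncorrected_mm2": m.damage_area_uncorrected,
            "corrected_area_mm2": corrected, "status": status,
            "true_damage_area_mm2": scan.truth.true_damage_area,
            "true_rosette_area_mm2": scan.truth.true_rosette_area,
        })
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return df, threshold, models, filtered


def run_ml_pipeline(
    specs: Optional[Sequence[syn.PhenotypeSpec]] = None,
    n_replicates: int = 8,
    seed: int = 0,
    dpi: float = 150.0,
    background: str = "black",
    n_train_scans: int = 6,
    labels_per_class: int = 400,
    n_trees: int = cls.DEFAULT_N_TREES,
    scales: Sequence[float] = cls.DEFAULT_SCALES,
    connectivity: int = 8,
    min_cluster_size: Optional[int] = None,
    condition_id: str = "synthetic",
) -> PipelineResult:
    """Run the machine-learning pipeline on a synthetic cohort.

    Training scans are drawn evenly across genotypes, alternating infested
    and control rosettes, and annotated with sparse rater-style labels
    (recognisable pale tissue is labelled healthy, ambiguous trichome
    glints are skipped); the forest then classifies every scan, cluster
    noise is filtered with the control-calibrated threshold, and damage is
    corrected per genotype.
    """
    if specs is None:
        specs = default_cohort_specs()
    scans = syn.generate_cohort(specs, n_replicates, seed, dpi=dpi, background=background)

    # pick training scans: first replicate of each genotype, infested first
    # so the damaged class is always represented
    train_scans: List[syn.SyntheticScan] = []
    for treatment in ("infested", "control"):
        for genotype in sorted({s.spec.genotype_label for s in scans}):
            pick = [s for s in scans if s.treatment == treatment
                    and s.spec.genotype_label == genotype]
            if pick and len(train_scans) < n_train_scans:
                train_scans.append(pick[0])
    label_rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    label_sets = [
        syn.sample_labels(s, labels_per_class, int(label_rng.integers(2**31 - 1)))
        for s in train_scans
    ]
    model = cls.train_pixel_classifier(
        [s.image for s in train_scans], label_sets,
        seed=seed, n_trees=n_trees, scales=scales,
    )
    raw_masks = [cls.damage_mask(model, s.image) for s in scans]
    df, threshold, models, filtered = _quantify_cohort(
        scans, raw_masks, condition_id, connectivity, min_cluster_size
    )
    return PipelineResult(measurements=df, cluster_threshold=threshold,
                          correction_models=models, scans=scans,
                          damage_masks=filtered, model=model)


def run_threshold_pipeline(
    specs: Sequence[syn.PhenotypeSpec],
    n_replicates: int = 8,
    seed: int = 0,
    dpi: float = 150.0,
    background: str = "white",
    rules: "tuple[cls.ThresholdRule, cls.ThresholdRule]" = DEFAULT_THRESHOLD_RULES,
    connectivity: int = 8,
    min_cluster_size: Optional[int] = 0,
    condition_id: str = "synthetic",
) -> PipelineResult:
    """Run the fixed-boundary colour-threshold pipeline on a cohort.

    Unlike the machine-learning tandem, the plain thresholding strategy has
    no cluster-noise filtering stage (``min_cluster_size`` defaults to 0);
    its false detections are handled entirely by the control correction.
    """
    scans = syn.generate_cohort(specs, n_replicates, seed, dpi=dpi, background=background)
    rosette_rule, damage_rule = rules
    raw_masks = [cls.threshold_classify(s.image, rosette_rule, damage_rule) for s in scans]
    df, threshold, models, filtered = _quantify_cohort(
        scans, raw_masks, condition_id, connectivity, min_cluster_size
    )
    return PipelineResult(measurements=df, cluster_threshold=threshold,
                          correction_models=models, scans=scans, damage_masks=filtered)


def manual_grid_areas(
    scans: Sequence[syn.SyntheticScan], grid_size: float = 0.25, rule: str = "any-overlap"
) -> pd.DataFrame:
    """Manual-grid reference areas on the ground-truth damage annotation."""
    rows = [
        {
            "rosette_id": s.scan_id,
            "manual_grid_area_mm2": cls.manual_grid_emulate(
                s.truth.damage_mask, grid_size, rule=rule, dpi=s.image.dpi
            ),
            "true_damage_area_mm2": s.truth.true_damage_area,
        }
        for s in scans
    ]
    return pd.DataFrame(rows)
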