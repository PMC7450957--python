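"""Seeded synthetic rosette scans with per-pixel ground truth.

Real validation data for mite-damage phenotyping are whole-rosette flatbed
scans: overlapping green leaves with petioles, pale chlorotic feeding
lesions, and a set of damage look-alikes (bright trichome specks, pale young
leaves, lightened leaf margins) on a white or black background.  This module
draws that scene procedurally so that every downstream stage — segmentation,
pixel classification, cluster filtering, control correction, agreement
statistics — can be exercised against a known per-pixel truth.

Geometry is deliberately simple (superellipse-ish leaf lobes with thin
petiole rectangles radiating from a centre); the point is to reproduce the
*failure modes* that matter for quantification (confounders that automatic
classifiers call damage, petioles visible against the background), not
photorealism.
"""

from __future__ import annotations

import dataclasses
import json
from typing import List, Sequence

import numpy as np
from PIL import Image

from .imaging import BACKGROUNDS, ScanImage, pixel_area_mm2

__all__ = [
    "CLASS_BACKGROUND",
    "CLASS_HEALTHY",
    "CLASS_DAMAGED",
    "CLASS_CONFOUNDER",
    "CLASS_NAMES",
    "PhenotypeSpec",
    "GroundTruth",
    "SyntheticScan",
    "generate_rosette",
    "generate_cohort",
    "sample_labels",
    "write_truth",
]

# Ground-truth pixel classes.  `confounder` marks tissue that *looks* pale
# (trichome glints, young-leaf pallor, lightened margins) but is not mite
# damage; it is what makes the control-correction stage non-trivial.
CLASS_BACKGROUND = 0
CLASS_HEALTHY = 1
CLASS_DAMAGED = 2
CLASS_CONFOUNDER = 3
CLASS_NAMES = ("background", "healthy", "damaged", "confounder")

# Rendering palette (8-bit RGB).  Chlorosis interpolates from the leaf green
# toward a pale yellow-white; trichome specks are brighter still.
_PALE_CHLOROTIC = np.array([235.0, 228.0, 170.0])
_SPECK_COLOUR = np.array([242.0, 238.0, 195.0])
_MARGIN_TINT = np.array([165.0, 220.0, 150.0])
_PALE_CENTER_TINT = np.array([160.0, 210.0, 130.0])
_WHITE_BG = 252.0
_BLACK_BG = 5.0


@dataclasses.dataclass(frozen=True)
class PhenotypeSpec:
    """Target phenotype of one synthetic genotype.

    ``damage_fraction`` is the fraction of rosette pixels rendered chlorotic
    (0 for uninfested controls); ``confounder_density`` is the number of
    bright specks per cm² of rosette tissue; ``pale_center`` adds the
    young-leaf pallor seen at the rosette centre.
    """

    genotype_label: str
    n_leaves: int = 10
    rosette_radius: float = 14.0  # mm
    damage_fraction: float = 0.0
    spot_size_mean: float = 0.8  # mm² per chlorotic lesion
    spot_size_cv: float = 0.6
    confounder_density: float = 4.0  # specks per cm² of rosette
    pale_center: bool = True

    def validate(self) -> None:
        if self.n_leaves < 3:
            raise ValueError(f"n_leaves must be >= 3, got {self.n_leaves}")
        if not self.rosette_radius > 0:
            raise ValueError(f"rosette_radius must be > 0, got {self.rosette_radius}")
        if not 0.0 <= self.damage_fraction <= 1.0:
            raise ValueError(
                f"damage_fraction must be in [0, 1], got {self.damage_fraction}"
            )
        if self.confounder_density < 0:
            raise ValueError(
                f"confounder_density must be >= 0, got {self.confounder_density}"
            )
        if not self.spot_size_mean > 0:
            raise ValueError(f"spot_size_mean must be > 0, got {self.spot_size_mean}")
        if self.spot_size_cv < 0:
            raise ValueError(f"spot_size_cv must be >= 0, got {self.spot_size_cv}")


#: Sub-types of confounder tissue (0 = not a confounder).  Margins and the
#: pale centre are recognisable as tissue by a rater; trichome specks are
#: the genuinely ambiguous glints a rater leaves unlabelled.
CONFOUNDER_NONE = 0
CONFOUNDER_MARGIN = 1
CONFOUNDER_PALE_CENTER = 2
CONFOUNDER_SPECK = 3


@dataclasses.dataclass
class GroundTruth:
    """Per-pixel class map plus the true areas it implies (mm²)."""

    class_map: np.ndarray  # uint8 of CLASS_* codes
    true_damage_area: float
    true_rosette_area: float
    confounder_kind: np.ndarray | None = None  # uint8 of CONFOUNDER_* codes

    @property
    def rosette_mask(self) -> np.ndarray:
        return self.class_map != CLASS_BACKGROUND

    @property
    def damage_mask(self) -> np.ndarray:
        return self.class_map == CLASS_DAMAGED


@dataclasses.dataclass
class SyntheticScan:
    """A rendered scan together with the truth it was rendered from."""

    image: ScanImage
    truth: GroundTruth
    spec: PhenotypeSpec
    seed: int
    treatment: str = "infested"
    scan_id: str = ""


def _ellipse_mask(shape, center_rc, angle, half_len, half_wid):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    dr = rr - center_rc[0]
    dc = cc - center_rc[1]
    u = dc * np.cos(angle) + dr * np.sin(angle)
    v = -dc * np.sin(angle) + dr * np.cos(angle)
    return (u / half_len) ** 2 + (v / half_wid) ** 2 <= 1.0


def generate_rosette(
    spec: PhenotypeSpec,
    seed: int,
    dpi: float = 150.0,
    background: str = "white",
) -> SyntheticScan:
    """Render one rosette scan with per-pixel ground truth.

    Deterministic for fixed ``(spec, seed, dpi, background)``; the two
    background tags share the same random stream, so the same seed yields
    the same plant geometry and truth on white and on black.
    """
    spec.validate()
    if dpi < 150:
        raise ValueError(f"dpi must be >= 150, got {dpi}")
    if background not in BACKGROUNDS:
        raise ValueError(f"background must be one of {BACKGROUNDS}")
    rng = np.random.default_rng(seed)
    ppm = dpi / 25.4  # pixels per mm
    size = int(round(2.5 * spec.rosette_radius * ppm))
    center = (size - 1) / 2.0

    # --- leaf geometry: lobes + petioles radiating from the centre -------
    leaf_id = np.zeros((size, size), dtype=np.int32)
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    base_angle = rng.uniform(0, 2 * np.pi)
    n = spec.n_leaves
    for i in range(n):
        angle = base_angle + 2 * np.pi * i / n + rng.normal(0, 0.12)
        length = spec.rosette_radius * rng.uniform(0.65, 1.0) * ppm
        width = length * rng.uniform(0.38, 0.55)
        pet_len = 0.30 * length
        # petiole: thin rectangle from the centre to the leaf base
        dr = rr - center
        dc = cc - center
        u = dc * np.cos(angle) + dr * np.sin(angle)
        v = -dc * np.sin(angle) + dr * np.cos(angle)
        pet_w = max(1.0, 0.35 * ppm)
        petiole = (u >= 0) & (u <= pet_len + 0.2 * length) & (np.abs(v) <= pet_w / 2)
        blade_center = (
            center + np.sin(angle) * (pet_len + length / 2),
            center + np.cos(angle) * (pet_len + length / 2),
        )
        blade = _ellipse_mask((size, size), blade_center, angle, length / 2, width / 2)
        leaf_id[petiole | blade] = i + 1

    rosette = leaf_id > 0
    if not rosette.any():
        raise ValueError("degenerate spec: rosette rendered no pixels")

    # the rosette centre is solid tissue: enclosed gaps between petioles
    # are filled and assigned to the nearest leaf
    from scipy import ndimage as ndi

    filled = ndi.binary_fill_holes(rosette)
    holes = filled & ~rosette
    if holes.any():
        ind = ndi.distance_transform_edt(~rosette, return_distances=False,
                                         return_indices=True)
        leaf_id[holes] = leaf_id[ind[0][holes], ind[1][holes]]
        rosette = leaf_id > 0
    n_rosette = int(rosette.sum())

    # --- confounder: lightened leaf margins (1 px band) ------------------

    margin = rosette & ~ndi.binary_erosion(rosette, iterations=1)

    # --- chlorotic lesions: irregular blobs confined to leaf tissue ------
    damage = np.zeros_like(rosette)
    px_area = pixel_area_mm2(dpi)
    target = int(round(spec.damage_fraction * n_rosette))
    added = 0
    attempts = 0
    if spec.spot_size_cv > 0:
        sigma2 = np.log1p(spec.spot_size_cv ** 2)
        mu = np.log(spec.spot_size_mean) - sigma2 / 2
    while added < target and attempts < 10_000:
        attempts += 1
        candidates = np.flatnonzero(rosette & ~damage)
        if candidates.size == 0:
            break
        idx = int(rng.choice(candidates))
        cy, cx = divmod(idx, size)
        if spec.spot_size_cv > 0:
            area = float(rng.lognormal(mu, np.sqrt(sigma2)))
        else:
            area = spec.spot_size_mean
        n_px = max(3, int(round(area / px_area)))
        r0 = np.sqrt(n_px / np.pi)
        k = rng.uniform(0.8, 1.3)
        theta = rng.uniform(0, np.pi)
        blob = _ellipse_mask((size, size), (cy, cx), theta, r0 * k, r0 / k)
        blob &= rosette & ~damage
        coords = np.flatnonzero(blob)
        if coords.size == 0:
            continue
        need = target - added
        if coords.size > need:
            # trim the blob to the pixels nearest its centre so the total
            # damaged fraction lands on the requested value
            by, bx = np.divmod(coords, size)
            d2 = (by - cy) ** 2 + (bx - cx) ** 2
            coords = coords[np.argsort(d2, kind="stable")[:need]]
        flat = damage.ravel()
        flat[coords] = True
        added += coords.size

    # --- confounder specks (trichome glints) on healthy tissue -----------
    speck = np.zeros_like(rosette)
    rosette_cm2 = n_rosette * px_area / 100.0
    n_specks = int(rng.poisson(spec.confounder_density * rosette_cm2))
    healthy_pool = rosette & ~damage
    for _ in range(n_specks):
        candidates = np.flatnonzero(healthy_pool & ~speck)
        if candidates.size == 0:
            break
        idx = int(rng.choice(candidates))
        cy, cx = divmod(idx, size)
        s_px = max(1.0, rng.lognormal(np.log(5.0), 0.7))
        r0 = np.sqrt(s_px / np.pi)
        blob = _ellipse_mask((size, size), (cy, cx), 0.0, r0, r0)
        speck |= blob & healthy_pool

    # --- confounder: pale young-leaf centre -------------------------------
    pale = np.zeros_like(rosette)
    if spec.pale_center:
        r_pale = 0.30 * spec.rosette_radius * ppm
        pale = _ellipse_mask((size, size), (center, center), 0.0, r_pale, r_pale)
        pale &= rosette & ~damage & ~speck

    # --- class map (damage wins over margin; specks/pale on healthy only) -
    class_map = np.zeros((size, size), dtype=np.uint8)
    class_map[rosette] = CLASS_HEALTHY
    class_map[margin] = CLASS_CONFOUNDER
    class_map[pale] = CLASS_CONFOUNDER
    class_map[speck] = CLASS_CONFOUNDER
    class_map[damage] = CLASS_DAMAGED
    confounder_kind = np.zeros((size, size), dtype=np.uint8)
    confounder_kind[margin] = CONFOUNDER_MARGIN
    confounder_kind[pale] = CONFOUNDER_PALE_CENTER
    confounder_kind[speck] = CONFOUNDER_SPECK
    confounder_kind[class_map != CLASS_CONFOUNDER] = CONFOUNDER_NONE

    # --- rendering ---------------------------------------------------------
    img = np.empty((size, size, 3), dtype=np.float64)
    bg = _WHITE_BG if background == "white" else _BLACK_BG
    img[:] = bg
    img += rng.normal(0.0, 3.0, img.shape)  # scanner background noise
    for i in range(n):
        m = leaf_id == i + 1
        if not m.any():
            continue
        g = rng.normal(150.0, 12.0)
        r = rng.normal(70.0, 10.0)
        b = rng.normal(50.0, 8.0)
        img[m] = (r, g, b)
    img[rosette] += rng.normal(0.0, 5.0, (int(rosette.sum()), 3))
    for m, tint, w in ((margin, _MARGIN_TINT, 0.35), (pale, _PALE_CENTER_TINT, 0.5)):
        if m.any():
            img[m] = (1 - w) * img[m] + w * tint
    if damage.any():
        alpha = rng.uniform(0.70, 1.0, (int(damage.sum()), 1))
        img[damage] = (1 - alpha) * img[damage] + alpha * _PALE_CHLOROTIC
        img[damage] += rng.normal(0.0, 4.0, (int(damage.sum()), 3))
    if speck.any():
        img[speck] = _SPECK_COLOUR + rng.normal(0.0, 4.0, (int(speck.sum()), 3))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        class_map=class_map,
        true_damage_area=float(damage.sum()) * px_area,
        true_rosette_area=float(n_rosette) * px_area,
        confounder_kind=confounder_kind,
    )
    image = ScanImage(pixels=pixels, dpi=dpi, background=background)
    return SyntheticScan(image=image, truth=truth, spec=spec, seed=seed,
                         treatment="control" if spec.damage_fraction == 0 else "infested",
                         scan_id=f"{spec.genotype_label}-s{seed}")


def generate_cohort(
    specs: Sequence[PhenotypeSpec],
    n_replicates: int,
    seed: int,
    dpi: float = 150.0,
    background: str = "white",
) -> List[SyntheticScan]:
    """Generate a treated + control cohort for each phenotype spec.

    For every spec, ``n_replicates`` infested scans (damage fraction as
    given) and ``n_replicates`` control scans (damage fraction forced to 0,
    confounders retained) are produced, with replicate-level jitter on
    rosette radius and leaf count.  Child seeds derive deterministically
    from ``seed``.
    """
    if len(specs) == 0:
        raise ValueError("specs list must not be empty")
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    rng = np.random.default_rng(seed)
    scans: List[SyntheticScan] = []
    for spec in specs:
        spec.validate()
        for treatment in ("infested", "control"):
            for rep in range(n_replicates):
                child_seed = int(rng.integers(0, 2**31 - 1))
                radius = spec.rosette_radius * float(rng.uniform(0.9, 1.1))
                leaves = max(3, spec.n_leaves + int(rng.integers(-1, 2)))
                rep_spec = dataclasses.replace(
                    spec,
                    rosette_radius=radius,
                    n_leaves=leaves,
                    damage_fraction=0.0 if treatment == "control" else spec.damage_fraction,
                )
                scan = generate_rosette(rep_spec, child_seed, dpi=dpi, background=background)
                scan.treatment = treatment
                scan.scan_id = f"{spec.genotype_label}-{treatment}-{rep}"
                scans.append(scan)
    return scans


def sample_labels(scan: SyntheticScan, n_per_class: int, seed: int):
    """Emulate a rater's sparse training annotation from ground truth.

    Samples up to ``n_per_class`` pixels for each of the three annotation
    classes.  A rater recognises lightened leaf margins and young-leaf
    pallor as tissue, so those confounders enter the ``healthy`` pool;
    trichome glints (specks) are genuinely ambiguous and are never
    labelled — which is exactly what lets a trained classifier confuse
    them with damage later.
    """
    from .classify import LabelSet

    rng = np.random.default_rng(seed)
    cmap = scan.truth.class_map
    kind = scan.truth.confounder_kind
    healthy_pool = cmap == CLASS_HEALTHY
    if kind is not None:
        healthy_pool |= (cmap == CLASS_CONFOUNDER) & np.isin(
            kind, (CONFOUNDER_MARGIN, CONFOUNDER_PALE_CENTER)
        )
    pools = (
        ("background", cmap == CLASS_BACKGROUND),
        ("healthy", healthy_pool),
        ("damaged", cmap == CLASS_DAMAGED),
    )
    rows, cols, names = [], [], []
    for name, pool in pools:
        coords = np.flatnonzero(pool)
        if coords.size == 0:
            continue
        take = min(n_per_class, coords.size)
        chosen = rng.choice(coords, size=take, replace=False)
        r, c = np.divmod(chosen, cmap.shape[1])
        rows.extend(int(v) for v in r)
        cols.extend(int(v) for v in c)
        names.extend([name] * take)
    return LabelSet(rows=np.array(rows), cols=np.array(cols), classes=list(names))


def write_truth(scan: SyntheticScan, png_path: str, json_path: str,
                kind_path: str | None = None) -> None:
    """Write the label map as a single-channel PNG plus a JSON sidecar.

    ``kind_path``, if given, stores the confounder sub-type map alongside.
    """
    Image.fromarray(scan.truth.class_map, mode="L").save(png_path)
    if kind_path is not None and scan.truth.confounder_kind is not None:
        Image.fromarray(scan.truth.confounder_kind, mode="L").save(kind_path)
    sidecar = {
        "seed": scan.seed,
        "spec": dataclasses.asdict(scan.spec),
        "treatment": scan.treatment,
        "true_damage_area_mm2": scan.truth.true_damage_area,
        "true_rosette_area_mm2": scan.truth.true_rosette_area,
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_truth(image_path: str, truth_png: str, kind_png: str | None = None,
               background: str = "white", dpi: float | None = None) -> SyntheticScan:
    """Reload a written synthetic scan (image + truth maps + sidecar)."""
    import os

    from .imaging import read_scan

    image = read_scan(image_path, background=background, dpi_override=dpi)
    class_map = np.asarray(Image.open(truth_png), dtype=np.uint8)
    kind = None
    if kind_png is not None and os.path.exists(kind_png):
        kind = np.asarray(Image.open(kind_png), dtype=np.uint8)
    json_path = os.path.splitext(truth_png)[0] + ".json"
    with open(json_path) as fh:
        sidecar = json.load(fh)
    spec = PhenotypeSpec(**sidecar["spec"])
    px = pixel_area_mm2(image.dpi)
    truth = GroundTruth(
        class_map=class_map,
        true_damage_area=float((class_map == CLASS_DAMAGED).sum()) * px,
        true_rosette_area=float((class_map != CLASS_BACKGROUND).sum()) * px,
        confounder_kind=kind,
    )
    return SyntheticScan(image=image, truth=truth, spec=spec,
                         seed=int(sidecar["seed"]), treatment=sidecar["treatment"])
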