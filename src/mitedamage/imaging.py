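"""Scan I/O, physical calibration and rosette/background segmentation.

A flatbed scan enters the pipeline as an 8-bit RGB pixel grid with dpi
metadata; dpi is the only calibration needed because the physical pixel
pitch is ``25.4 / dpi`` mm.  Scanner brightness/contrast settings are
emulated as a per-pixel linear transform so that a whole condition grid
(automatic setting, +/-10 brightness, extreme settings, white or black
background) can be replayed on the same underlying scene.
"""

from __future__ import annotations

import dataclasses
import os
from typing import List, Tuple

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage as ndi

__all__ = [
    "ScanImage",
    "ScanCondition",
    "RosetteMask",
    "NonRGBImageError",
    "MissingDpiError",
    "NoPlantFoundError",
    "read_scan",
    "write_scan",
    "pixel_area_mm2",
    "contrast_gain",
    "apply_scan_condition",
    "segment_rosette",
    "split_rosettes",
]

BACKGROUNDS = ("white", "black")

#: RGB reference colour of each background tag and the default Euclidean
#: distance beyond which a pixel counts as plant tissue.
BACKGROUND_REFERENCE = {"white": (255.0, 255.0, 255.0), "black": (0.0, 0.0, 0.0)}
DEFAULT_PLANT_DISTANCE = 60.0


class NonRGBImageError(ValueError):
    """Raised when a scan file is not 8-bit three-channel RGB."""


class MissingDpiError(ValueError):
    """Raised when a scan file carries no dpi metadata and no override is given."""


class NoPlantFoundError(ValueError):
    """Raised when rosette segmentation finds no plant pixels."""


@dataclasses.dataclass
class ScanImage:
    """8-bit RGB scan with physical calibration.

    Parameters
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array, row-major, origin top-left.
    dpi:
        Scan resolution in dots per inch (> 0).
    background:
        ``"white"`` or ``"black"`` scanning background tag.
    """

    pixels: np.ndarray
    dpi: float
    background: str = "white"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise NonRGBImageError(
                f"expected an (H, W, 3) RGB array, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise NonRGBImageError(f"expected uint8 channels, got {self.pixels.dtype}")
        if not self.dpi > 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")
        if self.background not in BACKGROUNDS:
            raise ValueError(f"background must be one of {BACKGROUNDS}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def pixel_area_mm2(self) -> float:
        return pixel_area_mm2(self.dpi)


@dataclasses.dataclass(frozen=True)
class ScanCondition:
    """One scanner brightness/contrast setting on one background.

    Brightness and contrast are stored exactly as the scanner UI reports
    them; both orderings seen in practice are accommodated by keeping the
    two fields explicit rather than positional.
    """

    condition_id: str
    brightness: float
    contrast: float
    background: str = "white"

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise ValueError(f"background must be one of {BACKGROUNDS}")


@dataclasses.dataclass
class RosetteMask:
    """Binary plant-tissue mask aligned with its source scan."""

    mask: np.ndarray
    dpi: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.dpi > 0:
            raise ValueError("dpi must be positive")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * pixel_area_mm2(self.dpi)


def pixel_area_mm2(dpi: float) -> float:
    """Physical area of one pixel, in mm², at the given scan resolution."""
    if not dpi > 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    return (25.4 / dpi) ** 2


def read_scan(path: str, background: str = "white", dpi_override: float | None = None) -> ScanImage:
    """Read a TIFF or PNG scan, requiring dpi metadata unless overridden."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode != "RGB":
            raise NonRGBImageError(f"{path}: image mode {im.mode!r} is not RGB")
        dpi_info = im.info.get("dpi")
        pixels = np.asarray(im, dtype=np.uint8)
    dpi = None
    if dpi_info is not None:
        dpi = float(dpi_info[0]) if isinstance(dpi_info, (tuple, list)) else float(dpi_info)
        if dpi <= 0:
            dpi = None
        elif abs(dpi - round(dpi)) < 0.05:
            # PNG stores pixel density in dots per metre; undo the round-trip
            # error for the integer dpi values scanners actually use
            dpi = float(round(dpi))
    if dpi is None:
        if dpi_override is None:
            raise MissingDpiError(f"{path}: no dpi metadata and no dpi_override supplied")
        dpi = float(dpi_override)
    return ScanImage(pixels=pixels, dpi=dpi, background=background)


def write_scan(image: ScanImage, path: str) -> None:
    """Write a scan to TIFF or PNG, embedding dpi metadata (lossless)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels, resolution=(image.dpi, image.dpi),
                         resolutionunit="INCH")
    elif ext == ".png":
        Image.fromarray(image.pixels).save(path, dpi=(image.dpi, image.dpi))
    else:
        raise ValueError(f"unsupported scan format {ext!r} (use .tif/.tiff/.png)")


def contrast_gain(contrast: float) -> float:
    """Standard 8-bit contrast curve gain; identity (1.0) at contrast 0."""
    return (259.0 * (contrast + 255.0)) / (255.0 * (259.0 - contrast))


def apply_scan_condition(image: ScanImage, condition: ScanCondition) -> ScanImage:
    """Replay a scanner brightness/contrast setting on an existing scan.

    The mapping is ``out = clip(gain(contrast) * (in - 128) + 128 + brightness)``
    applied per channel about mid-gray, so brightness is an exact additive
    offset in counts and contrast 0 leaves pixel values untouched.
    """
    if condition.background != image.background:
        raise ValueError(
            f"condition background {condition.background!r} does not match "
            f"image background {image.background!r}"
        )
    gain = contrast_gain(condition.contrast)
    out = gain * (image.pixels.astype(np.float64) - 128.0) + 128.0 + condition.brightness
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return ScanImage(pixels=out, dpi=image.dpi, background=image.background)


def _plant_distance(image: ScanImage) -> np.ndarray:
    ref = np.array(BACKGROUND_REFERENCE[image.background], dtype=np.float64)
    diff = image.pixels.astype(np.float64) - ref
    return np.sqrt((diff ** 2).sum(axis=2))


def segment_rosette(image: ScanImage, threshold: float = DEFAULT_PLANT_DISTANCE) -> RosetteMask:
    """Separate a single rosette from the scanning background.

    Pixels whose RGB distance from the background reference exceeds
    ``threshold`` are plant candidates; the largest connected component is
    kept and its holes (e.g. strongly bleached lesion interiors on a white
    background) are filled.
    """
    plant = _plant_distance(image) > threshold
    labels, n = ndi.label(plant)
    if n == 0:
        raise NoPlantFoundError("no plant pixels above the background threshold")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    mask = ndi.binary_fill_holes(mask)
    return RosetteMask(mask=mask, dpi=image.dpi)


def split_rosettes(
    image: ScanImage,
    min_area_mm2: float,
    threshold: float = DEFAULT_PLANT_DISTANCE,
    margin_px: int = 5,
) -> List[Tuple[ScanImage, RosetteMask]]:
    """Individualize rosettes on a multi-plant scan.

    Connected plant components with physical area at least ``min_area_mm2``
    are each cropped (with a margin) together with their own mask, ordered
    top-left to bottom-right by bounding-box origin.
    """
    plant = _plant_distance(image) > threshold
    plant = ndi.binary_fill_holes(plant)
    labels, n = ndi.label(plant)
    px_area = pixel_area_mm2(image.dpi)
    out: List[Tuple[ScanImage, RosetteMask]] = []
    slices = ndi.find_objects(labels)
    entries = []
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        if comp.sum() * px_area < min_area_mm2:
            continue
        entries.append((sl[0].start, sl[1].start, lab, sl))
    entries.sort(key=lambda e: (e[0], e[1]))
    h, w = image.shape
    for r0, c0, lab, sl in entries:
        rs = slice(max(0, sl[0].start - margin_px), min(h, sl[0].stop + margin_px))
        cs = slice(max(0, sl[1].start - margin_px), min(w, sl[1].stop + margin_px))
        crop = ScanImage(
            pixels=image.pixels[rs, cs].copy(), dpi=image.dpi, background=image.background
        )
        mask = RosetteMask(mask=(labels[rs, cs] == lab), dpi=image.dpi)
        out.append((crop, mask))
    return out
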