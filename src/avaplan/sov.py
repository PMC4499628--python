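"""Detection and cropping of the Sinus of Valsalva (SOV).

The valve sits in the central part of the reformatted valve-plane image, so
detection is deliberately simple: crop the central window, binarize with a
histogram-based global threshold (Otsu), drop small objects (< 700 px) and
objects touching the border, keep the surviving component nearest the image
center, and return its padded bounding box mapped back to original-image
coordinates.  All later stages run on the cropped image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border as _sk_clear_border

from .errors import ConfigurationError, DetectionError, InputError
from .io import BinaryMask, GrayImage

__all__ = [
    "CropRegion",
    "SovConfig",
    "preliminary_crop",
    "global_threshold",
    "remove_small_objects",
    "clear_border_objects",
    "detect_sov",
    "crop_image",
]

MIN_CROP_SIZE = 32


@dataclass(frozen=True)
class CropRegion:
    """Half-open pixel-index window [row_start, row_stop) x [col_start, col_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ConfigurationError(f"empty crop region: {self}")
        if self.row_start < 0 or self.col_start < 0:
            raise ConfigurationError(f"crop region outside image bounds: {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)

    @property
    def center(self) -> tuple[float, float]:
        return (
            (self.row_start + self.row_stop - 1) / 2.0,
            (self.col_start + self.col_stop - 1) / 2.0,
        )

    def contains(self, other: "CropRegion") -> bool:
        return (
            self.row_start <= other.row_start
            and self.row_stop >= other.row_stop
            and self.col_start <= other.col_start
            and self.col_stop >= other.col_stop
        )


@dataclass
class SovConfig:
    """Knobs of the detection stage.

    central_fraction: fraction of each axis kept by the preliminary crop.
    min_object_pixels: components strictly smaller than this are discarded.
    bbox_pad_fraction: padding added around the detected bounding box,
    as a fraction of the box size per axis.
    """

    central_fraction: float = 0.5
    min_object_pixels: int = 700
    bbox_pad_fraction: float = 0.1


def preliminary_crop(
    image: GrayImage, central_fraction: float = 0.5
) -> tuple[GrayImage, CropRegion]:
    """Crop the centered window covering ``central_fraction`` of each axis."""
    if not 0 < central_fraction <= 1:
        raise ConfigurationError(
            f"central_fraction must be in (0, 1], got {central_fraction}"
        )
    nr, nc = image.shape
    hr = max(int(round(nr * central_fraction)), 1)
    hc = max(int(round(nc * central_fraction)), 1)
    if hr < MIN_CROP_SIZE or hc < MIN_CROP_SIZE:
        raise ConfigurationError(
            f"preliminary crop {hr}x{hc} is smaller than "
            f"{MIN_CROP_SIZE}x{MIN_CROP_SIZE}; lower the fraction or use a larger image"
        )
    r0 = (nr - hr) // 2
    c0 = (nc - hc) // 2
    region = CropRegion(r0, r0 + hr, c0, c0 + hc)
    return crop_image(image, region), region


def crop_image(image: GrayImage, region: CropRegion) -> GrayImage:
    if region.row_stop > image.shape[0] or region.col_stop > image.shape[1]:
        raise ConfigurationError(f"crop region {region} exceeds image {image.shape}")
    data = image.data[region.row_start : region.row_stop, region.col_start : region.col_stop]
    return GrayImage(data.copy(), image.spacing, source=f"{image.source}[{region}]")


def global_threshold(image: GrayImage) -> float:
    """Histogram-based global threshold (Otsu, 256 bins).

    Returns the level maximizing between-class variance; foreground is
    intensity > level.  Constant images have no separable classes.
    """
    data = image.data
    if float(data.min()) == float(data.max()):
        raise InputError("cannot threshold a constant image")
    return float(threshold_otsu(data, nbins=256))


def remove_small_objects(mask: BinaryMask, min_pixels: int) -> BinaryMask:
    """Delete 8-connected components with *strictly fewer* than ``min_pixels``
    pixels (a 700-pixel component survives a 700-pixel cutoff)."""
    if min_pixels < 1:
        raise ConfigurationError(f"min_pixels must be >= 1, got {min_pixels}")
    labels, n = label(mask.data, connectivity=2, return_num=True)
    if n == 0:
        return BinaryMask(mask.data.copy(), mask.spacing)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep = sizes >= min_pixels
    keep[0] = False
    return BinaryMask(keep[labels], mask.spacing)


def clear_border_objects(mask: BinaryMask) -> BinaryMask:
    """Delete every 8-connected component touching any image edge."""
    return BinaryMask(_sk_clear_border(label(mask.data, connectivity=2)) > 0, mask.spacing)


def detect_sov(image: GrayImage, config: SovConfig | None = None) -> CropRegion:
    """Locate the SOV and return its padded bounding box in original coordinates.

    Stages: preliminary central crop -> Otsu binarization -> remove objects
    < ``min_object_pixels`` -> remove border-touching objects -> of the
    survivors keep the component whose centroid is nearest the window center
    (ties: largest component); return its bounding box padded by
    ``bbox_pad_fraction`` and clipped to the image.
    """
    config = config or SovConfig()
    window, region = preliminary_crop(image, config.central_fraction)
    level = global_threshold(window)
    binary = BinaryMask(window.data > level, window.spacing)
    binary = remove_small_objects(binary, config.min_object_pixels)
    binary = clear_border_objects(binary)

    labels = label(binary.data, connectivity=2)
    props = regionprops(labels)
    if not props:
        raise DetectionError(
            "no candidate object survived SOV detection; "
            "crop the valve region manually and rerun"
        )
    wc = ((binary.data.shape[0] - 1) / 2.0, (binary.data.shape[1] - 1) / 2.0)
    best = min(
        props,
        key=lambda p: (
            round((p.centroid[0] - wc[0]) ** 2 + (p.centroid[1] - wc[1]) ** 2, 9),
            -p.area,
        ),
    )
    r0, c0, r1, c1 = best.bbox  # half-open
    pad_r = int(round((r1 - r0) * config.bbox_pad_fraction))
    pad_c = int(round((c1 - c0) * config.bbox_pad_fraction))
    nr, nc = image.shape
    return CropRegion(
        max(region.row_start + r0 - pad_r, 0),
        min(region.row_start + r1 + pad_r, nr),
        max(region.col_start + c0 - pad_c, 0),
        min(region.col_start + c1 + pad_c, nc),
    )
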