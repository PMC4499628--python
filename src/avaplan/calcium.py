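"""Contrast-adaptive calcium detection.

On contrast-enhanced CT the conventional fixed 130 HU calcium threshold is
useless — the opacified blood pool itself exceeds it — so the threshold must
be derived per image from the intensity histogram.  The cropped valve image
is first min-max normalized to 8 bits (the algorithm is defined on bin
indices, not calibrated HU), then five steps are applied to its 256-bin
histogram:

1. ``im_max``: index of the highest occupied bin (maximum intensity present).
2. ``max_h``: the largest bin count (the histogram mode height, MaxH).
3. ``t_calc_est``: scanning *down* from ``im_max``, the first bin whose count
   reaches MaxH/3 — the upper edge of the bright blood-pool peak, the initial
   threshold estimate.
4. ``dr``: the dynamic-range index — accumulating counts from bin 0, the bin
   at which the running total reaches half the pixels.
5. ``t_calc``: the estimate pushed toward ``im_max`` by a branch-dependent
   fraction: 0.5 for bright images (``dr > 0.7 * im_max``), 0.2 otherwise::

       t_calc = t_calc_est + (im_max - t_calc_est) * factor

Calcified pixels are those strictly brighter than ``t_calc``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io import BinaryMask, GrayImage

__all__ = [
    "CalciumConfig",
    "HistogramSummary",
    "normalize_8bit",
    "compute_histogram",
    "estimate_calcium_threshold",
    "detect_calcium",
    "filter_calcium_mask",
]

N_BINS = 256


@dataclass
class CalciumConfig:
    """Tunable constants of the five-step threshold rule."""

    maxh_divisor: float = 3.0    # step 3 stops at max_h / maxh_divisor
    dr_factor: float = 0.7       # bright-image branch rule: dr > dr_factor * im_max
    bright_factor: float = 0.5   # interpolation factor, bright branch
    dark_factor: float = 0.2     # interpolation factor, dark branch
    strict_compare: bool = True  # calcium = intensity > t_calc (False: >=)
    min_blob_mm2: float = 1.0    # smallest connected area treated as a deposit


@dataclass
class HistogramSummary:
    """All intermediate quantities of the threshold computation.

    ``branch`` records which interpolation fired: "bright" (dr above
    0.7*im_max) or "dark".  Invariant: t_calc_est <= t_calc <= im_max.
    """

    counts: np.ndarray
    im_max: int
    max_h: int
    t_calc_est: int
    dr: int
    t_calc: float
    branch: str


def normalize_8bit(image: GrayImage) -> GrayImage:
    """Linear min-max rescale to integer levels 0..255."""
    data = image.data
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise InputError("cannot normalize a constant image")
    out = np.rint((data - lo) * (255.0 / (hi - lo)))
    return GrayImage(out, image.spacing, source=f"{image.source}|8bit")


def compute_histogram(image: GrayImage) -> np.ndarray:
    """256-bin histogram of an 8-bit-normalized image (bin = intensity)."""
    vals = np.rint(image.data).astype(int)
    if vals.min() < 0 or vals.max() > 255:
        raise InputError("histogram expects intensities in 0..255; normalize first")
    return np.bincount(vals.ravel(), minlength=N_BINS)


def estimate_calcium_threshold(
    counts: np.ndarray, config: CalciumConfig | None = None
) -> HistogramSummary:
    """Run the five-step threshold derivation on a 256-bin histogram."""
    config = config or CalciumConfig()
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size == 0 or counts.size > N_BINS:
        raise InputError(f"expected a histogram of <= {N_BINS} bins")
    if counts.sum() == 0:
        raise InputError("histogram is empty (all-zero counts)")

    occupied = np.flatnonzero(counts)
    im_max = int(occupied[-1])
    max_h = int(counts.max())

    # step 3: first bin at or below im_max whose count reaches max_h / divisor
    stop = max_h / config.maxh_divisor
    t_calc_est = im_max
    for idx in range(im_max, -1, -1):
        if counts[idx] >= stop:
            t_calc_est = idx
            break

    # step 4: dynamic range = bin where the cumulative count reaches half
    half = counts.sum() / 2.0
    dr = int(np.searchsorted(np.cumsum(counts), half))

    # step 5: branch on image brightness
    if dr > config.dr_factor * im_max:
        factor, branch = config.bright_factor, "bright"
    else:
        factor, branch = config.dark_factor, "dark"
    t_calc = t_calc_est + (im_max - t_calc_est) * factor

    return HistogramSummary(
        counts=counts,
        im_max=im_max,
        max_h=max_h,
        t_calc_est=t_calc_est,
        dr=dr,
        t_calc=float(t_calc),
        branch=branch,
    )


def detect_calcium(
    image: GrayImage,
    summary: HistogramSummary,
    config: CalciumConfig | None = None,
) -> BinaryMask:
    """Mask of calcified pixels: intensity strictly above ``t_calc``.

    ``image`` must be the 8-bit-normalized cropped valve image the summary
    was computed from.
    """
    config = config or CalciumConfig()
    if config.strict_compare:
        sel = image.data > summary.t_calc
    else:
        sel = image.data >= summary.t_calc
    return BinaryMask(sel, image.spacing)


def filter_calcium_mask(mask: BinaryMask, min_blob_mm2: float = 1.0) -> BinaryMask:
    """Keep only connected calcium components of real-deposit size.

    Thresholding always flags the extreme upper tail of the blood-pool noise;
    those are isolated pixels, whereas genuine calcific deposits are connected
    areas.  As in conventional calcium scoring, components below
    ``min_blob_mm2`` of physical area are discarded.
    """
    if min_blob_mm2 <= 0:
        return mask
    from skimage.measure import label

    labels, n = label(mask.data, connectivity=2, return_num=True)
    if n == 0:
        return mask
    pixel_area = mask.spacing[0] * mask.spacing[1]
    sizes = np.bincount(labels.ravel(), minlength=n + 1) * pixel_area
    keep = sizes >= min_blob_mm2
    keep[0] = False
    return BinaryMask(keep[labels], mask.spacing)
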