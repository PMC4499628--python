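"""End-to-end semiautomatic aortic-valve-area planimetry.

Chain (all on the cropped Sinus-of-Valsalva image): detect + crop SOV,
min-max normalize to 8 bits, derive the adaptive calcium threshold and mask,
binarize adaptively, build the initial contour from the three user seeds,
mask the binary image with the seed circle (first masking), fill interior
holes, run the GVF snake, mask again with the converged contour (double
masking), keep the right component (size/distance rules), exclude calcium,
and convert the pixel count to cm².  The manual-planimetry comparator (trace
a polygon, count pixels inside) shares the same rasterizer so the two modes
measure area identically.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops

from . import calcium as calcium_mod
from . import snake as snake_mod
from . import sov as sov_mod
from .config import PipelineConfig
from .errors import ConfigurationError, SegmentationError
from .io import BinaryMask, GrayImage
from .raster import is_simple_polygon, rasterize_polygon
from .snake import Contour
from .sov import CropRegion

__all__ = [
    "AVAResult",
    "adaptive_binarize",
    "fill_holes",
    "mask_with_contour",
    "select_ava_object",
    "measure_area",
    "segment_ava",
    "manual_planimetry",
]


@dataclass
class AVAResult:
    """Everything the semiautomatic measurement produced.

    ``ava_mask`` is the final orifice mask *after* calcium exclusion, so it is
    always disjoint from ``calcium_excluded_mask`` and
    ``area_cm2 == ava_mask.count * spacing_row * spacing_col / 100`` exactly.
    Masks and the contour live in cropped-image coordinates; ``crop_region``
    maps them back to the original image.
    """

    ava_mask: BinaryMask
    calcium_excluded_mask: BinaryMask
    contour: Contour
    area_cm2: float
    crop_region: CropRegion
    summary: calcium_mod.HistogramSummary
    stage_timings: dict[str, float] = field(default_factory=dict)


def adaptive_binarize(image: GrayImage, window: int = 31, offset: float = 10.0) -> BinaryMask:
    """Local-mean adaptive threshold: foreground iff intensity > mean(window) + offset.

    The bright contrast-filled lumen/orifice becomes foreground, the darker
    leaflets background.  A small positive offset keeps homogeneous regions
    from speckling under noise; on a constant image with offset 0 the strict
    comparison yields all background.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigurationError(f"window must be odd and >= 3, got {window}")
    if window > min(image.shape):
        raise ConfigurationError(
            f"window {window} larger than image {image.shape}"
        )
    local_mean = ndimage.uniform_filter(image.data, size=window, mode="reflect")
    return BinaryMask(image.data > local_mean + offset, image.spacing)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background regions not connected to the image border."""
    return BinaryMask(ndimage.binary_fill_holes(mask.data), mask.spacing)


def mask_with_contour(
    mask: BinaryMask, contour: Contour, include_edge: bool = False
) -> BinaryMask:
    """Intersect a binary mask with the rasterized contour interior.

    With ``include_edge`` the one-pixel ring under the contour line is kept
    as well — the converged contour covers the edge pixels of the opening in
    addition to the interior, and those edge pixels belong to the orifice.
    """
    interior = rasterize_polygon(contour.vertices, mask.data.shape)
    if not interior.any() and contour.enclosed_area() >= 1.0:
        # a valid contour entirely outside the raster is a degenerate request
        raise SegmentationError("contour interior does not overlap the image raster")
    if include_edge:
        interior = ndimage.binary_dilation(
            interior, structure=ndimage.generate_binary_structure(2, 2)
        )
    return BinaryMask(mask.data & interior, mask.spacing)


def select_ava_object(
    mask: BinaryMask,
    min_area_mm2: float = 40.0,
    center: tuple[float, float] | None = None,
) -> BinaryMask:
    """Keep the one component that is the valve orifice.

    Components with physical area strictly below ``min_area_mm2`` are deleted;
    of the survivors, only the component whose centroid is nearest ``center``
    (default: the image center) is kept — equivalently, the more distant
    objects are removed.  No survivor is a segmentation failure.
    """
    labels = label(mask.data, connectivity=2)
    props = regionprops(labels)
    if not props:
        raise SegmentationError("mask contains no components")
    pixel_area = mask.spacing[0] * mask.spacing[1]
    survivors = [p for p in props if p.area * pixel_area >= min_area_mm2]
    if not survivors:
        raise SegmentationError(
            f"no candidate object reaches {min_area_mm2:g} mm²; "
            "segmentation failed (extreme stenosis or bad seeds?)"
        )
    if center is None:
        center = ((mask.data.shape[0] - 1) / 2.0, (mask.data.shape[1] - 1) / 2.0)
    best = min(
        survivors,
        key=lambda p: (
            round((p.centroid[0] - center[0]) ** 2 + (p.centroid[1] - center[1]) ** 2, 9),
            -p.area,
        ),
    )
    return BinaryMask(labels == best.label, mask.spacing)


def measure_area(
    ava_mask: BinaryMask,
    calcium_mask: BinaryMask | None,
    image: GrayImage,
) -> tuple[float, BinaryMask]:
    """Pixel-count area in cm² with calcified pixels excluded.

    Returns (area_cm2, excluded_mask) where excluded = ava ∩ calcium and the
    area counts ava \\ excluded pixels times the per-pixel area
    (spacing_row x spacing_col mm², anisotropy supported) / 100.
    """
    if calcium_mask is None:
        excluded = np.zeros_like(ava_mask.data)
    else:
        if calcium_mask.data.shape != ava_mask.data.shape:
            raise ConfigurationError("ava and calcium masks must share a shape")
        excluded = ava_mask.data & calcium_mask.data
    kept = ava_mask.data & ~excluded
    area_cm2 = float(kept.sum()) * image.pixel_area_mm2 / 100.0
    return area_cm2, BinaryMask(excluded, ava_mask.spacing)


def manual_planimetry(polygon: np.ndarray, image: GrayImage) -> float:
    """Manual comparator: area of a hand-traced orifice polygon in cm².

    Rasterized with the same pixel-center rule as the semiautomatic path, so
    the two modes share one measurement model.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ConfigurationError("polygon must be an (N>=3, 2) array of (row, col)")
    if not is_simple_polygon(poly):
        raise ConfigurationError("traced polygon is self-intersecting; re-trace")
    mask = rasterize_polygon(poly, image.shape)
    return float(mask.sum()) * image.pixel_area_mm2 / 100.0


def segment_ava(
    image: GrayImage,
    seeds: np.ndarray,
    config: PipelineConfig | None = None,
) -> AVAResult:
    """Full semiautomatic AVA measurement from image + three seed points.

    ``seeds`` are (row, col) points in *original-image* coordinates, placed
    where the cusps join; they are mapped into the cropped frame internally.
    Per-stage wall-clock timings are recorded in the result.
    """
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0

        return _T()

    seeds = np.asarray(seeds, dtype=float)
    if seeds.shape != (3, 2):
        raise ConfigurationError("exactly three (row, col) seed points are required")

    with timed("detect_sov"):
        region = sov_mod.detect_sov(image, cfg.sov)
        cropped = sov_mod.crop_image(image, region)
    local_seeds = seeds - np.array([region.row_start, region.col_start], dtype=float)

    with timed("normalize"):
        norm = calcium_mod.normalize_8bit(cropped)

    with timed("calcium"):
        hist = calcium_mod.compute_histogram(norm)
        summary = calcium_mod.estimate_calcium_threshold(hist, cfg.calcium)
        calcium_mask = calcium_mod.detect_calcium(norm, summary, cfg.calcium)
        calcium_mask = calcium_mod.filter_calcium_mask(
            calcium_mask, cfg.calcium.min_blob_mm2
        )

    with timed("binarize"):
        binary = adaptive_binarize(norm, cfg.adaptive_window, cfg.adaptive_offset)
        if cfg.calcium_exclusion == "pre":
            binary = BinaryMask(binary.data & ~calcium_mask.data, binary.spacing)

    with timed("snake"):
        init = snake_mod.init_contour(local_seeds, cfg.snake.n_vertices)
        first_masked = mask_with_contour(binary, init, cfg.contour_covers_edge)
        if cfg.fill_holes:
            first_masked = fill_holes(first_masked)
        edges = snake_mod.edge_map(first_masked.data, cfg.snake.edge_sigma)
        gvf = snake_mod.compute_gvf(edges, cfg.snake)
        contour = snake_mod.evolve_snake(init, gvf, cfg.snake)
        double_masked = mask_with_contour(first_masked, contour, cfg.contour_covers_edge)

    with timed("select"):
        n_objects = int(label(double_masked.data, connectivity=2).max())
        if n_objects == 0:
            raise SegmentationError("double-masked image is empty; segmentation failed")
        if n_objects > 1:
            # size/distance filtering applies only when more than one object remains
            selected = select_ava_object(double_masked, cfg.min_area_mm2)
        else:
            selected = double_masked

    with timed("measure"):
        if cfg.calcium_exclusion == "post":
            area_cm2, excluded = measure_area(selected, calcium_mask, cropped)
        else:
            area_cm2, excluded = measure_area(selected, None, cropped)
        final_mask = BinaryMask(selected.data & ~excluded.data, selected.spacing)

    return AVAResult(
        ava_mask=final_mask,
        calcium_excluded_mask=excluded,
        contour=contour,
        area_cm2=area_cm2,
        crop_region=region,
        summary=summary,
        stage_timings=timings,
    )
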