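"""Synthetic valve-plane phantoms with known orifice area.

The phantom emulates a contrast-enhanced aortic-root cross-section at maximal
systolic opening: a bright circular Sinus-of-Valsalva (SOV) lumen filled with
contrast agent, darker leaflet tissue forming a plate around the open orifice
and past the commissures, the bright triradiate orifice itself, optional very
bright calcific deposits, darker surrounding tissue, and additive Gaussian
noise.  Because the orifice
polygon is rasterized with the same pixel-center fill rule used by every
measurement stage (:mod:`avaplan.raster`), the ground-truth area is exact by
construction: ``orifice_area_cm2 = pixel count x pixel area / 100``.

The three commissure points (where adjacent cusps join, on the outer side of
the leaflet band) are returned as the natural seed points for the snake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .io import BinaryMask, GrayImage
from .raster import polygon_area, rasterize_polygon

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "triradiate_orifice",
    "generate_phantom",
    "sweep_specs",
]


def triradiate_orifice(
    center: tuple[float, float],
    area_mm2: float,
    spacing: tuple[float, float],
    waist_ratio: float = 0.45,
    rotation_deg: float = 90.0,
) -> np.ndarray:
    """Vertices (pixel coords) of a three-armed star orifice of given area.

    The open aortic orifice is roughly triradiate: three arms reaching toward
    the commissures, with concave waists between them where the leaflet free
    edges bow inward.  Modeled as a 6-vertex star alternating tip radius ``a``
    and waist radius ``waist_ratio * a``; ``a`` is solved so the *polygon*
    (shoelace) area equals ``area_mm2``.  Degenerate request ``area_mm2 = 0``
    returns a zero-radius polygon.
    """
    if area_mm2 < 0:
        raise ConfigurationError("orifice area must be >= 0")
    sr, sc = spacing
    # shoelace area of the alternating star with unit tip radius, in mm²
    unit = 3.0 * waist_ratio * math.sin(math.pi / 3.0)
    a_mm = math.sqrt(area_mm2 / unit) if area_mm2 > 0 else 0.0
    angles = np.deg2rad(rotation_deg) + np.arange(6) * (math.pi / 3.0)
    radii_mm = np.where(np.arange(6) % 2 == 0, a_mm, waist_ratio * a_mm)
    rows = center[0] - radii_mm * np.sin(angles) / sr
    cols = center[1] + radii_mm * np.cos(angles) / sc
    return np.stack([rows, cols], axis=1)


@dataclass
class PhantomSpec:
    """Geometry, intensity, and noise specification of one phantom.

    Intensities must be strictly ordered background < leaflet < lumen <
    calcium (tissue is darkest, contrast-filled lumen bright, calcification
    brightest).  The orifice polygon must sit strictly inside the SOV disc,
    and the disc strictly inside the image with a margin of at least 10% of
    the image size.  Identical spec + seed yields a bit-identical image.
    """

    image_size: tuple[int, int] = (224, 224)
    pixel_spacing: tuple[float, float] = (0.5, 0.5)
    sov_radius: float = 14.0            # mm
    sov_center: tuple[float, float] | None = None  # pixel coords; None = image center
    orifice_vertices: np.ndarray | None = None     # None = default 40 mm² star
    orifice_area_mm2: float = 40.0      # used only when orifice_vertices is None
    leaflet_thickness: float = 1.5      # mm, orifice free edge -> commissure ring
    plate_margin: float = 2.5           # mm, leaflet tissue beyond the commissures
    intensity_background: float = 30.0
    background_ramp: float = 50.0       # peak-to-peak smooth tissue inhomogeneity
    intensity_leaflet: float = 90.0
    intensity_lumen: float = 180.0
    intensity_calcium: float = 250.0
    calcium_blobs: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    noise_sd: float = 0.0               # grayscale units
    rng_seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.sov_center is not None:
            return (float(self.sov_center[0]), float(self.sov_center[1]))
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)

    def resolved_orifice(self) -> np.ndarray:
        if self.orifice_vertices is not None:
            v = np.asarray(self.orifice_vertices, dtype=float)
            if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
                raise ConfigurationError(
                    "orifice_vertices must be an (N>=3, 2) array of (row, col) points"
                )
            return v
        return triradiate_orifice(
            self.resolved_center(), self.orifice_area_mm2, self.pixel_spacing
        )

    def orifice_radius_mm(self) -> float:
        """Largest radial distance (mm) of an orifice vertex from the valve center."""
        verts = self.resolved_orifice()
        cr, cc = self.resolved_center()
        sr, sc = self.pixel_spacing
        d_r = (verts[:, 0] - cr) * sr
        d_c = (verts[:, 1] - cc) * sc
        return float(np.sqrt(d_r**2 + d_c**2).max()) if verts.size else 0.0

    def validate(self) -> None:
        if not (
            self.intensity_background
            < self.intensity_leaflet
            < self.intensity_lumen
            < self.intensity_calcium
        ):
            raise ConfigurationError(
                "intensities must satisfy background < leaflet < lumen < calcium"
            )
        if self.background_ramp < 0 or (
            self.intensity_background + self.background_ramp >= self.intensity_leaflet
        ):
            raise ConfigurationError(
                "background_ramp must be >= 0 and keep background below the leaflet level"
            )
        nr, nc = self.image_size
        if nr < 32 or nc < 32:
            raise ConfigurationError("image_size must be at least 32x32")
        sr, sc = self.pixel_spacing
        if sr <= 0 or sc <= 0:
            raise ConfigurationError("pixel_spacing must be positive")
        if self.sov_radius <= 0:
            raise ConfigurationError("sov_radius must be positive")
        cr, cc = self.resolved_center()
        rad_r, rad_c = self.sov_radius / sr, self.sov_radius / sc
        margin_r, margin_c = 0.1 * nr, 0.1 * nc
        if (
            cr - rad_r < margin_r
            or cr + rad_r > nr - 1 - margin_r
            or cc - rad_c < margin_c
            or cc + rad_c > nc - 1 - margin_c
        ):
            raise ConfigurationError(
                "SOV disc must lie strictly inside the image with a margin "
                ">= 10% of the image size"
            )
        if self.leaflet_thickness <= 0 or self.plate_margin < 0:
            raise ConfigurationError("leaflet_thickness must be > 0, plate_margin >= 0")
        rmax = self.orifice_radius_mm()
        if rmax + self.leaflet_thickness + self.plate_margin >= self.sov_radius:
            raise ConfigurationError(
                f"orifice (max radius {rmax:.1f} mm) + leaflet plate "
                f"({self.leaflet_thickness + self.plate_margin:.1f} mm) must lie "
                f"strictly inside the SOV disc (radius {self.sov_radius:.1f} mm)"
            )
        for (br, bc), rad in self.calcium_blobs:
            if rad <= 0:
                raise ConfigurationError("calcium blob radius must be positive")
            d = math.hypot((br - cr) * sr, (bc - cc) * sc)
            if d + rad >= self.sov_radius:
                raise ConfigurationError("calcium blob must lie inside the SOV disc")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    orifice_mask: BinaryMask            # rasterized orifice minus calcium overlap
    orifice_area_cm2: float             # == orifice_mask.count * pixel area / 100
    calcium_mask: BinaryMask
    commissure_points: np.ndarray       # (3, 2) cusp-junction seed points
    sov_mask: BinaryMask                # full SOV disc (for detection tests)


def _disc_mask(shape, center, radius_mm, spacing) -> np.ndarray:
    rr = (np.arange(shape[0])[:, None] - center[0]) * spacing[0]
    cc = (np.arange(shape[1])[None, :] - center[1]) * spacing[1]
    return rr**2 + cc**2 <= radius_mm**2


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, PhantomTruth]:
    """Render the phantom image and its ground truth.

    Drawing order: background, bright contrast-filled SOV lumen disc, the
    dark leaflet plate — a concentric disc reaching ``leaflet_thickness +
    plate_margin`` beyond the orifice tips, modelling the closed leaflet
    tissue between the free edges and past the commissures — the bright open
    orifice cut into the plate, calcium discs on top, then i.i.d. Gaussian
    noise clipped to [0, 4095] (12-bit CT-like range).  Truth masks use the
    same rasterizer as the measurement stages, so the reported area is exact
    by construction.
    """
    spec.validate()
    shape = tuple(spec.image_size)
    spacing = spec.pixel_spacing
    center = spec.resolved_center()
    verts = spec.resolved_orifice()

    sov = _disc_mask(shape, center, spec.sov_radius, spacing)
    orifice = rasterize_polygon(verts, shape)

    plate_radius = spec.orifice_radius_mm() + spec.leaflet_thickness + spec.plate_margin
    ring = _disc_mask(shape, center, plate_radius, spacing) & ~orifice

    calcium = np.zeros(shape, dtype=bool)
    for (br, bc), rad in spec.calcium_blobs:
        calcium |= _disc_mask(shape, (br, bc), rad, spacing)

    img = np.full(shape, spec.intensity_background, dtype=float)
    if spec.background_ramp > 0:
        # smooth tissue inhomogeneity: a linear ramp outside the root, so the
        # surrounding tissue spreads flat over many histogram bins instead of
        # forming one artificial narrow mode
        rr = np.arange(shape[0], dtype=float)[:, None] / max(shape[0] - 1, 1)
        img += spec.background_ramp * rr * np.ones((1, shape[1]))
    img[sov] = spec.intensity_lumen
    img[ring & sov] = spec.intensity_leaflet
    img[orifice] = spec.intensity_lumen
    img[calcium] = spec.intensity_calcium

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        img = np.clip(img, 0.0, 4095.0)

    truth_orifice = orifice & ~calcium
    pixel_area = spacing[0] * spacing[1]
    truth = PhantomTruth(
        orifice_mask=BinaryMask(truth_orifice, spacing),
        orifice_area_cm2=float(truth_orifice.sum()) * pixel_area / 100.0,
        calcium_mask=BinaryMask(calcium, spacing),
        commissure_points=_commissures(spec, verts, center),
        sov_mask=BinaryMask(sov, spacing),
    )
    gray = GrayImage(
        img, spacing, source=f"phantom(seed={spec.rng_seed}, area={polygon_area(verts):.1f}px²)"
    )
    return gray, truth


def sweep_specs(seed: int = 0) -> list[PhantomSpec]:
    """A 20-phantom validation sweep spanning the clinically relevant range.

    Orifice areas 0.3–2.0 cm² (severe stenosis to normal), pixel spacings
    0.4–0.7 mm (typical cardiac CT in-plane resolution), noise SD 0–5 gray
    levels, and 0–4 calcific deposits.  The SOV radius grows with the orifice
    so large valves stay anatomically plausible (orifice + leaflet band
    strictly inside the root).  ``seed`` only offsets the per-phantom noise
    seeds; the geometry grid is fixed.
    """
    areas_cm2 = [0.3, 0.55, 0.85, 1.2, 1.6, 2.0]
    spacings = [0.4, 0.55, 0.7]
    noise_levels = [0.0, 2.5, 5.0]
    specs: list[PhantomSpec] = []
    for i in range(20):
        area_mm2 = areas_cm2[i % len(areas_cm2)] * 100.0
        sp = spacings[i % len(spacings)]
        noise = noise_levels[i % len(noise_levels)]
        n_blobs = i % 5
        unit = 3.0 * 0.45 * math.sin(math.pi / 3.0)
        a_mm = math.sqrt(area_mm2 / unit)
        # leaflet plate ends at a + 4 mm; keep a sinus annulus >= 5 mm wide
        sov_radius = max(14.0, a_mm + 9.0)
        spec = PhantomSpec(
            image_size=(256, 256),
            pixel_spacing=(sp, sp),
            sov_radius=sov_radius,
            orifice_area_mm2=area_mm2,
            noise_sd=noise,
            rng_seed=seed + 1000 + i,
        )
        center = spec.resolved_center()
        blob_r_mm = (a_mm + 1.5 + sov_radius) / 2.0  # between leaflet band and wall
        blobs = []
        for k in range(n_blobs):
            ang = 2.0 * math.pi * (k + 0.35 * i) / max(n_blobs, 1)
            br = center[0] - blob_r_mm * math.sin(ang) / sp
            bc = center[1] + blob_r_mm * math.cos(ang) / sp
            blobs.append(((br, bc), 1.2))
        spec.calcium_blobs = blobs
        spec.validate()
        specs.append(spec)
    return specs


def _commissures(spec: PhantomSpec, verts: np.ndarray, center) -> np.ndarray:
    """Cusp-junction points: orifice arm tips pushed to the outer edge of the
    leaflet band (anatomically, commissures sit on the wall side)."""
    sr, sc = spec.pixel_spacing
    tips = verts[0::2][:3] if verts.shape[0] >= 6 else verts[:3]
    out = []
    for tr, tc in tips:
        d_mm = np.array([(tr - center[0]) * sr, (tc - center[1]) * sc])
        norm = np.linalg.norm(d_mm)
        if norm == 0:
            out.append((tr, tc))
            continue
        shift = d_mm / norm * spec.leaflet_thickness
        out.append((tr + shift[0] / sr, tc + shift[1] / sc))
    return np.asarray(out, dtype=float)
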