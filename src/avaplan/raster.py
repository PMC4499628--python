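"""Polygon rasterization shared by every stage that turns a contour into pixels.

Area measurement in this package is "count foreground pixels, multiply by the
pixel size", so the fill rule must be a single fixed convention used both by
the phantom ground truth and by every masking stage, or areas stop being
comparable.  The rule: a pixel belongs to the polygon iff its *center* lies
inside under the even-odd rule; boundary ties are broken by the half-open
crossing test below (a pixel center exactly on an edge is counted for the
edge's upper/left side only), so abutting polygons never double-count a pixel.

Coordinates are (row, col), 0-based, pixel centers at integer coordinates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rasterize_polygon", "polygon_area", "is_simple_polygon"]


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon, in squared vertex units."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        return 0.0
    r, c = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def is_simple_polygon(vertices: np.ndarray) -> bool:
    """True if the closed polygon does not self-intersect (shapely check)."""
    from shapely.geometry import Polygon

    v = np.asarray(vertices, dtype=float)
    if v.shape[0] < 3:
        return False
    return Polygon(v).is_valid


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon into a boolean mask of the given shape.

    Parameters
    ----------
    vertices
        (N, 2) array of subpixel (row, col) polygon vertices; the polygon is
        implicitly closed (last vertex connects to the first).
    shape
        (rows, cols) of the output raster.

    Returns
    -------
    Boolean array; True where the pixel center is inside the polygon
    (even-odd rule, half-open tie convention).

    Notes
    -----
    Implemented as a vectorized crossing-number test per edge: edge
    (r0,c0)-(r1,c1) crosses the horizontal ray from pixel (r,c) iff
    ``(r0 <= r) != (r1 <= r)`` and the edge's column at row r is strictly
    greater than c.  The asymmetric ``<=`` pair makes the fill half-open so
    vertices and horizontal edges are never counted twice.  Degenerate
    (zero-area) polygons rasterize to an empty mask.
    """
    v = np.asarray(vertices, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        return mask

    rmin = max(int(np.floor(v[:, 0].min())), 0)
    rmax = min(int(np.ceil(v[:, 0].max())), shape[0] - 1)
    cmin = max(int(np.floor(v[:, 1].min())), 0)
    cmax = min(int(np.ceil(v[:, 1].max())), shape[1] - 1)
    if rmin > rmax or cmin > cmax:
        return mask

    rows = np.arange(rmin, rmax + 1, dtype=float)[:, None]   # (R, 1)
    cols = np.arange(cmin, cmax + 1, dtype=float)[None, :]   # (1, C)
    inside = np.zeros((rows.size, cols.shape[1]), dtype=bool)

    r0, c0 = v[:, 0], v[:, 1]
    r1, c1 = np.roll(r0, -1), np.roll(c0, -1)
    for e in range(v.shape[0]):
        a, b = r0[e], r1[e]
        if a == b:  # horizontal edge never crosses the half-open ray
            continue
        straddles = (a <= rows) != (b <= rows)               # (R, 1)
        # column where the edge intersects each pixel row
        c_at = c0[e] + (rows - a) * (c1[e] - c0[e]) / (b - a)  # (R, 1)
        inside ^= straddles & (cols < c_at)

    mask[rmin:rmax + 1, cmin:cmax + 1] = inside
    return mask
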