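"""Independent brute-force oracles the tests compare the package against.

Each oracle deliberately takes the dumbest correct route — per-pixel loops,
breadth-first flood fill, exhaustive threshold scans, dense Jacobi fixed
points — so it shares no code path with the implementation it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components via BFS flood fill; returns pixel-coordinate sets."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    nr, nc = mask.shape
    for r in range(nr):
        for c in range(nc):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    pr, pc = q.popleft()
                    comp.add((pr, pc))
                    for dr, dc in NEIGHBORS_8:
                        qr, qc = pr + dr, pc + dc
                        if 0 <= qr < nr and 0 <= qc < nc and mask[qr, qc] and not seen[qr, qc]:
                            seen[qr, qc] = True
                            q.append((qr, qc))
                comps.append(comp)
    return comps


def components_to_mask(comps, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for comp in comps:
        for r, c in comp:
            out[r, c] = True
    return out


def remove_small_oracle(mask: np.ndarray, min_pixels: int) -> np.ndarray:
    comps = [c for c in flood_fill_components(mask) if len(c) >= min_pixels]
    return components_to_mask(comps, mask.shape)


def clear_border_oracle(mask: np.ndarray) -> np.ndarray:
    nr, nc = mask.shape
    comps = [
        c
        for c in flood_fill_components(mask)
        if not any(r in (0, nr - 1) or col in (0, nc - 1) for r, col in c)
    ]
    return components_to_mask(comps, mask.shape)


def select_object_oracle(
    mask: np.ndarray, min_area_mm2: float, pixel_area: float, center
) -> np.ndarray | None:
    """Filter-then-nearest-centroid selection; None when nothing survives."""
    comps = [
        c for c in flood_fill_components(mask) if len(c) * pixel_area >= min_area_mm2
    ]
    if not comps:
        return None

    def dist2(comp):
        rr = np.array([p[0] for p in comp], dtype=float)
        cc = np.array([p[1] for p in comp], dtype=float)
        return round((rr.mean() - center[0]) ** 2 + (cc.mean() - center[1]) ** 2, 9)

    best = min(comps, key=lambda c: (dist2(c), -len(c)))
    return components_to_mask([best], mask.shape)


def otsu_between_class_variance(data: np.ndarray):
    """Between-class variance profile over 256 candidate split points.

    Returns (bin_centers, variances) where variances[k] is the between-class
    variance of splitting below/above center k (nan where a class is empty).
    """
    lo, hi = float(data.min()), float(data.max())
    edges = np.linspace(lo, hi, 257)
    hist, _ = np.histogram(data.ravel(), bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    variances = np.full(256, np.nan)
    for k in range(1, 256):
        w0 = hist[:k].sum()
        w1 = hist[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        variances[k - 1] = w0 * w1 * (mu0 - mu1) ** 2
    return centers, variances


def otsu_oracle(data: np.ndarray) -> float:
    """Exhaustive between-class-variance maximizer over 256 candidate levels."""
    centers, variances = otsu_between_class_variance(data)
    return float(centers[np.nanargmax(variances)])


def point_in_polygon_count(vertices: np.ndarray, shape) -> int:
    """Pixel-center containment count via matplotlib's independent path test."""
    from matplotlib.path import Path

    poly = Path(np.asarray(vertices, dtype=float))
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return int(poly.contains_points(pts).sum())


def jacobi_gvf(edge: np.ndarray, mu: float, iters: int = 20000, tol: float = 1e-12):
    """Dense Jacobi fixed point of the stationary GVF equations.

    Solves mu * lap(u) - (u - f_r) * (f_r^2 + f_c^2) = 0 directly:
    u = (mu * sum_of_neighbors + b * f_r) / (4 mu + b), with edge-replicated
    boundaries (same Neumann handling as the diffusion solver it checks).
    """
    f = np.asarray(edge, dtype=float)
    fr, fc = np.gradient(f)
    b = fr**2 + fc**2
    u, v = fr.copy(), fc.copy()

    def nb_sum(a):
        p = np.pad(a, 1, mode="edge")
        return p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]

    denom = 4.0 * mu + b
    for _ in range(iters):
        u_new = (mu * nb_sum(u) + b * fr) / denom
        v_new = (mu * nb_sum(v) + b * fc) / denom
        delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
        u, v = u_new, v_new
        if delta < tol:
            break
    return u, v
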