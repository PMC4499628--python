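"""Gradient-vector-flow (GVF) active contour.

The segmentation engine: an edge map is computed from the binarized valve
image (binary edges are far crisper than grayscale ones), diffused into a
gradient vector flow field — which extends the capture range of the edge
force deep into homogeneous regions — and a closed snake initialized from
three user seed points shrinks onto the orifice boundary.

The GVF field (u, v) minimizes

    E = ∬ mu (|∇u|² + |∇v|²) + |∇f|² |(u, v) - ∇f|² dx dy

and is computed by explicit diffusion of the Euler equations

    u_t = mu ∇²u - (u - f_r)(f_r² + f_c²)   (and symmetrically for v),

initialized at ∇f, with the explicit-scheme step bound dt <= 1/(4 mu).
The snake update is the classic semi-implicit scheme: internal tension
(alpha) and rigidity (beta) assembled into a cyclic pentadiagonal — here
circulant — system solved exactly each step, external force sampled from
the GVF field bilinearly at each vertex.

Coordinates are (row, col) with pixel centers at integers; u is the
row-component of the force, v the column-component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.linalg import solve_circulant

from .errors import ConfigurationError, NumericalError, SegmentationError

__all__ = [
    "SnakeConfig",
    "VectorField",
    "Contour",
    "edge_map",
    "compute_gvf",
    "init_contour",
    "evolve_snake",
]


@dataclass
class SnakeConfig:
    """Snake and GVF solver parameters.

    mu : GVF regularization weight (higher = smoother, longer-range field).
    gvf_iters / gvf_tol : diffusion iteration cap and max-update stopping
        tolerance.  gvf_step: explicit step size; None picks 0.9/(4 mu),
        inside the stability bound.
    alpha / beta : contour tension and rigidity weights (px units).
    tau : evolution step size;  max_iters / converge_tol : stop when the
        mean vertex displacement per step drops below converge_tol px.
    n_vertices : contour resolution; resample_every : iterations between
        uniform-arc-length resamplings (prevents vertex bunching while the
        contour shrinks).
    """

    mu: float = 0.2
    gvf_iters: int = 200
    gvf_tol: float = 1e-3
    gvf_step: float | None = None
    alpha: float = 0.1
    beta: float = 0.1
    tau: float = 1.0
    max_iters: int = 500
    converge_tol: float = 0.05
    n_vertices: int = 100
    resample_every: int = 10
    edge_sigma: float = 1.0

    def validate(self) -> None:
        if self.mu < 0 or self.alpha < 0 or self.beta < 0:
            raise ConfigurationError("mu, alpha, beta must be >= 0")
        if self.tau <= 0 or self.gvf_tol <= 0 or self.converge_tol <= 0:
            raise ConfigurationError("tau and tolerances must be > 0")
        if self.n_vertices < 8:
            raise ConfigurationError("n_vertices must be >= 8")


@dataclass
class VectorField:
    """Per-pixel force field over the image grid; u = row, v = col component."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ConfigurationError("u and v must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape  # type: ignore[return-value]

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Bilinear force at subpixel (row, col) points; outside the grid the
        nearest border pixel is used (matches vertex clamping)."""
        coords = points.T
        fu = ndimage.map_coordinates(self.u, coords, order=1, mode="nearest")
        fv = ndimage.map_coordinates(self.v, coords, order=1, mode="nearest")
        return np.stack([fu, fv], axis=1)


class Contour:
    """Closed ordered polyline of subpixel (row, col) vertices."""

    def __init__(self, vertices: np.ndarray, require_simple: bool = True):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 8:
            raise ConfigurationError("a contour needs >= 8 (row, col) vertices")
        if require_simple:
            from .raster import is_simple_polygon

            if not is_simple_polygon(v):
                raise ConfigurationError("contour polygon must be simple (non-self-intersecting)")
        self.vertices = v

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def enclosed_area(self) -> float:
        from .raster import polygon_area

        return polygon_area(self.vertices)

    def resampled(self, n: int | None = None) -> "Contour":
        """Resample to n vertices uniformly spaced in arc length."""
        v = self.vertices
        n = n or len(self)
        closed = np.vstack([v, v[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total == 0:
            return Contour(np.repeat(v[:1], n, axis=0), require_simple=False)
        t = np.linspace(0.0, total, n, endpoint=False)
        rows = np.interp(t, s, closed[:, 0])
        cols = np.interp(t, s, closed[:, 1])
        return Contour(np.stack([rows, cols], axis=1), require_simple=False)


def edge_map(binary: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Edge strength of a binary mask: gradient magnitude of the lightly
    Gaussian-smoothed mask, normalized to [0, 1]."""
    f = ndimage.gaussian_filter(np.asarray(binary, dtype=float), sigma=sigma)
    gr, gc = np.gradient(f)
    mag = np.hypot(gr, gc)
    peak = mag.max()
    if peak > 0:
        mag /= peak
    return mag


def compute_gvf(edge: np.ndarray, config: SnakeConfig | None = None) -> VectorField:
    """Diffuse the edge gradient into a gradient-vector-flow field.

    Iterates the explicit update until the max component change drops below
    ``gvf_tol`` or ``gvf_iters`` is hit.  With mu = 0 the fixed point is the
    raw gradient wherever it is nonzero, and the initialization already sits
    there, so the solver returns immediately.
    """
    config = config or SnakeConfig()
    config.validate()
    f = np.asarray(edge, dtype=float)
    if not np.all(np.isfinite(f)):
        raise NumericalError("edge map contains non-finite values")
    fr, fc = np.gradient(f)
    b = fr**2 + fc**2
    u, v = fr.copy(), fc.copy()
    if config.mu == 0:
        return VectorField(u, v)
    dt = config.gvf_step if config.gvf_step is not None else 0.9 / (4.0 * config.mu)
    for _ in range(config.gvf_iters):
        lap_u = ndimage.laplace(u, mode="nearest")
        lap_v = ndimage.laplace(v, mode="nearest")
        du = dt * (config.mu * lap_u - (u - fr) * b)
        dv = dt * (config.mu * lap_v - (v - fc) * b)
        u += du
        v += dv
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise NumericalError(
                f"GVF diffusion diverged (step size {dt:.3g}); reduce gvf_step"
            )
        if max(np.abs(du).max(), np.abs(dv).max()) < config.gvf_tol:
            break
    return VectorField(u, v)


def init_contour(seeds: np.ndarray, n_vertices: int = 100) -> Contour:
    """Initial contour: the circle through the three seed points.

    The user drops one seed at each commissure (where adjacent cusps join);
    the circumscribed circle through them encloses the orifice and is sampled
    at ``n_vertices`` equally spaced points, counter-clockwise.
    """
    pts = np.asarray(seeds, dtype=float)
    if pts.shape != (3, 2):
        raise ConfigurationError("exactly three (row, col) seed points are required")
    (r1, c1), (r2, c2), (r3, c3) = pts
    # circumcenter from perpendicular-bisector linear system
    a = np.array([[r2 - r1, c2 - c1], [r3 - r1, c3 - c1]], dtype=float)
    rhs = 0.5 * np.array(
        [r2**2 - r1**2 + c2**2 - c1**2, r3**2 - r1**2 + c3**2 - c1**2]
    )
    det = np.linalg.det(a)
    scale = max(np.abs(a).max(), 1e-12)
    if abs(det) < 1e-9 * scale**2:
        raise ConfigurationError(
            "seed points are collinear or coincident; re-select three distinct "
            "non-collinear commissure points"
        )
    center = np.linalg.solve(a, rhs)
    radius = float(np.linalg.norm(pts[0] - center))
    theta = np.linspace(0.0, 2.0 * np.pi, int(n_vertices), endpoint=False)
    # counter-clockwise in display axes (x = col right, y = row down)
    rows = center[0] - radius * np.sin(theta)
    cols = center[1] + radius * np.cos(theta)
    return Contour(np.stack([rows, cols], axis=1), require_simple=False)


def _internal_matrix_column(n: int, alpha: float, beta: float) -> np.ndarray:
    """First column of the circulant internal-energy matrix A = -alpha D2 + beta D4."""
    col = np.zeros(n)
    col[0] = 2.0 * alpha + 6.0 * beta
    col[1] = col[-1] = -alpha - 4.0 * beta
    col[2] = col[-2] = beta
    return col


def evolve_snake(
    contour: Contour,
    field: VectorField,
    config: SnakeConfig | None = None,
) -> Contour:
    """Evolve the contour under internal elasticity and the GVF force.

    Semi-implicit update per iteration: (I + tau A) x_new = x_old + tau F,
    with A the cyclic pentadiagonal internal-energy matrix (circulant for a
    uniformly indexed closed contour, solved exactly via FFT) and F the GVF
    force sampled at each vertex.  Vertices are clamped to the image and
    resampled to uniform arc length every ``resample_every`` iterations.
    Stops when the mean vertex displacement per step falls below
    ``converge_tol`` or after ``max_iters``.
    """
    config = config or SnakeConfig()
    config.validate()
    x = contour.vertices.copy()
    n = x.shape[0]
    nr, nc = field.shape
    col = _internal_matrix_column(n, config.alpha, config.beta)
    system_col = config.tau * col
    system_col[0] += 1.0

    for it in range(config.max_iters):
        force = field.sample(x)
        rhs = x + config.tau * force
        x_new = np.stack(
            [
                solve_circulant(system_col, rhs[:, 0]),
                solve_circulant(system_col, rhs[:, 1]),
            ],
            axis=1,
        )
        x_new[:, 0] = np.clip(x_new[:, 0], 0.0, nr - 1.0)
        x_new[:, 1] = np.clip(x_new[:, 1], 0.0, nc - 1.0)
        disp = float(np.linalg.norm(x_new - x, axis=1).mean())
        x = x_new
        if config.resample_every and (it + 1) % config.resample_every == 0:
            x = Contour(x, require_simple=False).resampled(n).vertices
        if disp < config.converge_tol:
            break

    result = Contour(x, require_simple=False)
    if result.enclosed_area() < 1.0:
        raise SegmentationError(
            "snake collapsed to a degenerate contour (enclosed area < 1 px²)"
        )
    return result
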