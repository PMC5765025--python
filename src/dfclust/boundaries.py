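"""Cluster boundaries as level sets of the Lagrangian field.

The Lagrangian density functional L = gamma^2 t - gamma u is evaluated on a
regular grid over the feature plane.  Each cluster center is a local
maximum of L ringed by a valley (the kinetic term wins at the density peak,
the long-range potential digs a moat around it), and the valley floor is
the cluster boundary, visible as a bright ring on the landscape.  The most
possible boundary of a cluster is therefore the *minimum-level* iso-contour
of L that still encloses only that cluster's center: growing the superlevel
set {L >= lambda} around a center, the boundary level lambda* is the last
level before the component spills across the valley into a neighbouring
center's region.  lambda* is located by bisection — the (inverted)
watershed merge level of the two summit regions.  For a single cluster
there is no merge; the boundary is the ring of regional minima encircling
the center (the zero set of the functional derivative of L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.ndimage import binary_dilation
from skimage import measure

from .errors import (
    DegenerateCentersError,
    DimensionMismatchError,
    InvalidParameterError,
)
from .functionals import WeightedPointSet, adaptive_gamma, kedf, pedf
from .mixture import MixtureDensity, density_at, responsibilities

__all__ = [
    "ScalarField",
    "ClusterSolution",
    "ldf_landscape",
    "cluster_boundaries",
    "assign_labels",
    "bounds_from_data",
]


@dataclass
class ScalarField:
    """Values of a field (rho, t, u, H or L) on a regular grid.

    ``values[i, j, ...]`` sits at ``origin + (i, j, ...) * spacing``; axis k
    of the array is feature axis k.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    name: str = "L"
    gamma: float | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).ravel()
        self.spacing = np.asarray(self.spacing, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float)
        if self.name not in ("rho", "t", "u", "H", "L"):
            raise InvalidParameterError(f"unknown field name {self.name!r}")
        if np.any(self.spacing <= 0):
            raise InvalidParameterError("grid spacing must be positive")
        if self.values.ndim != self.origin.size or self.origin.size != self.spacing.size:
            raise DimensionMismatchError("grid metadata does not match values")

    @property
    def dim(self) -> int:
        return self.values.ndim

    def to_index(self, points):
        """Fractional grid indices of feature-space points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) / self.spacing

    def to_feature(self, indices):
        """Feature-space coordinates of (fractional) grid indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + idx * self.spacing


@dataclass
class ClusterSolution:
    """Selected cluster number, centers, boundary polylines and point labels.

    ``boundaries[k]`` is a list of closed polylines (arrays of (x, y) feature
    coordinates) delimiting cluster k; ``labels`` is filled by
    :func:`assign_labels`.
    """

    m_star: int
    centers: np.ndarray
    boundaries: list = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.m_star != self.centers.shape[0]:
            raise InvalidParameterError("one center per cluster required")


def bounds_from_data(data, pad_sigmas: float = 3.0):
    """Axis-aligned box around the data, padded by pooled standard deviations."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    sigma = float(np.mean(data.std(axis=0)))
    lo = data.min(axis=0) - pad_sigmas * sigma
    hi = data.max(axis=0) + pad_sigmas * sigma
    return np.stack([lo, hi], axis=1)


def _coulomb_kernel_2d(shape, spacing):
    nx, ny = shape
    dx, dy = spacing
    ii = np.arange(-(nx - 1), nx) * dx
    jj = np.arange(-(ny - 1), ny) * dy
    r = np.hypot(ii[:, None], jj[None, :])
    with np.errstate(divide="ignore"):
        k = np.where(r > 0, 1.0 / r, 0.0)
    return k


def grid_coulomb(mass, spacing, origin_weight: float = 0.0):
    """1/r potential of a gridded mass distribution via FFT convolution.

    With ``origin_weight = 0`` (default) this is exactly the pairwise sum
    with self-exclusion.  Quadrature of a *continuous* density can pass the
    analytic self-cell weight instead (see :func:`cell_self_weight`), since
    the mass inside each node's own cell has a finite 1/r integral that
    plain self-exclusion would drop — an O(h) bias.
    """
    mass = np.asarray(mass, dtype=float)
    kern = _coulomb_kernel_2d(mass.shape, spacing)
    kern[mass.shape[0] - 1, mass.shape[1] - 1] = origin_weight
    out = fftconvolve(mass, kern, mode="same")
    return np.maximum(out, 0.0)


def cell_self_weight(spacing):
    """Mean 1/r potential of a unit point mass spread over its own grid cell:
    ``integral of dA/|r| over the cell, divided by the cell area``."""
    a, b = 0.5 * spacing[0], 0.5 * spacing[1]
    integral = 4.0 * (a * np.arcsinh(b / a) + b * np.arcsinh(a / b))
    return integral / (4.0 * a * b)


def ldf_landscape(model: MixtureDensity, bounds, resolution: int = 128) -> ScalarField:
    """Evaluate the Lagrangian field of a mixture density on a regular grid.

    rho comes from the mixture, t from the KEDF, u from the grid-quadrature
    PEDF (mass = rho * cell volume; FFT path in 2-D, direct pairwise sum in
    higher dimension), gamma from the same masses.
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    d = model.dim
    if bounds.shape != (d, 2):
        raise DimensionMismatchError(f"bounds must have shape ({d}, 2)")
    if np.any(bounds[:, 1] <= bounds[:, 0]):
        raise InvalidParameterError("bounds box has zero or negative volume")
    res = np.broadcast_to(np.asarray(resolution, dtype=int), (d,)).copy()
    if np.any(res < 2):
        raise InvalidParameterError("resolution must be at least 2 per axis")

    axes = [np.linspace(bounds[k, 0], bounds[k, 1], res[k]) for k in range(d)]
    spacing = np.array([ax[1] - ax[0] for ax in axes])
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)

    rho = density_at(model, pts).reshape(tuple(res))
    cellvol = float(np.prod(spacing))
    mass = rho * cellvol
    t = kedf(rho.ravel(), d).reshape(rho.shape)
    if d == 2:
        u = grid_coulomb(mass, spacing, origin_weight=cell_self_weight(spacing))
    else:
        src = WeightedPointSet(pts, mass.ravel(), quadrature="grid")
        u = pedf(src, pts).reshape(rho.shape)
    gamma = adaptive_gamma(t.ravel(), u.ravel(), mass.ravel())
    lfield = gamma**2 * t - gamma * u
    return ScalarField(
        origin=bounds[:, 0], spacing=spacing, values=lfield, name="L", gamma=gamma
    )


def _center_cells(field: ScalarField, centers):
    idx = np.rint(field.to_index(centers)).astype(int)
    shape = field.values.shape
    for k, cell in enumerate(idx):
        if np.any(cell < 0) or np.any(cell >= shape):
            raise InvalidParameterError(f"center {k} falls outside the grid")
    cells = [tuple(c) for c in idx]
    if len(set(cells)) < len(cells):
        raise DegenerateCentersError("two centers share a grid cell")
    return cells


def merge_level(values, cell, other_cells, iters: int = 48):
    """Smallest level lambda at which the superlevel component {L >= lambda}
    of ``cell`` still excludes every cell in ``other_cells`` and stays off
    the grid border.

    Cluster centers are local maxima of L ringed by a valley; lowering
    lambda grows the center's summit region outward until it spills across
    the valley — into a neighbouring center's region, or (for a lone
    center) out toward the unbounded far field.  The last pre-spill level,
    found by bisection, is the height of the valley barrier: the level of
    the minimum iso-contour that contains only this center.
    """

    def merged(lam):
        lbl = measure.label(values >= lam, connectivity=2)
        comp = lbl[cell]
        if any(lbl[o] == comp and lbl[o] != 0 for o in other_cells):
            return True
        mask = lbl == comp
        return bool(
            mask[0, :].any() or mask[-1, :].any()
            or mask[:, 0].any() or mask[:, -1].any()
        )

    hi = float(values[cell])
    lo = float(values.min())
    if merged(hi):
        return hi
    if not merged(lo):
        return lo
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if merged(mid):
            lo = mid
        else:
            hi = mid
    return hi


def _polygon_area(poly):
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def points_in_polygon(points, poly):
    """Even-odd ray-casting test; ``poly`` is a closed (K, 2) polyline."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    px, py = poly[:-1, 0], poly[:-1, 1]
    qx, qy = np.roll(px, -1), np.roll(py, -1)
    x = pts[:, 0][:, None]
    y = pts[:, 1][:, None]
    crosses = (py > y) != (qy > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = px + (y - py) * (qx - px) / (qy - py)
    hits = crosses & (x < xint)
    return np.sum(hits, axis=1) % 2 == 1


def _closed_contours(values, level):
    out = []
    for c in measure.find_contours(values, level):
        if len(c) >= 4 and np.allclose(c[0], c[-1]):
            out.append(c)
    return out


def _mask_contour(mask):
    cs = _closed_contours(mask.astype(float), 0.5)
    if not cs:
        return None
    return max(cs, key=_polygon_area)

def _component_mask(values, cell, lam):
    lbl = measure.label(values >= lam, connectivity=2)
    return lbl == lbl[cell]


def _select_contour(values, level, cell, other_cells, comp_mask):
    """Closed iso-contour at ``level`` tracing the superlevel component of
    ``cell``.

    Among the closed contours at the level, keeps those that enclose the
    cell, exclude the other centers and run along the component itself (the
    same level also carves a contour on the far side of the boundary
    valley, which must not be picked); falls back to the component-mask
    outline when the iso-contour is open (e.g. clipped by the grid edge).
    """
    near = binary_dilation(comp_mask, structure=np.ones((3, 3), dtype=bool))
    cands = []
    for c in _closed_contours(values, level):
        if not points_in_polygon([cell], c)[0]:
            continue
        if any(points_in_polygon([o], c)[0] for o in other_cells):
            continue
        idx = np.clip(np.rint(c).astype(int), 0, np.array(values.shape) - 1)
        if np.mean(near[idx[:, 0], idx[:, 1]]) < 0.9:
            continue
        cands.append(c)
    if cands:
        return max(cands, key=_polygon_area)
    return _mask_contour(comp_mask)


def cluster_boundaries(
    field: ScalarField, centers, model: MixtureDensity | None = None
) -> ClusterSolution:
    """Extract one closed boundary per cluster center from an L field.

    For several centers the boundary of center c is the iso-contour at the
    merge level of its superlevel-set component (last level before another
    center joins across the boundary valley); for a single center it is the
    contour through the ring of regional minima.
    """
    if field.dim != 2:
        raise InvalidParameterError("contour extraction requires a 2-D field")
    if field.name != "L":
        raise InvalidParameterError("cluster_boundaries expects an L field")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    m = centers.shape[0]
    cells = _center_cells(field, centers)
    values = field.values

    boundaries = []
    for k in range(m):
        others = [c for i, c in enumerate(cells) if i != k]
        # contour exactly at the pre-spill level; any offset could cross the
        # valley barrier and swallow the neighbouring region
        lam = merge_level(values, cells[k], others)
        comp = _component_mask(values, cells[k], lam)
        contour = _select_contour(values, lam, cells[k], others, comp)
        polys = []
        if contour is not None:
            polys.append(field.to_feature(contour))
        boundaries.append(polys)
    solution = ClusterSolution(m_star=m, centers=centers, boundaries=boundaries)
    if model is not None:
        pass  # labels are assigned separately; model kept for callers
    return solution


def assign_labels(data, solution: ClusterSolution, model: MixtureDensity | None = None):
    """Label every point: unique enclosing boundary wins, otherwise the
    highest-responsibility component (or nearest center when no model is
    given).  Ties break to the lowest cluster index."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    m = solution.m_star
    inside = np.zeros((n, m), dtype=bool)
    if data.shape[1] == 2:
        for k, polys in enumerate(solution.boundaries):
            for poly in polys:
                inside[:, k] |= points_in_polygon(data, np.asarray(poly))
    count = inside.sum(axis=1)
    labels = np.full(n, -1, dtype=int)
    unique = count == 1
    labels[unique] = np.argmax(inside[unique], axis=1)
    rest = ~unique
    if np.any(rest):
        if model is not None:
            resp = responsibilities(model, data[rest])
            labels[rest] = np.argmax(resp, axis=1)
        else:
            d2 = ((data[rest, None, :] - solution.centers[None, :, :]) ** 2).sum(-1)
            labels[rest] = np.argmin(d2, axis=1)
    solution.labels = labels
    return labels
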