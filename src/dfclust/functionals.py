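"""Energy density functionals over data densities.

The clustering machinery of this package treats an estimated data
probability density :math:`\\rho` the way density functional theory treats
an electron density: the density is mapped through a kinetic energy density
functional (KEDF) and a potential energy density functional (PEDF), and the
Hamiltonian/Lagrangian fields assembled from them carry the cluster
structure.

Under the local density approximation the Fermi wavevector of a
*D*-dimensional data density is

.. math:: k_F[\\rho] = 2\\pi\\,(D\\rho/\\alpha_D)^{1/D},

from which the per-point kinetic term follows as

.. math:: t[\\rho] = \\frac{2\\pi^2 D}{D+2}\\Big(\\frac{D}{\\alpha_D}\\Big)^{2/D}\\rho^{2/D},

i.e. :math:`t = 2\\pi^2\\rho` in two dimensions with :math:`\\alpha_2 = 1`.
The KEDF weights a point by how significant (dense) its neighbourhood is.
The PEDF is a Coulomb-like pairwise similarity,

.. math:: u(r'') = \\sum_n \\frac{m_n}{|r'' - r'_n|}\\,,\\qquad r'' \\ne r'_n,

with the self term excluded.  The two are balanced by the adaptive scaling
factor :math:`\\gamma = \\tfrac12 \\langle u\\rangle/\\langle t\\rangle`, which
makes the Hamiltonian field :math:`\\mathcal H = \\gamma^2 t + \\gamma u` and
the Lagrangian field :math:`\\mathcal L = \\gamma^2 t - \\gamma u` invariant
under uniform rescaling of the feature coordinates.  The dimension-dependent
constant :math:`\\alpha_D` cancels against the hyper-volume in the same way
and defaults to 1 throughout.

Expectations :math:`\\langle\\cdot\\rangle` are Monte-Carlo averages when the
points were sampled from :math:`\\rho` (``quadrature="sample"``, equal masses
summing to one) and mass-weighted sums when the points are grid nodes
carrying ``density * cell volume`` masses (``quadrature="grid"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateDensityError,
    DimensionMismatchError,
    DomainError,
    InvalidParameterError,
)

__all__ = [
    "WeightedPointSet",
    "FunctionalValues",
    "fermi_wavevector",
    "kedf",
    "pedf",
    "adaptive_gamma",
    "energy_fields",
    "hf_statistic",
]


@dataclass
class WeightedPointSet:
    """Points in feature space carrying nonnegative probability masses.

    Parameters
    ----------
    coords : (N, D) array
        Point locations in feature units.
    weights : (N,) array
        Nonnegative masses.  For ``quadrature="sample"`` these are
        Monte-Carlo masses and must sum to 1; for ``quadrature="grid"``
        they are quadrature masses (density times cell volume).
    quadrature : {"sample", "grid"}
        Declares how expectations over the set are to be taken.
    """

    coords: np.ndarray
    weights: np.ndarray
    quadrature: str = "sample"

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        n, d = self.coords.shape
        if n < 1 or d < 1:
            raise InvalidParameterError("point set needs N >= 1 and D >= 1")
        if self.weights.shape != (n,):
            raise DimensionMismatchError(
                f"weights shape {self.weights.shape} does not match N={n}"
            )
        if np.any(self.weights < 0):
            raise DomainError("weights must be nonnegative")
        if not np.any(self.weights > 0):
            raise DomainError("at least one weight must be positive")
        if self.quadrature not in ("sample", "grid"):
            raise InvalidParameterError(
                f"quadrature must be 'sample' or 'grid', got {self.quadrature!r}"
            )
        if self.quadrature == "sample":
            total = float(self.weights.sum())
            if abs(total - 1.0) > 1e-9:
                raise InvalidParameterError(
                    f"sample-quadrature weights must sum to 1 (got {total})"
                )

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclass
class FunctionalValues:
    """Per-point kinetic/potential terms and the assembled H and L fields.

    The constructor enforces the defining identities
    ``H - L = 2*gamma*u`` and ``H + L = 2*gamma**2*t``.
    """

    t: np.ndarray
    u: np.ndarray
    gamma: float
    H: np.ndarray = field(default=None)
    L: np.ndarray = field(default=None)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.u = np.asarray(self.u, dtype=float).ravel()
        if self.t.shape != self.u.shape:
            raise DimensionMismatchError("t and u must have the same length")
        if not self.gamma > 0:
            raise InvalidParameterError("gamma must be positive")
        if self.H is None:
            self.H = self.gamma**2 * self.t + self.gamma * self.u
        if self.L is None:
            self.L = self.gamma**2 * self.t - self.gamma * self.u
        self.H = np.asarray(self.H, dtype=float).ravel()
        self.L = np.asarray(self.L, dtype=float).ravel()
        scale = max(1.0, float(np.max(np.abs(self.H), initial=0.0)))
        if not np.allclose(self.H - self.L, 2 * self.gamma * self.u,
                           rtol=1e-9, atol=1e-9 * scale):
            raise InvalidParameterError("H - L != 2*gamma*u")
        if not np.allclose(self.H + self.L, 2 * self.gamma**2 * self.t,
                           rtol=1e-9, atol=1e-9 * scale):
            raise InvalidParameterError("H + L != 2*gamma^2*t")


def _check_d_alpha(D, alpha):
    if int(D) != D or D < 1:
        raise InvalidParameterError(f"dimension D must be a positive integer, got {D}")
    if not alpha > 0:
        raise InvalidParameterError(f"alpha must be positive, got {alpha}")
    return int(D), float(alpha)


def fermi_wavevector(rho, D, alpha=1.0):
    """Fermi wavevector of a data density: ``2*pi*(D*rho/alpha)**(1/D)``.

    Links a local density value to the radius of the occupied region in
    wavevector space; zero density maps to zero.
    """
    D, alpha = _check_d_alpha(D, alpha)
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise DomainError("density must be nonnegative")
    out = 2.0 * np.pi * (D * rho_arr / alpha) ** (1.0 / D)
    return out if out.ndim else float(out)


def kedf(rho, D, alpha=1.0):
    """Kinetic energy density functional ``c_D * rho**(2/D)`` (elementwise).

    ``c_D = (2*pi**2*D/(D+2)) * (D/alpha)**(2/D)``; for ``D=2, alpha=1`` this
    is the closed form ``2*pi**2*rho``.  Homogeneous of degree ``2/D`` in the
    density.
    """
    D, alpha = _check_d_alpha(D, alpha)
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise DomainError("density must be nonnegative")
    coeff = (2.0 * np.pi**2 * D / (D + 2.0)) * (D / alpha) ** (2.0 / D)
    out = coeff * rho_arr ** (2.0 / D)
    return out if out.ndim else float(out)


def pedf(sources: WeightedPointSet, queries, exclude_radius: float = 0.0):
    """Pairwise 1/distance potential of ``sources`` evaluated at ``queries``.

    ``u(q) = sum_n w_n / |q - r_n|`` over sources with ``|q - r_n| >
    exclude_radius``; coincident pairs (distance zero) never contribute, so
    the default radius 0 realises plain self-exclusion.
    """
    if not isinstance(sources, WeightedPointSet):
        raise InvalidParameterError("sources must be a WeightedPointSet")
    q = np.atleast_2d(np.asarray(queries, dtype=float))
    if q.shape[1] != sources.dim:
        raise DimensionMismatchError(
            f"queries have dimension {q.shape[1]}, sources {sources.dim}"
        )
    if exclude_radius < 0:
        raise InvalidParameterError("exclude_radius must be nonnegative")
    dist = cdist(q, sources.coords)
    with np.errstate(divide="ignore"):
        contrib = np.where(dist > exclude_radius, 1.0 / dist, 0.0)
    return contrib @ sources.weights


def adaptive_gamma(t, u, mass):
    """Adaptive scaling factor ``gamma = 0.5 * <u> / <t>``.

    Both expectations are weighted by ``mass`` (Monte-Carlo or quadrature
    masses), so gamma inherits the scale of the data: rescaling every
    coordinate by ``s`` multiplies gamma by ``s`` and leaves the H/L fields
    unchanged.
    """
    t = np.asarray(t, dtype=float).ravel()
    u = np.asarray(u, dtype=float).ravel()
    mass = np.asarray(mass, dtype=float).ravel()
    if not (t.shape == u.shape == mass.shape):
        raise DimensionMismatchError("t, u and mass must have the same length")
    if np.any(mass < 0):
        raise DomainError("masses must be nonnegative")
    total = mass.sum()
    if total <= 0:
        raise DegenerateDensityError("total mass is zero")
    mean_t = float(mass @ t) / total
    mean_u = float(mass @ u) / total
    if mean_t <= 0:
        raise DegenerateDensityError("<t> must be positive")
    return 0.5 * mean_u / mean_t


def energy_fields(t, u, gamma) -> FunctionalValues:
    """Assemble the Hamiltonian and Lagrangian fields from t, u and gamma."""
    return FunctionalValues(t=t, u=u, gamma=float(gamma))


def hf_statistic(t, u, gamma) -> float:
    """Averaged Hamiltonian functional ``(gamma^2*mean(t) + gamma*mean(u)) / N``.

    The means are uniform sample averages (the Monte-Carlo estimate of the
    density-weighted integral); the explicit 1/N makes the statistic an
    intensive per-point quantity used for cluster-number selection.
    """
    t = np.asarray(t, dtype=float).ravel()
    u = np.asarray(u, dtype=float).ravel()
    if t.size == 0 or u.size == 0:
        raise InvalidParameterError("hf_statistic needs nonempty t and u")
    if t.shape != u.shape:
        raise DimensionMismatchError("t and u must have the same length")
    n = t.size
    return (gamma**2 * float(t.mean()) + gamma * float(u.mean())) / n
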