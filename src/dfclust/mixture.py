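"""Gaussian-mixture estimation of the most probable data density.

The density that feeds the energy functionals is estimated as a Gaussian
mixture

.. math:: \\rho(x) = \\sum_{j=1}^{M} \\pi_j\\, \\mathcal N(x;\\, \\mu_j, \\Sigma_j)

fitted by expectation-maximization from a k-means++ initialization.  The EM
loop is implemented here (rather than delegated) because the surrounding
machinery relies on contracts a generic fitter does not expose:

* the per-iteration log-likelihood trace is recorded and checked to be
  non-decreasing on every fit;
* the fit is a pure function of ``(data, M, seed)``;
* a covariance that loses positive-definiteness despite the ridge
  regularization raises :class:`~dfclust.errors.IllConditionedFitError`,
  which the model-selection loop uses as its truncation signal.

The closed-form linear-Gaussian estimates
``w_hat = (X^T X)^{-1} X^T R`` and
``sigma2_hat = [tr(R^T R) - tr(R^T X w_hat)] / N``
are provided for the idealized non-interacting (conditionally independent)
model that motivates the mixture form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr, solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .errors import (
    DimensionMismatchError,
    IllConditionedFitError,
    InvalidParameterError,
    SingularDesignError,
    TooFewPointsError,
)

__all__ = [
    "MixtureDensity",
    "LinearGaussianFit",
    "fit_linear_gaussian",
    "fit_mixture_em",
    "density_at",
    "sample_mixture",
    "responsibilities",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixtureDensity:
    """A fitted Gaussian mixture: weights, means and full covariances."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihoods: list = field(default_factory=list, repr=False)
    converged: bool = True
    seed: int | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        m, d = self.means.shape
        if self.covariances.shape != (m, d, d):
            raise DimensionMismatchError(
                f"covariances must have shape {(m, d, d)}, got {self.covariances.shape}"
            )
        if self.weights.shape != (m,):
            raise DimensionMismatchError("one weight per component required")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("mixture weights must sum to 1")
        for j in range(m):
            cov = self.covariances[j]
            if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-12):
                raise InvalidParameterError(f"covariance {j} is not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise IllConditionedFitError(
                    f"covariance {j} is not positive definite"
                )

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def density(self, points):
        return density_at(self, points)

    def sample(self, n, seed):
        return sample_mixture(self, n, seed)


@dataclass
class LinearGaussianFit:
    """Closed-form coefficients and shared variance of the linear-Gaussian model."""

    w_hat: np.ndarray
    sigma2_hat: float
    n: int

    def __post_init__(self):
        if self.sigma2_hat < 0:
            raise InvalidParameterError("sigma2_hat must be nonnegative")


def fit_linear_gaussian(X, R, cond_cap: float = 1e12) -> LinearGaussianFit:
    """Maximum-likelihood fit of the linear-Gaussian observation model.

    Solves the normal equations for ``w_hat`` and returns the shared
    variance estimate, clamped at zero against roundoff.  A rank-deficient
    design raises :class:`SingularDesignError` naming the deficient columns
    (identified by pivoted QR).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    R = np.asarray(R, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    n, p = X.shape
    if R.shape[0] != n:
        raise DimensionMismatchError("X and R must have the same number of rows")
    if n < p:
        raise TooFewPointsError(f"need N >= P, got N={n}, P={p}")
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < p:
        raise SingularDesignError(sorted(int(c) for c in piv[rank:]))
    if np.linalg.cond(X) > cond_cap:
        raise SingularDesignError(range(p))
    w_hat, *_ = np.linalg.lstsq(X, R, rcond=None)
    sigma2 = (np.trace(R.T @ R) - np.trace(R.T @ X @ w_hat)) / n
    sigma2 = max(0.0, float(sigma2))
    if w_hat.shape[1] == 1:
        w_hat = w_hat.ravel()
    return LinearGaussianFit(w_hat=w_hat, sigma2_hat=sigma2, n=n)


def _component_log_pdf(data, mean, cov):
    """Gaussian log-density via Cholesky; raises IllConditionedFitError."""
    d = data.shape[1]
    if not np.all(np.isfinite(cov)):
        raise IllConditionedFitError("covariance contains non-finite entries")
    try:
        low = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise IllConditionedFitError(
            "covariance lost positive-definiteness"
        ) from exc
    diff = (data - mean).T
    sol = solve_triangular(low, diff, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(low)))
    return -0.5 * (d * _LOG2PI + logdet + np.sum(sol**2, axis=0))


def _weighted_log_prob(data, weights, means, covs):
    m = means.shape[0]
    wlp = np.empty((data.shape[0], m))
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    for j in range(m):
        wlp[:, j] = logw[j] + _component_log_pdf(data, means[j], covs[j])
    return wlp


def fit_mixture_em(
    data,
    M: int,
    seed: int,
    max_iter: int = 200,
    reg: float = 1e-6,
    tol: float = 1e-4,
) -> MixtureDensity:
    """Fit an M-component full-covariance Gaussian mixture by EM.

    Deterministic given ``(data, M, seed)``: means are initialized by
    k-means++ seeded with ``seed``, covariances by the (ridge-regularized)
    pooled data covariance, weights uniformly.  Iterates until the mean
    log-likelihood changes by less than ``tol`` (relative) or ``max_iter``
    is reached; the trace is stored on the returned model and verified to be
    non-decreasing.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = data.shape
    if int(M) != M or M < 1:
        raise InvalidParameterError(f"M must be a positive integer, got {M}")
    M = int(M)
    if n <= M:
        raise TooFewPointsError(f"need N > M, got N={n}, M={M}")
    if reg < 0:
        raise InvalidParameterError("reg must be nonnegative")

    means, _ = kmeans_plusplus(data, n_clusters=M, random_state=int(seed))
    base_cov = np.atleast_2d(np.cov(data, rowvar=False))
    if base_cov.shape != (d, d):
        base_cov = base_cov.reshape(d, d)
    base_cov = base_cov + reg * np.eye(d)
    covs = np.repeat(base_cov[None, :, :], M, axis=0)
    weights = np.full(M, 1.0 / M)

    eye = np.eye(d)
    ll_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        wlp = _weighted_log_prob(data, weights, means, covs)
        norm = logsumexp(wlp, axis=1)
        ll = float(norm.mean())
        if ll_trace and ll < ll_trace[-1] - 1e-7 * max(1.0, abs(ll_trace[-1])):
            raise IllConditionedFitError(
                "EM log-likelihood decreased; fit is numerically unstable"
            )
        stop = bool(ll_trace) and abs(ll - ll_trace[-1]) < tol * max(1.0, abs(ll))
        ll_trace.append(ll)
        if stop:
            converged = True
            break
        resp = np.exp(wlp - norm[:, None])
        nk = resp.sum(axis=0) + 10.0 * np.finfo(float).eps
        weights = nk / n
        means = (resp.T @ data) / nk[:, None]
        for j in range(M):
            diff = data - means[j]
            covs[j] = (resp[:, j, None] * diff).T @ diff / nk[j] + reg * eye

    weights = weights / weights.sum()
    # A covariance whose smallest eigenvalue sits at the ridge floor has
    # collapsed onto a lower-dimensional point set (e.g. duplicated rows);
    # report it instead of repairing it -- model selection listens for this.
    for j in range(M):
        if np.linalg.eigvalsh(covs[j]).min() <= 10.0 * reg:
            raise IllConditionedFitError(
                f"component {j} collapsed to the regularization floor"
            )
    model = MixtureDensity(
        weights=weights,
        means=means,
        covariances=covs,
        log_likelihoods=ll_trace,
        converged=converged,
        seed=int(seed),
    )
    return model


def density_at(model: MixtureDensity, points):
    """Mixture density values at ``points`` (strictly positive)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != model.dim:
        raise DimensionMismatchError(
            f"points have dimension {pts.shape[1]}, model {model.dim}"
        )
    wlp = _weighted_log_prob(pts, model.weights, model.means, model.covariances)
    return np.exp(logsumexp(wlp, axis=1))


def responsibilities(model: MixtureDensity, points):
    """Posterior component probabilities for each point, shape (Q, M)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != model.dim:
        raise DimensionMismatchError("dimension mismatch")
    wlp = _weighted_log_prob(pts, model.weights, model.means, model.covariances)
    return np.exp(wlp - logsumexp(wlp, axis=1)[:, None])


def sample_mixture(model: MixtureDensity, N: int, seed: int):
    """Draw N points (and component labels) from the mixture, deterministically.

    Component counts are multinomial in the mixture weights; the returned
    rows are shuffled so label blocks do not leak ordering.
    """
    if int(N) != N or N < 1:
        raise InvalidParameterError(f"N must be a positive integer, got {N}")
    rng = np.random.default_rng(int(seed))
    counts = rng.multinomial(int(N), model.weights)
    chunks, labels = [], []
    for j, c in enumerate(counts):
        if c == 0:
            continue
        chunks.append(
            rng.multivariate_normal(model.means[j], model.covariances[j], size=c)
        )
        labels.append(np.full(c, j, dtype=int))
    data = np.concatenate(chunks, axis=0)
    labels = np.concatenate(labels)
    perm = rng.permutation(int(N))
    return data[perm], labels[perm]
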