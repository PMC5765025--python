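"""Cluster-number selection from the averaged Hamiltonian (HF) curve.

For each candidate cluster number M a batch of seeded mixture fits is run;
each fit yields per-point kinetic and potential terms and hence one value of
the averaged Hamiltonian functional

.. math:: \\mathcal{HF} = \\{\\gamma^2\\langle t\\rangle + \\gamma\\langle u\\rangle\\}/N .

The potential term depends only on the data sample, so across M the curve
is driven by how well the fitted density concentrates on the data.  The
curve stabilizes once additional components stop improving the density
estimate; that first plateau (the quasi-stationary point) is taken as the
most probable cluster number.  A data set that is a single cluster never
develops a plateau-after-trend and is assigned M* = 1.

Bimodality of the per-trial HF values at the selected M (two branches
H+ / H-) indicates severely mixed clusters: EM alternates between treating
the mixed pair as one large component or splitting it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau

from .errors import (
    IllConditionedFitError,
    InvalidParameterError,
    NoStationaryPointError,
)
from .functionals import WeightedPointSet, adaptive_gamma, hf_statistic, kedf, pedf
from .mixture import MixtureDensity, density_at, fit_mixture_em

__all__ = [
    "HFCurve",
    "SplitReport",
    "trial_seed",
    "hf_curve",
    "detect_quasi_stationary",
    "detect_branch_split",
]


@dataclass
class HFCurve:
    """Averaged-HF values per candidate cluster number, plus the raw trials."""

    m_values: np.ndarray
    hf_mean: np.ndarray
    hf_trials: list
    truncated_at: int | None = None
    best_models: dict | None = None

    def __post_init__(self):
        self.m_values = np.asarray(self.m_values, dtype=int)
        self.hf_mean = np.asarray(self.hf_mean, dtype=float)
        if len(self.m_values) != len(self.hf_mean):
            raise InvalidParameterError("m_values and hf_mean length mismatch")
        for m, mean, trials in zip(self.m_values, self.hf_mean, self.hf_trials):
            if abs(mean - float(np.mean(trials))) > 1e-12 * max(1.0, abs(mean)):
                raise InvalidParameterError(
                    f"hf_mean at M={m} is not the mean of its trials"
                )

    def trials_at(self, m: int) -> np.ndarray:
        idx = np.nonzero(self.m_values == m)[0]
        if idx.size == 0:
            raise InvalidParameterError(f"M={m} is not on the curve")
        return np.asarray(self.hf_trials[idx[0]], dtype=float)


@dataclass
class SplitReport:
    """Outcome of the HF branch-split (bimodality) test at one M."""

    split_detected: bool
    split_at: int | None = None
    branch_means: tuple | None = None

    def __post_init__(self):
        if self.split_detected:
            if self.branch_means is None:
                raise InvalidParameterError("split requires branch means")
            hi, lo = self.branch_means
            if not hi > lo:
                raise InvalidParameterError("H+ branch mean must exceed H-")


def trial_seed(seed: int, m: int, trial: int) -> int:
    """Derived seed for one (M, trial) cell; reproducible and collision-free
    for trials < 1000."""
    return int(seed) + 1000 * int(m) + int(trial)


def hf_curve(
    data,
    m_max: int,
    trials: int = 85,
    seed: int = 0,
    max_iter: int = 200,
    reg: float = 1e-6,
    keep_best_models: bool = False,
) -> HFCurve:
    """Compute the averaged-HF curve over M = 1..m_max.

    Per trial: fit an M-component mixture with a derived seed, evaluate the
    fitted density at the data points, map through the KEDF, combine with
    the sample-quadrature PEDF of the data (weights 1/N, fixed across M),
    compute the adaptive gamma and the HF statistic.  Ill-conditioned trials
    are dropped; if every trial at some M fails the curve stops there and
    records ``truncated_at``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = data.shape
    if int(m_max) != m_max or m_max < 1:
        raise InvalidParameterError("m_max must be a positive integer")
    if m_max >= n:
        raise InvalidParameterError(f"m_max must be < N (got m_max={m_max}, N={n})")
    if trials < 1:
        raise InvalidParameterError("trials must be positive")

    sample = WeightedPointSet(data, np.full(n, 1.0 / n), quadrature="sample")
    u = pedf(sample, data)
    mass = np.full(n, 1.0 / n)

    m_values, hf_means, hf_trials = [], [], []
    best_models: dict[int, MixtureDensity] = {}
    truncated_at = None
    for m in range(1, int(m_max) + 1):
        vals = []
        best: MixtureDensity | None = None
        for k in range(int(trials)):
            try:
                model = fit_mixture_em(
                    data, m, seed=trial_seed(seed, m, k), max_iter=max_iter, reg=reg
                )
            except IllConditionedFitError:
                continue
            rho = density_at(model, data)
            t = kedf(rho, d)
            gamma = adaptive_gamma(t, u, mass)
            vals.append(hf_statistic(t, u, gamma))
            if keep_best_models and (
                best is None or model.log_likelihoods[-1] > best.log_likelihoods[-1]
            ):
                best = model
        if not vals:
            truncated_at = m
            break
        m_values.append(m)
        hf_means.append(float(np.mean(vals)))
        hf_trials.append(vals)
        if keep_best_models:
            best_models[m] = best
    return HFCurve(
        m_values=np.array(m_values, dtype=int),
        hf_mean=np.array(hf_means, dtype=float),
        hf_trials=hf_trials,
        truncated_at=truncated_at,
        best_models=best_models if keep_best_models else None,
    )


def _is_decreasing_trend(m, h, alpha: float = 0.05) -> bool:
    """Mann-Kendall-style one-sided test for a monotone decreasing curve.

    Trial noise keeps a slowly draining curve from being literally
    monotone, so the single-cluster convention is judged by trend: all
    pairwise differences nonpositive, or a significant decreasing Kendall
    trend of the means against M.
    """
    if np.all(np.diff(h) <= 0):
        return True
    res = kendalltau(m, h, alternative="less")
    return bool(res.statistic < 0 and res.pvalue < alpha)


def detect_quasi_stationary(
    curve: HFCurve, rel_tol: float = 0.05, window: int = 2
) -> int:
    """First M at which the HF curve has stabilized (stable-tail rule).

    The curve "becomes stable after reaching" the quasi-stationary point,
    so the detector returns the smallest M from which *every* subsequent
    per-step change stays within ``rel_tol * range(hf_mean)``; at least
    ``window`` later entries must exist for M to qualify (the last points
    of the curve cannot qualify vacuously).  Residual drift accumulated
    over many steps is tolerated: mixture estimates are inexact and a
    slowly draining tail is the documented non-ideality of the method.
    A curve that never stabilizes but trends monotonically downward
    (elementwise, or by a one-sided Kendall trend test at the 5% level) is
    a single cluster and returns 1.  A curve truncated by ill-conditioned
    fits relaxes the lookahead requirement and returns the last stable M
    before the truncation; otherwise :class:`NoStationaryPointError`.
    """
    h = np.asarray(curve.hf_mean, dtype=float)
    m = np.asarray(curve.m_values, dtype=int)
    if int(window) != window or window < 1:
        raise InvalidParameterError("window must be a positive integer")
    window = int(window)
    if len(h) < max(3, window + 1):
        raise InvalidParameterError(
            f"curve too short: {len(h)} entries for window={window}"
        )
    tol = rel_tol * float(h.max() - h.min())
    steps = np.abs(np.diff(h))
    for i in range(len(h) - window):
        if np.all(steps[i:] <= tol):
            return int(m[i])
    if _is_decreasing_trend(m, h):
        return 1
    if curve.truncated_at is not None:
        stable = [int(m[i]) for i in range(len(h) - 1) if np.all(steps[i:] <= tol)]
        if stable:
            return stable[-1]
    raise NoStationaryPointError("no quasi-stationary point on the HF curve")


def detect_branch_split(curve: HFCurve, m: int, min_trials: int = 10) -> SplitReport:
    """Largest-gap bimodality test on the per-trial HF values at one M.

    A split is declared when the largest inter-trial gap of the sorted
    values exceeds three times the median gap and each side holds at least
    20% of the trials; branch means are the side averages (H+ above).
    """
    vals = np.sort(curve.trials_at(m))
    n = vals.size
    if n < min_trials:
        raise InvalidParameterError(
            f"need at least {min_trials} surviving trials at M={m}, have {n}"
        )
    gaps = np.diff(vals)
    if gaps.size == 0 or np.all(gaps == 0):
        return SplitReport(split_detected=False)
    k = int(np.argmax(gaps))
    g_max = float(gaps[k])
    g_med = float(np.median(gaps))
    lower, upper = k + 1, n - (k + 1)
    detected = g_max > 3.0 * g_med and min(lower, upper) >= 0.2 * n
    if not detected:
        return SplitReport(split_detected=False)
    return SplitReport(
        split_detected=True,
        split_at=int(m),
        branch_means=(float(vals[k + 1 :].mean()), float(vals[: k + 1].mean())),
    )
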