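"""End-to-end clustering driver: HF curve -> M* -> boundaries -> labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boundaries import (
    ClusterSolution,
    assign_labels,
    bounds_from_data,
    cluster_boundaries,
    ldf_landscape,
)
from .errors import InvalidParameterError
from .mixture import MixtureDensity, responsibilities
from .selection import HFCurve, SplitReport, detect_branch_split, detect_quasi_stationary, hf_curve

__all__ = ["ClusterResult", "cluster_dataset"]


@dataclass
class ClusterResult:
    """Everything one run of the unsupervised clustering produces."""

    curve: HFCurve
    m_star: int
    split: SplitReport | None
    model: MixtureDensity
    labels: np.ndarray
    solution: ClusterSolution | None = None


def cluster_dataset(
    data,
    m_max: int = 8,
    trials: int = 85,
    seed: int = 0,
    rel_tol: float = 0.05,
    window: int = 2,
    grid_resolution: int = 128,
    reg: float = 1e-6,
) -> ClusterResult:
    """Select the cluster number from the HF curve and label the data.

    Runs the seeded HF-curve search, applies the quasi-stationary plateau
    detector and the branch-split test at the selected M, keeps the
    highest-likelihood mixture fit at M*, and — for planar data — extracts
    per-cluster boundaries from the Lagrangian landscape.  Labels come from
    the boundaries where unambiguous and from posterior responsibilities
    otherwise.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    curve = hf_curve(
        data, m_max=m_max, trials=trials, seed=seed, reg=reg, keep_best_models=True
    )
    m_star = detect_quasi_stationary(curve, rel_tol=rel_tol, window=window)
    try:
        split = detect_branch_split(curve, m_star)
    except InvalidParameterError:
        split = None
    model = curve.best_models[m_star]
    solution = None
    if data.shape[1] == 2:
        field = ldf_landscape(
            model, bounds_from_data(data), resolution=grid_resolution
        )
        solution = cluster_boundaries(field, model.means, model=model)
        labels = assign_labels(data, solution, model=model)
    else:
        labels = np.argmax(responsibilities(model, data), axis=1)
    return ClusterResult(
        curve=curve,
        m_star=int(m_star),
        split=split,
        model=model,
        labels=labels,
        solution=solution,
    )
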