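"""Condition-averaged PCA trajectories and trajectory distances.

Kernel-smoothed mean rates per neuron and condition are arranged in a
neurons x (time x condition) matrix, each neuron's row is mean-centered,
and the principal components of the neuron-space covariance are computed.
Projecting the centered matrix onto the leading components and reshaping
per condition yields low-dimensional population trajectories; pairwise
Euclidean distances between condition trajectories (water-sucrose pairs or
all stimulus pairs) quantify when the population state separates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .binning import SmoothedRates

__all__ = [
    "TrajectorySet", "DistanceSeries",
    "condition_matrix", "pca_trajectories", "trajectory_distances",
    "water_sucrose_pairs", "all_stimulus_pairs",
]


@dataclass
class TrajectorySet:
    coefficients: np.ndarray        # (neurons, components)
    explained_variance: np.ndarray  # fractions, non-increasing
    trajectories: np.ndarray        # (conditions, components, n_t)
    conditions: list
    t_grid: np.ndarray


@dataclass
class DistanceSeries:
    t_grid: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    pairs: list[tuple]


def condition_matrix(smoothed: SmoothedRates, min_trials_ok: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, list, np.ndarray]:
    """neurons x (time * conditions) matrix, condition-major column order.

    Column j*T + t holds condition j at time-grid point t.  ``min_trials_ok``
    optionally masks neurons that failed the per-condition trial threshold.
    Returns (matrix, conditions, kept neuron ids).
    """
    rates = smoothed.rates
    ids = smoothed.neuron_ids
    if min_trials_ok is not None:
        keep = np.asarray(min_trials_ok, dtype=bool)
        rates, ids = rates[keep], ids[keep]
    n, c, t = rates.shape
    return rates.reshape(n, c * t), list(smoothed.conditions), ids


def pca_trajectories(matrix: np.ndarray, conditions: list, t_grid: np.ndarray,
                     n_components: int | None = None,
                     lowess_span: float = 0.1) -> TrajectorySet:
    """Covariance PCA of the neuron space and per-condition trajectories.

    Rows are mean-centered (no variance scaling); components are
    eigenvectors of the neuron-space covariance.  Each projected trajectory
    is smoothed with locally weighted regression (``lowess_span`` fraction
    of the epoch); a span of 0 disables smoothing.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >=2 neurons and >=2 columns")
    n, m = X.shape
    n_cond, n_t = len(conditions), len(t_grid)
    if n_cond * n_t != m:
        raise ValueError("column count inconsistent with conditions x time")

    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / (m - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    total = evals.sum()
    frac = evals / total if total > 0 else evals

    k = n_components or n
    P = evecs[:, :k].T                  # (components, neurons)
    Y = P @ Xc                          # (components, conditions*time)
    traj = Y.reshape(k, n_cond, n_t).transpose(1, 0, 2)

    if lowess_span and n_t >= 10:
        sm = np.empty_like(traj)
        xs = np.asarray(t_grid, dtype=float)
        for ci in range(n_cond):
            for ki in range(k):
                sm[ci, ki] = lowess(traj[ci, ki], xs, frac=lowess_span,
                                    return_sorted=False)
        traj = sm

    return TrajectorySet(coefficients=evecs[:, :k],
                         explained_variance=frac[:k],
                         trajectories=traj, conditions=list(conditions),
                         t_grid=np.asarray(t_grid))


def water_sucrose_pairs(conditions: list) -> list[tuple]:
    """The five water-sucrose pairs (condition 0 %w/v against each other)."""
    water = [c for c in conditions if float(c) == 0.0]
    if len(water) != 1:
        raise ValueError("expected exactly one water condition")
    return [(water[0], c) for c in conditions if c != water[0]]


def all_stimulus_pairs(conditions: list) -> list[tuple]:
    """All 15 unordered stimulus pairs."""
    return list(combinations(conditions, 2))


def trajectory_distances(ts: TrajectorySet, pairs: list[tuple],
                         n_components: int = 3) -> DistanceSeries:
    """Mean +/- SEM Euclidean distance over a pair set, per time point.

    Distances are taken in the leading ``n_components`` subspace and are
    invariant to orthogonal rotations of that subspace.
    """
    index = {c: i for i, c in enumerate(ts.conditions)}
    k = min(n_components, ts.trajectories.shape[1])
    d = np.empty((len(pairs), ts.t_grid.size))
    for i, (ca, cb) in enumerate(pairs):
        diff = ts.trajectories[index[ca], :k] - ts.trajectories[index[cb], :k]
        d[i] = np.linalg.norm(diff, axis=0)
    sem = (d.std(axis=0, ddof=1) / np.sqrt(len(pairs))
           if len(pairs) > 1 else np.zeros(ts.t_grid.size))
    return DistanceSeries(t_grid=ts.t_grid, mean=d.mean(axis=0), sem=sem,
                          pairs=list(pairs))
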