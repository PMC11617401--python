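"""Sequential structure of population encoding.

The selectivity matrix of an encoder population (neurons x bins of auROC
values) is rectified — |auROC - 0.5|, zeroed where the deviation is below
0.1 — and summarized by the Sequentiality Index (SqI), the geometric mean of
two normalized entropies:

* Peak entropy (PE): entropy of the distribution of per-neuron peak bins,
  normalized by ln(B).  PE -> 1 when the encoding peaks of different neurons
  homogeneously tile the analyzed period.
* Temporal sparsity (TS): one minus the mean per-bin entropy of the
  activity shares across neurons, normalized by ln(N).  TS -> 1 when each
  bin's encoding is attributable to a single neuron.

Both entropies use natural logs; normalization makes the base irrelevant.
Reproducibility of a sequence is assessed by splitting trials in half,
recomputing the auROC matrix per half, and comparing the halves' mean
squared difference against a null built by shuffling the second matrix's
rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .binning import RateTensor
from .screening import AUROC_MARGIN, SelectivityMatrix, _rank_auroc

__all__ = [
    "SequentialityResult", "ReproducibilityResult",
    "rectify", "peak_entropy", "temporal_sparsity", "sequentiality_index",
    "sort_by_peak", "sequentiality", "split_half_reproducibility",
    "latency_comparison",
]

SQI_WINDOW = (0.0, 800.0)   # ms post-alignment used for PE/TS/SqI


class DegenerateMatrixError(ValueError):
    """The rectified matrix carries no above-threshold encoding."""


@dataclass(frozen=True)
class SequentialityResult:
    PE: float
    TS: float
    SqI: float
    N: int
    B: int
    peak_bins: np.ndarray


@dataclass(frozen=True)
class ReproducibilityResult:
    mse: float
    p: float
    n_perm: int


def rectify(sm: SelectivityMatrix, window: tuple[float, float] = SQI_WINDOW,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Rectified deviations |A - 0.5| over bins centered inside ``window``.

    Deviations below the 0.4/0.6 margin are zeroed (they did not count as
    encoding).  Returns (R, kept bin centers).
    """
    centers = sm.bin_centers
    keep = (centers >= window[0]) & (centers <= window[1])
    dev = np.abs(sm.A[:, keep] - 0.5)
    R = np.where(dev >= AUROC_MARGIN - 1e-12, dev, 0.0)
    return R, centers[keep]


def _check_rows(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2:
        raise ValueError("expected a neurons x bins matrix")
    if not np.all(R.any(axis=1)):
        raise DegenerateMatrixError("a row carries no rectified activity")
    return R


def peak_entropy(R: np.ndarray) -> float:
    """Normalized entropy of the per-neuron peak-bin distribution.

    Normalization is by the attainable maximum ln(min(N, B)): with fewer
    neurons than bins the peak distribution has at most N atoms, so
    dividing by ln(B) would cap PE at ln(N)/ln(B) < 1 and a perfectly
    tiling population could never reach 1.
    """
    R = _check_rows(R)
    n, b = R.shape
    m = min(n, b)
    if m == 1:
        return 0.0
    peaks = np.argmax(R, axis=1)        # earliest bin on ties
    counts = np.bincount(peaks, minlength=b)
    q = counts[counts > 0] / n
    return float(np.clip(-(q * np.log(q)).sum() / np.log(m), 0.0, 1.0))


def temporal_sparsity(R: np.ndarray) -> float:
    """1 - mean normalized per-bin entropy of activity shares across neurons.

    Bins with zero total rectified activity are excluded from the average
    (a zero column is not a distribution).
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if n == 1:
        return 1.0
    col = R.sum(axis=0)
    nz = col > 0
    if not nz.any():
        raise DegenerateMatrixError("no bin carries rectified activity")
    shares = R[:, nz] / col[nz]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(shares > 0, shares * np.log(shares), 0.0)
    h = -terms.sum(axis=0)
    return float(np.clip(1.0 - h.mean() / np.log(n), 0.0, 1.0))


def sequentiality_index(pe: float, ts: float) -> float:
    """SqI = sqrt(PE * TS), the geometric mean of the two entropies."""
    if not (0 <= pe <= 1 and 0 <= ts <= 1):
        raise ValueError("PE and TS must lie in [0, 1]")
    return float(np.sqrt(pe * ts))


def sequentiality(sm: SelectivityMatrix,
                  window: tuple[float, float] = SQI_WINDOW,
                  ) -> SequentialityResult:
    """PE, TS and SqI of an encoder population's selectivity matrix.

    Neurons with no rectified activity inside the window do not constrain
    the sequence and are dropped before the entropies are taken.
    """
    R, _ = rectify(sm, window)
    keep = R.any(axis=1)
    if not keep.any():
        raise DegenerateMatrixError("no neuron encodes inside the window")
    R = R[keep]
    pe = peak_entropy(R)
    ts = temporal_sparsity(R)
    return SequentialityResult(PE=pe, TS=ts, SqI=sequentiality_index(pe, ts),
                               N=R.shape[0], B=R.shape[1],
                               peak_bins=np.argmax(R, axis=1))


def sort_by_peak(R: np.ndarray) -> np.ndarray:
    """Row order by ascending peak bin; ties keep row order (stable sort)."""
    R = np.asarray(R, dtype=float)
    peaks = np.argmax(R, axis=1)
    return np.argsort(peaks, kind="stable")


def split_half_reproducibility(rates: RateTensor, labels: np.ndarray,
                               n_perm: int = 10_000, seed: int = 0,
                               ) -> ReproducibilityResult:
    """Split-half reproducibility of an encoding sequence.

    Trials are partitioned into two class-stratified random halves (odd
    counts put the extra trial in half 1); the auROC matrix is recomputed
    per half, rows of both matrices are ordered by the first half's peak
    latencies (cosmetic: the MSE is invariant to a common row permutation),
    and the observed mean squared elementwise difference is compared against
    a null of ``n_perm`` row-shuffles of matrix 2.  p is the fraction of
    null MSEs at or below the observed one — small p means the sequence is
    more similar across halves than chance row correspondence allows.
    """
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5e0)))
    half1, half2 = [], []
    for cls in (False, True):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 4:
            raise ValueError(f"class {cls}: need >=4 trials to stratify, "
                             f"got {idx.size}")
        idx = rng.permutation(idx)
        cut = (idx.size + 1) // 2
        half1.append(idx[:cut])
        half2.append(idx[cut:])
    i1, i2 = np.concatenate(half1), np.concatenate(half2)

    def half_matrix(idx: np.ndarray) -> np.ndarray:
        lab = labels[idx]
        out = np.empty((rates.rates.shape[0], rates.rates.shape[2]))
        for n in range(out.shape[0]):
            out[n] = _rank_auroc(rates.rates[n, idx, :].astype(float), lab)
        return out

    m1, m2 = half_matrix(i1), half_matrix(i2)
    order = sort_by_peak(np.abs(m1 - 0.5))
    m1, m2 = m1[order], m2[order]

    observed = float(np.mean((m1 - m2) ** 2))
    n_rows = m1.shape[0]
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = np.mean((m1 - m2[rng.permutation(n_rows)]) ** 2)
    p = (1 + int(np.sum(null <= observed + 1e-15))) / (n_perm + 1)
    return ReproducibilityResult(mse=observed, p=p, n_perm=n_perm)


def latency_comparison(peaks_a: np.ndarray, peaks_b: np.ndarray,
                       ) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Two-sample KS test on encoding-peak times of two populations.

    Returns (D, p, cumulative curves) where each curve is the sorted peak
    times paired with cumulative proportions, for plotting recruitment.
    """
    peaks_a = np.asarray(peaks_a, dtype=float)
    peaks_b = np.asarray(peaks_b, dtype=float)
    if peaks_a.size < 3 or peaks_b.size < 3:
        raise ValueError("need at least three peaks per population")
    res = stats.ks_2samp(peaks_a, peaks_b)
    curves = tuple(
        (np.sort(p), np.arange(1, p.size + 1) / p.size)
        for p in (peaks_a, peaks_b)
    )
    return float(res.statistic), float(res.pvalue), curves
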