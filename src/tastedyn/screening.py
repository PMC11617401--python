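"""Signal-detection screening of single neurons.

Per neuron and sliding-window bin, the overlap between the firing-rate
distributions of two trial classes is measured by the area under the ROC
curve (auROC): the Mann-Whitney U statistic normalized by the product of
sample sizes, with half credit for ties.  Values near 0 or 1 mean fully
segregated distributions; 0.5 means complete overlap.  Significance comes
from a two-tailed permutation test of the class labels; a neuron is an
*encoder* when at least five consecutive bins qualify (significant and
|auROC - 0.5| >= 0.1, i.e. auROC outside [0.4, 0.6]).

For the stimulus contrast (water vs sucrose) a companion *choice
probability* index is computed from the same trials relabeled by the
animal's response; a bin counts toward stimulus encoding only when its
stimulus auROC deviates farther from 0.5, in the same direction, than the
choice probability.  This disambiguates stimulus from choice encoding,
which correlate trial-by-trial; the comparison only has content when error
trials are included, so the stimulus screen uses all labeled trials by
default.

Class orientation is fixed throughout: class A (coded low) = water /
water-response / non-rewarded; class B (coded high) = sucrose /
sucrose-response / rewarded.  auROC > 0.5 therefore means higher rates on
sucrose(-response)/rewarded trials.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binning import RateTensor
from .session import CORRECT, SUCROSE, EpochSpec, Session

logger = logging.getLogger(__name__)

__all__ = [
    "SelectivityMatrix", "EncoderResult",
    "auroc", "permutation_pvalue", "selectivity_matrix", "detect_encoders",
    "proportion_ztest", "neuron_counts_report", "contrast_labels",
    "screen_session",
]

CONTRASTS = ("stimulus", "choice", "outcome")
AUROC_MARGIN = 0.1      # |auROC - 0.5| threshold, i.e. the 0.4 / 0.6 rule
MIN_RUN = 5             # consecutive qualifying bins required of an encoder
ALPHA = 0.05


def _rank_auroc(rates: np.ndarray, is_b: np.ndarray) -> np.ndarray:
    """auROC per column of ``rates`` (trials x bins), class B coded high."""
    n_b = int(is_b.sum())
    n_a = is_b.size - n_b
    ranks = stats.rankdata(rates, axis=0)
    r_b = ranks[is_b].sum(axis=0)
    return (r_b - n_b * (n_b + 1) / 2.0) / (n_a * n_b)


def auroc(x_a: np.ndarray, x_b: np.ndarray) -> float:
    """P(X_b > X_a) + 0.5 P(X_b = X_a): Mann-Whitney U / (n_a * n_b).

    Symmetric under swapping the samples via A <-> 1 - A.
    """
    x_a = np.asarray(x_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    if x_a.size == 0 or x_b.size == 0:
        raise ValueError("auROC undefined for an empty sample")
    pooled = np.concatenate([x_a, x_b])[:, None]
    is_b = np.concatenate([np.zeros(x_a.size, bool), np.ones(x_b.size, bool)])
    return float(_rank_auroc(pooled, is_b)[0])


def _permutation_indicators(rng: np.random.Generator, n_trials: int, n_b: int,
                            n_perm: int) -> np.ndarray:
    """n_perm boolean rows, each a random relabeling with n_b class-B trials."""
    base = np.zeros(n_trials, dtype=bool)
    base[:n_b] = True
    return rng.permuted(np.tile(base, (n_perm, 1)), axis=1)


def _perm_aurocs(ranks: np.ndarray, indicators: np.ndarray,
                 n_a: int, n_b: int) -> np.ndarray:
    """Permuted auROCs: (n_perm, bins) from pooled ranks (trials, bins)."""
    sums = indicators.astype(float) @ ranks
    return (sums - n_b * (n_b + 1) / 2.0) / (n_a * n_b)


def permutation_pvalue(x_a: np.ndarray, x_b: np.ndarray, n_perm: int = 10_000,
                       seed: int | np.random.SeedSequence = 0) -> float:
    """Two-tailed permutation p for the auROC of two rate samples.

    p = (1 + #{perm: |A_perm - 0.5| >= |A_obs - 0.5|}) / (n_perm + 1).
    """
    x_a = np.asarray(x_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    if x_a.size + x_b.size < 2 or x_a.size == 0 or x_b.size == 0:
        raise ValueError("need at least one observation per group")
    pooled = np.concatenate([x_a, x_b])[:, None]
    is_b = np.concatenate([np.zeros(x_a.size, bool), np.ones(x_b.size, bool)])
    obs = abs(_rank_auroc(pooled, is_b)[0] - 0.5)
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(pooled, axis=0)
    ind = _permutation_indicators(rng, pooled.shape[0], int(is_b.sum()), n_perm)
    null = np.abs(_perm_aurocs(ranks, ind, x_a.size, int(is_b.sum()))[:, 0] - 0.5)
    exceed = int(np.sum(null >= obs - 1e-12))
    return (1 + exceed) / (n_perm + 1)


@dataclass
class SelectivityMatrix:
    """Per neuron x bin auROC screen for one contrast."""

    contrast: str
    epoch: EpochSpec
    A: np.ndarray                       # (neurons, bins) auROC
    p: np.ndarray                       # permutation p-values
    valid: np.ndarray                   # False where a class had <2 trials
    neuron_ids: np.ndarray
    C: np.ndarray | None = None         # choice-probability companion
    alpha: float = ALPHA
    class_low: str = ""                 # class A, coded low
    class_high: str = ""                # class B, coded high

    @property
    def sig(self) -> np.ndarray:
        """Significant selective bins: p <= alpha and auROC outside [0.4, 0.6]."""
        return (self.valid & (self.p <= self.alpha)
                & (np.abs(self.A - 0.5) >= AUROC_MARGIN - 1e-12))

    @property
    def bin_centers(self) -> np.ndarray:
        return self.epoch.bin_centers

    def restrict_neurons(self, mask: np.ndarray) -> "SelectivityMatrix":
        mask = np.asarray(mask, dtype=bool)
        return SelectivityMatrix(
            contrast=self.contrast, epoch=self.epoch, A=self.A[mask],
            p=self.p[mask], valid=self.valid[mask],
            neuron_ids=self.neuron_ids[mask],
            C=None if self.C is None else self.C[mask],
            alpha=self.alpha, class_low=self.class_low,
            class_high=self.class_high)


def selectivity_matrix(rates: RateTensor, labels: np.ndarray, contrast: str,
                       n_perm: int = 10_000, seed: int = 0,
                       choice_labels: np.ndarray | None = None,
                       alpha: float = ALPHA) -> SelectivityMatrix:
    """Sliding-window auROC screen of every neuron in a rate tensor.

    ``labels``: boolean per trial, True for the class coded high (sucrose /
    sucrose-response / rewarded).  For the stimulus contrast pass
    ``choice_labels`` (True = sucrose response) to obtain the companion
    choice-probability matrix C from the same trials.

    Permutation null: label shuffles drawn once per neuron from a
    counter-based split of the master seed, shared across that neuron's bins.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    labels = np.asarray(labels, dtype=bool)
    n_neurons, n_trials, n_bins = rates.rates.shape
    if labels.size != n_trials:
        raise ValueError("labels length disagrees with trial axis")

    n_b = int(labels.sum())
    n_a = n_trials - n_b
    A = np.full((n_neurons, n_bins), 0.5)
    p = np.ones((n_neurons, n_bins))
    valid = np.zeros((n_neurons, n_bins), dtype=bool)
    C = None

    class_low, class_high = {
        "stimulus": ("water", "sucrose"),
        "choice": ("water_response", "sucrose_response"),
        "outcome": ("non_rewarded", "rewarded"),
    }[contrast]

    if min(n_a, n_b) < 2:
        logger.warning("contrast %s: a class has <2 trials; matrix invalid",
                       contrast)
        return SelectivityMatrix(contrast, rates.epoch, A, p, valid,
                                 rates.neuron_ids, C, alpha,
                                 class_low, class_high)

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_neurons)
    for i in range(n_neurons):
        r = rates.rates[i].astype(float)            # (trials, bins)
        ranks = stats.rankdata(r, axis=0)
        obs = (ranks[labels].sum(axis=0) - n_b * (n_b + 1) / 2.0) / (n_a * n_b)
        A[i] = obs
        rng = np.random.default_rng(children[i])
        ind = _permutation_indicators(rng, n_trials, n_b, n_perm)
        null = np.abs(_perm_aurocs(ranks, ind, n_a, n_b) - 0.5)
        exceed = (null >= np.abs(obs - 0.5)[None, :] - 1e-12).sum(axis=0)
        p[i] = (1 + exceed) / (n_perm + 1)
        valid[i] = True

    if contrast == "stimulus" and choice_labels is not None:
        choice_labels = np.asarray(choice_labels, dtype=bool)
        ncb = int(choice_labels.sum())
        if min(ncb, n_trials - ncb) >= 2:
            C = np.empty((n_neurons, n_bins))
            for i in range(n_neurons):
                C[i] = _rank_auroc(rates.rates[i].astype(float), choice_labels)
        else:
            logger.warning("choice-probability companion skipped: a response "
                           "class has <2 trials")

    return SelectivityMatrix(contrast, rates.epoch, A, p, valid,
                             rates.neuron_ids, C, alpha, class_low, class_high)


@dataclass
class EncoderResult:
    """Encoder detection over a selectivity matrix."""

    contrast: str
    neuron_ids: np.ndarray
    is_encoder: np.ndarray              # (neurons,) bool
    best_bin: np.ndarray                # (neurons,) int, -1 if not encoder
    preference: np.ndarray              # classA/classB_preferring/switching/""
    runs: list[list[tuple[int, int]]]   # per neuron, [start, end) bin runs
    qualifying: np.ndarray              # (neurons, bins) bool
    bin_centers: np.ndarray

    @property
    def n_encoders(self) -> int:
        return int(self.is_encoder.sum())

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(dict(
            neuron_id=self.neuron_ids,
            is_encoder=self.is_encoder,
            best_bin_center=[self.bin_centers[b] if b >= 0 else np.nan
                             for b in self.best_bin],
            preference=self.preference,
        ))


def _maximal_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, q in enumerate(list(mask) + [False]):
        if q and start is None:
            start = i
        elif not q and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    return runs


def detect_encoders(sm: SelectivityMatrix, min_run: int = MIN_RUN,
                    ) -> EncoderResult:
    """Apply the consecutive-bin encoder rule to a selectivity matrix.

    A bin qualifies when it is significant and selective (``sm.sig``) and,
    for the stimulus contrast with a companion matrix, deviates farther from
    0.5 than the choice probability in the same direction (A > C for
    sucrose-preferring bins, A < C for water-preferring ones).  A neuron is
    an encoder when >=``min_run`` consecutive bins qualify.  best_bin is the
    earliest maximum of |A - 0.5| inside a qualifying run; preference comes
    from the sign structure of the qualifying runs (both signs present ->
    switching).
    """
    qual = sm.sig.copy()
    if sm.contrast == "stimulus" and sm.C is not None:
        high = sm.A >= 0.5
        qual &= np.where(high, sm.A > sm.C, sm.A < sm.C)

    n_neurons, n_bins = qual.shape
    is_enc = np.zeros(n_neurons, dtype=bool)
    best = np.full(n_neurons, -1, dtype=int)
    pref = np.full(n_neurons, "", dtype=object)
    all_runs: list[list[tuple[int, int]]] = []
    for i in range(n_neurons):
        runs = _maximal_runs(qual[i], min_run)
        all_runs.append(runs)
        if not runs:
            continue
        is_enc[i] = True
        in_run = np.zeros(n_bins, dtype=bool)
        for a, b in runs:
            in_run[a:b] = True
        dev = np.where(in_run, np.abs(sm.A[i] - 0.5), -np.inf)
        best[i] = int(np.argmax(dev))               # earliest max by argmax
        signs = set()
        for a, b in runs:
            signs.update(np.sign(sm.A[i, a:b] - 0.5).astype(int))
        signs.discard(0)
        if signs == {1}:
            pref[i] = "classB_preferring"
        elif signs == {-1}:
            pref[i] = "classA_preferring"
        else:
            pref[i] = "switching"
    return EncoderResult(contrast=sm.contrast, neuron_ids=sm.neuron_ids,
                         is_encoder=is_enc, best_bin=best,
                         preference=np.asarray(pref, dtype=object),
                         runs=all_runs, qualifying=qual,
                         bin_centers=sm.bin_centers)


def proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-tailed normal p."""
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError("counts must satisfy 0 <= k <= n, n >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; z defined as 0")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def neuron_counts_report(counts: dict[str, dict[str, tuple[int, int]]],
                         ) -> pd.DataFrame:
    """Encoder counts/percentages per contrast and region with z-tests.

    ``counts``: contrast -> {region: (n_encoders, n_neurons)}; exactly two
    regions per contrast are compared pairwise.
    """
    rows = []
    for contrast, by_region in counts.items():
        regions = list(by_region)
        if len(regions) != 2:
            raise ValueError("report expects exactly two regions per contrast")
        (r1, (k1, n1)), (r2, (k2, n2)) = by_region.items()
        z, p = proportion_ztest(k1, n1, k2, n2)
        for region, (k, n) in by_region.items():
            rows.append(dict(contrast=contrast, region=region, n_encoders=k,
                             n_neurons=n, percent=round(k / n * 100, 2),
                             z=round(z, 3), p=round(p, 3)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# session-level conveniences
# ---------------------------------------------------------------------------

def contrast_labels(session: Session, contrast: str,
                    trials: str = "all") -> tuple[np.ndarray, np.ndarray]:
    """(trial mask over session trial order, class-B labels) for a contrast.

    ``trials``: 'all' or 'correct'.  Outcome-epoch analyses always drop
    aborted trials (no feedback event).
    """
    tt = session.trial_table()
    mask = np.ones(len(tt), dtype=bool)
    if trials == "correct":
        mask &= (tt["outcome"] == CORRECT).to_numpy()
    elif trials != "all":
        raise ValueError("trials must be 'all' or 'correct'")
    if contrast == "outcome":
        mask &= ~tt["aborted"].to_numpy()
        labels = tt["rewarded"].to_numpy(bool)
    elif contrast == "stimulus":
        labels = (tt["category"] == SUCROSE).to_numpy()
    elif contrast == "choice":
        labels = (tt["choice"] == SUCROSE).to_numpy()
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return mask, labels[mask]


def screen_session(session: Session, contrast: str, n_perm: int = 10_000,
                   seed: int = 0, epoch: EpochSpec | None = None,
                   ) -> SelectivityMatrix:
    """End-to-end screen of one session for one contrast.

    Bins the session on the contrast's default epoch, picks the trial set
    (all labeled trials; the stimulus screen keeps error trials so the
    choice-probability disambiguation has content) and runs the auROC /
    permutation screen.
    """
    from .binning import sliding_rates
    from .session import epoch_defaults

    epoch = epoch or epoch_defaults(contrast)
    mask, labels = contrast_labels(session, contrast)
    keep_ids = {t.trial_id for t, m in zip(session.trials, mask) if m}
    tensor = sliding_rates(session, epoch,
                           trial_filter=lambda t: t.trial_id in keep_ids)
    # align label order with the tensor's retained-trial order
    retained = [t for t, m in zip(session.trials, mask) if m]
    label_of = {t.trial_id: lab for t, lab in zip(retained, labels)}
    labels = np.asarray([label_of[tid] for tid in tensor.trial_ids], bool)
    choice = None
    if contrast == "stimulus":
        by_id = {t.trial_id: t.choice == SUCROSE for t in session.trials}
        choice = np.asarray([by_id[tid] for tid in tensor.trial_ids], bool)
    return selectivity_matrix(tensor, labels, contrast, n_perm=n_perm,
                              seed=seed, choice_labels=choice)
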