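"""Resampled pseudo-population decoding with support vector machines.

Neurons recorded in different sessions are combined into pseudo-trials:
for each condition, a population feature vector is assembled by sampling,
independently per neuron and with replacement, one trial of that condition.
An 8-fold cross-validated one-vs-one SVM decodes the condition per sliding
bin; the whole construction is repeated over 15 neuron samplings x 10 trial
samplings = 150 resamples, and accuracy is reported as their mean +/- SEM.
A label-permutation arm estimates the empirical chance level (1/2 for the
binary water-vs-sucrose schema, 1/6 for the six-concentration schema).

Confusion matrices pooled over the late stimulus window are compared, by
mean squared error, against a *fine* theoretical pattern (perfect
six-way identification: the identity) and a *gross* pattern (perfect
water-vs-sucrose categorization only: water decoded as water, each sucrose
concentration spread uniformly over the five sucrose labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .binning import RateTensor, event_rate_tensor, warp_to_licks
from .session import EpochSpec, Session

logger = logging.getLogger(__name__)

__all__ = [
    "DecodingConfig", "DecodingResult", "fine_pattern", "gross_pattern",
    "select_extended_population", "build_pseudo_trials", "decode",
    "per_class_accuracy", "confusion_vs_patterns", "bootstrap_difference",
    "outcome_vs_licking_control", "warped_outcome_tensors",
]

_KERNELS = {"linear": dict(kernel="linear"),
            "gaussian": dict(kernel="rbf"),
            "poly3": dict(kernel="poly", degree=3)}


@dataclass(frozen=True)
class DecodingConfig:
    schema: str = "binary"          # binary | six_class
    kernel: str = "linear"
    n_folds: int = 8
    n_neuron_resamples: int = 15
    n_trial_resamples: int = 10
    trials_per_condition: int = 8
    permute_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schema not in ("binary", "six_class"):
            raise ValueError(f"unknown schema {self.schema!r}")
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def n_classes(self) -> int:
        return 2 if self.schema == "binary" else 6

    @property
    def n_resamples(self) -> int:
        return self.n_neuron_resamples * self.n_trial_resamples


@dataclass
class DecodingResult:
    bin_centers: np.ndarray
    accuracy: np.ndarray        # (n_resamples, n_bins) out-of-fold accuracy
    confusion_counts: np.ndarray  # (n_bins, n_classes, n_classes)
    config: DecodingConfig
    classes: np.ndarray

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    @property
    def sem_accuracy(self) -> np.ndarray:
        return self.accuracy.std(axis=0, ddof=1) / np.sqrt(self.accuracy.shape[0])

    def confusion_matrix(self, t_range: tuple[float, float] = (300.0, 840.0),
                         ) -> np.ndarray:
        """Row-normalized confusion (rows = true class) pooled over bins."""
        keep = (self.bin_centers >= t_range[0]) & (self.bin_centers <= t_range[1])
        counts = self.confusion_counts[keep].sum(axis=0)
        rows = counts.sum(axis=1, keepdims=True)
        return counts / np.where(rows == 0, 1, rows)


def fine_pattern() -> np.ndarray:
    """Perfect six-way identification: the 6x6 identity."""
    return np.eye(6)


def gross_pattern() -> np.ndarray:
    """Perfect categorization only: water -> water; each sucrose row uniform
    (1/5) over the five sucrose columns."""
    g = np.zeros((6, 6))
    g[0, 0] = 1.0
    g[1:, 1:] = 1.0 / 5.0
    return g


def confusion_vs_patterns(C: np.ndarray) -> tuple[float, float]:
    """(MSE vs fine pattern, MSE vs gross pattern) for a row-normalized 6x6."""
    C = np.asarray(C, dtype=float)
    if C.shape != (6, 6):
        raise ValueError("expected a 6x6 confusion matrix")
    return (float(np.mean((C - fine_pattern()) ** 2)),
            float(np.mean((C - gross_pattern()) ** 2)))


def select_extended_population(rates: RateTensor, concentrations: np.ndarray,
                               choice_encoders: np.ndarray | None = None,
                               alpha: float = 0.05) -> np.ndarray:
    """Neuron mask for the extended decoding population.

    Keeps neurons whose firing rate differs across the six concentrations
    (one-way ANOVA, any bin p <= alpha) and drops neurons flagged as
    choice-encoding.  ``concentrations`` label the tensor's trials;
    ``choice_encoders`` is a boolean mask over the tensor's neurons.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    levels = np.unique(concentrations)
    groups_idx = [np.flatnonzero(concentrations == lv) for lv in levels]
    if any(g.size < 2 for g in groups_idx):
        raise ValueError("each concentration needs >=2 trials for the ANOVA")
    n_neurons, _, n_bins = rates.rates.shape
    selected = np.zeros(n_neurons, dtype=bool)
    for i in range(n_neurons):
        for b in range(n_bins):
            samples = [rates.rates[i, g, b] for g in groups_idx]
            if all(np.ptp(s) == 0 for s in samples):
                continue            # constant groups: no variance to test
            _, p = stats.f_oneway(*samples)
            if p <= alpha:
                selected[i] = True
                break
    if choice_encoders is not None:
        selected &= ~np.asarray(choice_encoders, dtype=bool)
    return selected


def build_pseudo_trials(rates: np.ndarray, y: np.ndarray, classes: np.ndarray,
                        t_c: int, rng: np.random.Generator,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Assemble pseudo-trials by per-neuron sampling with replacement.

    ``rates``: (neurons, trials, bins).  For each class, ``t_c``
    pseudo-trials are built; each neuron contributes the rate of a trial of
    that class drawn independently with replacement.  Returns
    (X of shape (n_pseudo, neurons, bins), labels of shape (n_pseudo,)).
    """
    n_neurons = rates.shape[0]
    blocks, labels = [], []
    for ci, cls in enumerate(classes):
        pool = np.flatnonzero(y == cls)
        if pool.size == 0:
            raise ValueError(f"class {cls!r} has no trials")
        draws = rng.choice(pool, size=(t_c, n_neurons), replace=True)
        blocks.append(rates[np.arange(n_neurons)[None, :], draws, :])
        labels.append(np.full(t_c, ci))
    return np.concatenate(blocks, axis=0), np.concatenate(labels)


def _fold_accuracy(X: np.ndarray, y: np.ndarray, config: DecodingConfig,
                   rs: int, confusion: np.ndarray | None) -> float:
    """Stratified K-fold out-of-fold accuracy for one bin's feature matrix."""
    params = _KERNELS[config.kernel]
    n_classes = config.n_classes
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                              random_state=rs + attempt)
        try:
            correct = total = 0
            for train, test in skf.split(X, y):
                if np.unique(y[train]).size < n_classes:
                    raise ValueError("fold missing a class")
                clf = SVC(C=1.0, gamma="scale", **params)
                clf.fit(X[train], y[train])
                pred = clf.predict(X[test])
                correct += int((pred == y[test]).sum())
                total += len(test)
                if confusion is not None:
                    np.add.at(confusion, (y[test], pred), 1)
            return correct / total
        except ValueError:
            logger.info("refolding with a new seed (attempt %d)", attempt + 1)
            continue
    raise RuntimeError("could not build folds containing every class")


def decode(rates: np.ndarray, y: np.ndarray, config: DecodingConfig,
           bin_centers: np.ndarray,
           bins: np.ndarray | None = None) -> DecodingResult:
    """Resampled, cross-validated decoding of a condition from rates.

    ``rates``: (neurons, trials, bins); ``y``: per-trial class labels
    (any hashable values; sorted unique order defines the class index).
    ``bins``: optional index array restricting the decoded bins.
    """
    rates = np.asarray(rates, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != config.n_classes:
        raise ValueError(f"schema {config.schema!r} expects "
                         f"{config.n_classes} classes, got {classes.size}")
    if bins is None:
        bins = np.arange(rates.shape[2])
    bins = np.asarray(bins, dtype=int)

    n_neurons = rates.shape[0]
    root = np.random.SeedSequence((config.seed, 0xdec0))
    rng = np.random.default_rng(root)
    acc = np.empty((config.n_resamples, bins.size))
    confusion = np.zeros((bins.size, config.n_classes, config.n_classes))
    r = 0
    for i_n in range(config.n_neuron_resamples):
        neuron_sel = rng.choice(n_neurons, size=n_neurons, replace=True)
        sub = rates[neuron_sel]
        for i_t in range(config.n_trial_resamples):
            X_all, yy = build_pseudo_trials(sub, y, classes,
                                            config.trials_per_condition, rng)
            if config.permute_labels:
                yy = rng.permutation(yy)
            fold_seed = int(rng.integers(2**31 - 1))
            for j, b in enumerate(bins):
                acc[r, j] = _fold_accuracy(X_all[:, :, b], yy, config,
                                           fold_seed, confusion[j])
            r += 1
    return DecodingResult(bin_centers=np.asarray(bin_centers)[bins],
                          accuracy=acc, confusion_counts=confusion,
                          config=config, classes=classes)


def per_class_accuracy(result: DecodingResult,
                       t_range: tuple[float, float] = (300.0, 840.0),
                       ) -> np.ndarray:
    """Per-class correct-classification proportion pooled over ``t_range``.

    Equals the diagonal of the row-normalized confusion matrix.
    """
    return np.diag(result.confusion_matrix(t_range))


def bootstrap_difference(acc_a: np.ndarray, acc_b: np.ndarray,
                         n_boot: int = 10_000, seed: int = 0) -> np.ndarray:
    """Per-bin two-sided bootstrap p for a difference of resample means.

    Resamples the per-resample accuracies of each arm with replacement and
    takes p as twice the smaller tail fraction of the bootstrap differences
    around zero.
    """
    acc_a = np.atleast_2d(acc_a)
    acc_b = np.atleast_2d(acc_b)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xb007)))
    n_a, n_bins = acc_a.shape
    n_b = acc_b.shape[0]
    ia = rng.integers(n_a, size=(n_boot, n_a))
    ib = rng.integers(n_b, size=(n_boot, n_b))
    p = np.empty(n_bins)
    for j in range(n_bins):
        d = acc_a[:, j][ia].mean(axis=1) - acc_b[:, j][ib].mean(axis=1)
        lo = np.mean(d <= 0)
        hi = np.mean(d >= 0)
        p[j] = min(1.0, 2.0 * min(lo, hi))
    return p


def warped_outcome_tensors(session: Session, neuron_ids: np.ndarray,
                           epoch: EpochSpec | None = None,
                           target_ili: float = 140.0,
                           ) -> tuple[RateTensor, RateTensor, np.ndarray]:
    """Lick-warped spike-rate and lick-rate tensors around feedback.

    Every trial's full lick train (central + lateral) is warped so all
    inter-lick intervals last ``target_ili`` ms; spike times are mapped
    through the same piecewise-linear warp; both are aligned to the warped
    feedback time (second lateral lick).  Returns (neural tensor over the
    requested neurons, single-channel lick tensor, rewarded labels).
    """
    if epoch is None:
        epoch = EpochSpec("outcome_warped", "feedback_t", -400.0, 800.0)
    keep = set(int(n) for n in neuron_ids)
    trains = [st for st in session.spike_trains if int(st.neuron_id) in keep]

    trials = [t for t in session.trials if not t.aborted]
    spike_rows = [[] for _ in trains]
    lick_rows, aligns, labels, used = [], [], [], []
    for t in trials:
        licks = np.sort(np.asarray(t.central_lick_ts + t.lateral_lick_ts))
        if licks.size < 2:
            continue
        warped_licks = target_ili * np.arange(licks.size)
        # feedback = second lateral lick, located inside the warped train
        fb_idx = int(np.searchsorted(licks, t.feedback_t))
        fb_warped = warped_licks[fb_idx]
        for i, st in enumerate(trains):
            spike_rows[i].append(warp_to_licks(st.spike_ts, licks, target_ili))
        lick_rows.append(warped_licks)
        aligns.append(fb_warped)
        labels.append(t.rewarded)
        used.append(t)

    if not used:
        raise ValueError("no trials with enough licks to warp")

    # warped clocks are per-trial; stack counts manually via the shared kernel
    n_bins = epoch.n_bins
    neural = np.zeros((len(trains), len(used), n_bins))
    lickr = np.zeros((1, len(used), n_bins))
    starts = epoch.window_starts
    for j, t0 in enumerate(aligns):
        win = t0 + starts
        for i in range(len(trains)):
            ts = np.sort(spike_rows[i][j])
            lo = np.searchsorted(ts, win, side="left")
            hi = np.searchsorted(ts, win + epoch.w, side="left")
            neural[i, j] = hi - lo
        ts = lick_rows[j]
        lo = np.searchsorted(ts, win, side="left")
        hi = np.searchsorted(ts, win + epoch.w, side="left")
        lickr[0, j] = hi - lo
    neural *= 1000.0 / epoch.w
    lickr *= 1000.0 / epoch.w

    trial_ids = np.asarray([t.trial_id for t in used])
    nt = RateTensor(epoch=epoch, rates=neural,
                    neuron_ids=np.asarray([st.neuron_id for st in trains]),
                    trial_ids=trial_ids)
    lt = RateTensor(epoch=epoch, rates=lickr, neuron_ids=np.asarray([0]),
                    trial_ids=trial_ids)
    return nt, lt, np.asarray(labels, dtype=bool)


def outcome_vs_licking_control(session: Session, neuron_ids: np.ndarray,
                               config: DecodingConfig | None = None,
                               bins: np.ndarray | None = None,
                               n_boot: int = 10_000,
                               ) -> dict:
    """Reward-vs-omission decoding from warped neural activity vs lick rate.

    Both arms use the same trials, the same linear-kernel resampled decoder
    and the same schema (rewarded vs non-rewarded); per-bin significance of
    the accuracy difference comes from a bootstrap over the 150 resample
    accuracies.
    """
    if config is None:
        config = DecodingConfig(schema="binary", kernel="linear")
    neural, licks, rewarded = warped_outcome_tensors(session, neuron_ids)
    y = rewarded.astype(int)
    res_n = decode(neural.rates, y, config, neural.bin_centers, bins=bins)
    res_l = decode(licks.rates, y, config, licks.bin_centers, bins=bins)
    p = bootstrap_difference(res_n.accuracy, res_l.accuracy,
                             n_boot=n_boot, seed=config.seed)
    return dict(neural=res_n, licking=res_l, p_per_bin=p,
                bin_centers=res_n.bin_centers)
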