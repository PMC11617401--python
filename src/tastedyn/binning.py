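"""Aligned firing-rate tensors, kernel-smoothed rates and lick-based warping.

Rates are raw (no z-scoring): a count in a half-open 100 ms window scaled to
Hz.  Kernel rates convolve each spike with a Gaussian (sigma = 20 ms) on a
1 ms grid.  Lick warping rescales spike times piecewise-linearly so that
every inter-lick interval lasts exactly 140 ms, aligning lick-locked
activity across trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .session import EpochSpec, Session, Trial

logger = logging.getLogger(__name__)

__all__ = [
    "RateTensor", "SmoothedRates",
    "sliding_rates", "kernel_rates", "warp_to_licks", "lick_rates",
    "event_rate_tensor",
]


@dataclass
class RateTensor:
    """neurons x trials x bins sliding-window rates (Hz) for one epoch."""

    epoch: EpochSpec
    rates: np.ndarray            # (n_neurons, n_trials, n_bins)
    neuron_ids: np.ndarray
    trial_ids: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return self.epoch.bin_centers

    def __post_init__(self) -> None:
        n, t, b = self.rates.shape
        if b != self.epoch.n_bins:
            raise ValueError("tensor bin count disagrees with epoch spec")
        if n != len(self.neuron_ids) or t != len(self.trial_ids):
            raise ValueError("tensor axes disagree with id vectors")

    def select_trials(self, mask: np.ndarray) -> "RateTensor":
        mask = np.asarray(mask, dtype=bool)
        return RateTensor(self.epoch, self.rates[:, mask, :],
                          self.neuron_ids, self.trial_ids[mask])


@dataclass
class SmoothedRates:
    """Per-neuron, per-condition mean rates (Hz) on a 1 ms grid."""

    t_grid: np.ndarray                      # ms relative to alignment
    rates: np.ndarray                       # (n_neurons, n_conditions, n_t)
    neuron_ids: np.ndarray
    conditions: list
    sigma_ms: float = 20.0


def _count_windows(event_ts: np.ndarray, starts: np.ndarray, w: float) -> np.ndarray:
    """Counts of sorted events in half-open windows [start, start + w)."""
    lo = np.searchsorted(event_ts, starts, side="left")
    hi = np.searchsorted(event_ts, starts + w, side="left")
    return (hi - lo).astype(float)


def event_rate_tensor(event_trains: Sequence[np.ndarray], trials: Sequence[Trial],
                      epoch: EpochSpec, neuron_ids: Sequence[int],
                      align_times: Sequence[float] | None = None) -> RateTensor:
    """Shared counting kernel for spikes and licks.

    ``event_trains``: one sorted time array per row (neuron, or a single lick
    channel).  Rates are counts in [align + t_start + b*s, ... + w) scaled by
    1000/w.
    """
    starts = epoch.window_starts
    n_rows, n_trials, n_bins = len(event_trains), len(trials), epoch.n_bins
    rates = np.zeros((n_rows, n_trials, n_bins))
    if align_times is None:
        align_times = [t.align_time(epoch.align_event) for t in trials]
    for j, (trial, t0) in enumerate(zip(trials, align_times)):
        win = t0 + starts
        for i, ts in enumerate(event_trains):
            rates[i, j, :] = _count_windows(ts, win, epoch.w)
    rates *= 1000.0 / epoch.w
    return RateTensor(epoch=epoch, rates=rates,
                      neuron_ids=np.asarray(neuron_ids),
                      trial_ids=np.asarray([t.trial_id for t in trials]))


def _retain_trials(session: Session, epoch: EpochSpec,
                   trial_filter: Callable[[Trial], bool] | None) -> list[Trial]:
    retained = []
    for t in session.trials:
        if trial_filter is not None and not trial_filter(t):
            continue
        if epoch.align_event == "feedback_t" and t.aborted:
            logger.info("trial %d excluded: no feedback event", t.trial_id)
            continue
        retained.append(t)
    return retained


def sliding_rates(session: Session, epoch: EpochSpec,
                  trial_filter: Callable[[Trial], bool] | None = None,
                  ) -> RateTensor:
    """Sliding-window firing rates for every neuron and retained trial."""
    trials = _retain_trials(session, epoch, trial_filter)
    return event_rate_tensor([st.spike_ts for st in session.spike_trains],
                             trials, epoch,
                             [st.neuron_id for st in session.spike_trains])


def lick_rates(session: Session, epoch: EpochSpec,
               trial_filter: Callable[[Trial], bool] | None = None,
               ) -> RateTensor:
    """Lick rate in the same sliding windows, licks treated as events.

    Produces a single-row tensor (one lick channel per session); all central
    and lateral licks of each trial contribute.
    """
    trials = _retain_trials(session, epoch, trial_filter)
    trains = [np.sort(np.asarray(t.central_lick_ts + t.lateral_lick_ts, float))
              for t in trials]
    starts = epoch.window_starts
    rates = np.zeros((1, len(trials), epoch.n_bins))
    for j, t in enumerate(trials):
        t0 = t.align_time(epoch.align_event)
        rates[0, j, :] = _count_windows(trains[j], t0 + starts, epoch.w)
    rates *= 1000.0 / epoch.w
    return RateTensor(epoch=epoch, rates=rates, neuron_ids=np.asarray([0]),
                      trial_ids=np.asarray([t.trial_id for t in trials]))


def kernel_rates(session: Session, align_event: str,
                 t_range: tuple[float, float],
                 condition_map: Mapping[int, object] | Callable[[Trial], object],
                 min_trials: int = 2, sigma_ms: float = 20.0) -> SmoothedRates:
    """Condition-averaged, Gaussian-smoothed rates on a 1 ms grid.

    ``condition_map`` maps a trial (or its id) to a condition label; trials
    mapping to None are dropped.  Neurons are shared across conditions here,
    so a neuron is excluded when any condition has fewer than ``min_trials``
    trials (the whole population shares trials within a session, so the
    exclusion is effectively a condition check).

    rate(t) = mean over the condition's trials of
    sum_spikes N(t - t_spike; sigma) * 1000, a kernel-density estimate scaled
    to Hz that conserves one unit of mass per spike away from epoch edges.
    """
    if callable(condition_map):
        cond_of = condition_map
    else:
        cond_of = lambda tr: condition_map.get(tr.trial_id)  # noqa: E731

    by_cond: dict[object, list[Trial]] = {}
    for tr in session.trials:
        c = cond_of(tr)
        if c is None:
            continue
        if align_event == "feedback_t" and tr.aborted:
            continue
        by_cond.setdefault(c, []).append(tr)

    conditions = sorted(by_cond, key=str)
    small = [c for c in conditions if len(by_cond[c]) < min_trials]
    if small:
        logger.info("conditions below min_trials=%d: %s", min_trials, small)

    t_grid = np.arange(t_range[0], t_range[1] + 1.0, 1.0)
    n_neurons = session.n_neurons
    out = np.zeros((n_neurons, len(conditions), t_grid.size))
    denom = sigma_ms * np.sqrt(2 * np.pi)
    pad = 5 * sigma_ms
    for i, st in enumerate(session.spike_trains):
        for j, c in enumerate(conditions):
            trials = by_cond[c]
            acc = np.zeros_like(t_grid)
            for tr in trials:
                t0 = tr.align_time(align_event)
                rel = st.spike_ts[(st.spike_ts >= t0 + t_range[0] - pad)
                                  & (st.spike_ts <= t0 + t_range[1] + pad)] - t0
                for s in rel:
                    acc += np.exp(-0.5 * ((t_grid - s) / sigma_ms) ** 2)
            out[i, j] = acc / denom * 1000.0 / max(len(trials), 1)
    return SmoothedRates(t_grid=t_grid, rates=out,
                         neuron_ids=np.asarray([st.neuron_id
                                                for st in session.spike_trains]),
                         conditions=conditions, sigma_ms=sigma_ms)


def warp_to_licks(spike_ts: np.ndarray, lick_ts: np.ndarray,
                  target_ili: float = 140.0) -> np.ndarray:
    """Warp spike times so every inter-lick interval lasts ``target_ili`` ms.

    Piecewise-linear: lick k maps to k * target_ili; a spike a fraction f
    through interval k maps to (k + f) * target_ili.  Spikes outside
    [first lick, last lick] are discarded — extrapolated time has no
    behavioral meaning.
    """
    lick_ts = np.sort(np.asarray(lick_ts, dtype=float))
    if lick_ts.size < 2:
        raise ValueError("warping needs at least two licks")
    spike_ts = np.asarray(spike_ts, dtype=float)
    inside = (spike_ts >= lick_ts[0]) & (spike_ts <= lick_ts[-1])
    nodes = target_ili * np.arange(lick_ts.size)
    return np.interp(spike_ts[inside], lick_ts, nodes)
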