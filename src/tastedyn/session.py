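"""Data model for a water-vs-sucrose categorization session.

A session couples a trials table (stimulus concentration, choice, outcome,
event timestamps), per-neuron spike-time lists and per-trial lick trains on
one shared millisecond clock.  Analysis epochs (stimulus, choice, outcome)
are defined relative to a per-trial alignment event and discretized with
overlapping sliding windows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

CONCENTRATIONS = (0.0, 0.5, 1.3, 3.2, 7.9, 20.0)
SUCROSE_CONCENTRATIONS = CONCENTRATIONS[1:]

WATER = "water"
SUCROSE = "sucrose"
CORRECT = "correct"
INCORRECT = "incorrect"

REGIONS = ("aIC", "OFC")


class SessionValidationError(ValueError):
    """A trial or spike train violates a session invariant."""


@dataclass(frozen=True)
class Stimulus:
    """One of six sucrose concentrations (%w/v); 0 is the water category."""

    concentration: float

    def __post_init__(self) -> None:
        if not any(math.isclose(self.concentration, c) for c in CONCENTRATIONS):
            raise SessionValidationError(
                f"concentration {self.concentration} not in {CONCENTRATIONS}"
            )

    @property
    def category(self) -> str:
        return WATER if self.concentration == 0 else SUCROSE


@dataclass
class Trial:
    """A single categorization trial with its behavioral event times (ms).

    Feedback time is the second lick on the chosen lateral spout: the moment
    reward is delivered (correct) or omitted (incorrect).
    """

    trial_id: int
    stimulus: Stimulus
    choice: str
    outcome: str
    rewarded: bool
    stimulus_delivery_t: float
    central_lick_ts: list[float]
    lateral_lick_ts: list[float]

    @property
    def last_central_lick_t(self) -> float:
        return max(self.central_lick_ts)

    @property
    def feedback_t(self) -> float:
        if len(self.lateral_lick_ts) < 2:
            raise SessionValidationError(
                f"trial {self.trial_id}: feedback undefined with "
                f"{len(self.lateral_lick_ts)} lateral licks"
            )
        return sorted(self.lateral_lick_ts)[1]

    @property
    def aborted(self) -> bool:
        """Early abort: fewer than two lateral licks, so no feedback event."""
        return len(self.lateral_lick_ts) < 2

    def align_time(self, event: str) -> float:
        if event == "stimulus_delivery_t":
            return self.stimulus_delivery_t
        if event == "last_central_lick_t":
            return self.last_central_lick_t
        if event == "feedback_t":
            return self.feedback_t
        raise ValueError(f"unknown alignment event {event!r}")

    def validate(self) -> None:
        tid = self.trial_id
        if self.choice not in (WATER, SUCROSE):
            raise SessionValidationError(f"trial {tid}: bad choice {self.choice!r}")
        if self.outcome not in (CORRECT, INCORRECT):
            raise SessionValidationError(f"trial {tid}: bad outcome {self.outcome!r}")
        expected = CORRECT if self.choice == self.stimulus.category else INCORRECT
        if self.outcome != expected:
            raise SessionValidationError(
                f"trial {tid}: outcome {self.outcome!r} inconsistent with "
                f"choice {self.choice!r} and stimulus category "
                f"{self.stimulus.category!r}"
            )
        if self.rewarded != (self.outcome == CORRECT):
            raise SessionValidationError(
                f"trial {tid}: rewarded={self.rewarded} inconsistent with "
                f"outcome {self.outcome!r}"
            )
        if len(self.central_lick_ts) < 2:
            raise SessionValidationError(
                f"trial {tid}: needs >=2 central licks, got {len(self.central_lick_ts)}"
            )
        if self.lateral_lick_ts:
            first_lateral = min(self.lateral_lick_ts)
            if not (self.stimulus_delivery_t < self.last_central_lick_t <= first_lateral):
                raise SessionValidationError(
                    f"trial {tid}: event order violated "
                    f"(stimulus {self.stimulus_delivery_t}, last central "
                    f"{self.last_central_lick_t}, first lateral {first_lateral})"
                )
            if not self.aborted and not first_lateral < self.feedback_t:
                raise SessionValidationError(
                    f"trial {tid}: feedback must follow the first lateral lick"
                )


@dataclass
class SpikeTrain:
    """Spike times (ms, session clock) of one neuron, sorted ascending."""

    neuron_id: int
    region: str
    spike_ts: np.ndarray

    def __post_init__(self) -> None:
        self.spike_ts = np.asarray(self.spike_ts, dtype=float)
        if self.spike_ts.size and np.any(np.diff(self.spike_ts) < 0):
            raise SessionValidationError(
                f"neuron {self.neuron_id}: spike times not sorted"
            )
        if self.spike_ts.size and self.spike_ts[0] < 0:
            raise SessionValidationError(
                f"neuron {self.neuron_id}: negative spike time"
            )


@dataclass
class Session:
    session_id: str
    region: str
    trials: list[Trial]
    spike_trains: list[SpikeTrain]
    rat_id: str = ""
    seed: int | None = None
    notes: str = ""

    def validate(self) -> "Session":
        for t in self.trials:
            t.validate()
        return self

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_neurons(self) -> int:
        return len(self.spike_trains)

    def trial_table(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                dict(
                    trial_id=t.trial_id,
                    concentration=t.stimulus.concentration,
                    category=t.stimulus.category,
                    choice=t.choice,
                    outcome=t.outcome,
                    rewarded=t.rewarded,
                    aborted=t.aborted,
                    stimulus_delivery_t=t.stimulus_delivery_t,
                    last_central_lick_t=t.last_central_lick_t,
                    feedback_t=(np.nan if t.aborted else t.feedback_t),
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "trial_id", "concentration", "category", "choice", "outcome",
                "rewarded", "aborted", "stimulus_delivery_t",
                "last_central_lick_t", "feedback_t",
            ],
        )


@dataclass(frozen=True)
class EpochSpec:
    """A sliding-window discretization of a trial epoch.

    Windows are half-open ``[t0, t0 + w)`` and timestamped at their center.
    ``t_start``/``t_end`` are ms relative to the alignment event.
    """

    name: str
    align_event: str
    t_start: float
    t_end: float
    w: float = 100.0
    s: float = 10.0

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")
        if self.w <= 0 or self.s <= 0:
            raise ValueError("window and step must be positive")
        if self.n_bins < 1:
            raise ValueError("epoch shorter than one window")

    @property
    def n_bins(self) -> int:
        return int(math.floor((self.t_end - self.t_start - self.w) / self.s)) + 1

    @property
    def window_starts(self) -> np.ndarray:
        return self.t_start + self.s * np.arange(self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.window_starts + self.w / 2.0


_EPOCH_DEFAULTS = {
    "stimulus": ("stimulus_delivery_t", -400.0, 800.0),
    "choice": ("last_central_lick_t", -300.0, 800.0),
    "outcome": ("feedback_t", -300.0, 800.0),
}


def epoch_defaults(name: str) -> EpochSpec:
    """Default analysis epoch for a task variable.

    stimulus: [-400, 800] ms around stimulus delivery; choice: [-300, 800] ms
    around the last central-spout lick; outcome: [-300, 800] ms around
    feedback.  All use 100 ms windows sliding in 10 ms steps.
    """
    try:
        align, t0, t1 = _EPOCH_DEFAULTS[name]
    except KeyError:
        raise ValueError(f"unknown epoch {name!r}; expected one of "
                         f"{sorted(_EPOCH_DEFAULTS)}") from None
    return EpochSpec(name=name, align_event=align, t_start=t0, t_end=t1)


# ---------------------------------------------------------------------------
# on-disk layout: session.json + trials.tsv + spikes.tsv + licks.tsv
# ---------------------------------------------------------------------------

# lateral spout convention: water choice -> left spout, sucrose choice -> right
_CHOICE_SPOUT = {WATER: "left", SUCROSE: "right"}
_SPOUT_CHOICE = {v: k for k, v in _CHOICE_SPOUT.items()}


def write_session(session: Session, path: str | Path) -> None:
    """Write a session to ``path`` as tab-delimited text plus session.json.

    File content is deterministic for a fixed session (stable row order,
    fixed float formatting).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    trials = sorted(session.trials, key=lambda t: t.trial_id)
    trows, lrows = [], []
    for t in trials:
        trows.append(dict(
            trial_id=t.trial_id,
            concentration=t.stimulus.concentration,
            choice=t.choice,
            outcome=t.outcome,
            rewarded=t.rewarded,
            stimulus_delivery_t=t.stimulus_delivery_t,
            last_central_lick_t=t.last_central_lick_t,
            feedback_t=(np.nan if t.aborted else t.feedback_t),
        ))
        for lt in sorted(t.central_lick_ts):
            lrows.append(dict(trial_id=t.trial_id, spout="central", lick_t=lt))
        for lt in sorted(t.lateral_lick_ts):
            lrows.append(dict(trial_id=t.trial_id,
                              spout=_CHOICE_SPOUT[t.choice], lick_t=lt))

    tcols = ["trial_id", "concentration", "choice", "outcome", "rewarded",
             "stimulus_delivery_t", "last_central_lick_t", "feedback_t"]
    pd.DataFrame(trows, columns=tcols).to_csv(
        path / "trials.tsv", sep="\t", index=False, float_format="%.10g")

    pd.DataFrame(lrows, columns=["trial_id", "spout", "lick_t"]).to_csv(
        path / "licks.tsv", sep="\t", index=False, float_format="%.10g")

    srows = []
    for st in sorted(session.spike_trains, key=lambda s: s.neuron_id):
        for ts in st.spike_ts:
            srows.append(dict(neuron_id=st.neuron_id, region=st.region, spike_t=ts))
    pd.DataFrame(srows, columns=["neuron_id", "region", "spike_t"]).to_csv(
        path / "spikes.tsv", sep="\t", index=False, float_format="%.10g")

    meta = dict(session_id=session.session_id, region=session.region,
                rat_id=session.rat_id, seed=session.seed, notes=session.notes)
    (path / "session.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_session(path: str | Path) -> Session:
    """Load and validate a session from its on-disk TSV/JSON layout."""
    path = Path(path)
    for fname in ("session.json", "trials.tsv", "spikes.tsv", "licks.tsv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing session file: {path / fname}")

    meta = json.loads((path / "session.json").read_text())
    trials_df = pd.read_csv(path / "trials.tsv", sep="\t")
    licks_df = pd.read_csv(path / "licks.tsv", sep="\t")
    spikes_df = pd.read_csv(path / "spikes.tsv", sep="\t")

    licks_by_trial = dict(tuple(licks_df.groupby("trial_id")))
    trials: list[Trial] = []
    for row in trials_df.itertuples(index=False):
        lk = licks_by_trial.get(row.trial_id)
        central = (sorted(lk.loc[lk.spout == "central", "lick_t"])
                   if lk is not None else [])
        lateral = (sorted(lk.loc[lk.spout != "central", "lick_t"])
                   if lk is not None else [])
        trial = Trial(
            trial_id=int(row.trial_id),
            stimulus=Stimulus(float(row.concentration)),
            choice=str(row.choice),
            outcome=str(row.outcome),
            rewarded=bool(row.rewarded),
            stimulus_delivery_t=float(row.stimulus_delivery_t),
            central_lick_ts=[float(x) for x in central],
            lateral_lick_ts=[float(x) for x in lateral],
        )
        trial.validate()
        # cross-check the stored redundant columns against the lick trains
        if not math.isclose(trial.last_central_lick_t,
                            float(row.last_central_lick_t), abs_tol=1e-6):
            raise SessionValidationError(
                f"trial {trial.trial_id}: last_central_lick_t column disagrees "
                f"with licks.tsv")
        if not trial.aborted and not math.isclose(
                trial.feedback_t, float(row.feedback_t), abs_tol=1e-6):
            raise SessionValidationError(
                f"trial {trial.trial_id}: feedback_t column disagrees with "
                f"licks.tsv (feedback is the second lateral lick)")
        trials.append(trial)

    spike_trains = [
        SpikeTrain(neuron_id=int(nid),
                   region=str(grp["region"].iloc[0]),
                   spike_ts=np.sort(grp["spike_t"].to_numpy(float)))
        for nid, grp in spikes_df.groupby("neuron_id")
    ]

    return Session(
        session_id=str(meta.get("session_id", path.name)),
        region=str(meta.get("region", "")),
        trials=trials,
        spike_trains=spike_trains,
        rat_id=str(meta.get("rat_id", "")),
        seed=meta.get("seed"),
        notes=str(meta.get("notes", "")),
    ).validate()
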