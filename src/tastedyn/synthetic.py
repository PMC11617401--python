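"""Synthetic categorization sessions with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: six sucrose concentrations {0, 0.5, 1.3, 3.2, 7.9, 20 %w/v} with
half of the trials water; a clipped power-law psychometric choice rule
p(sucrose | c) = clip(a * c**b, eps, 1 - eps); rhythmic lick trains with
~140 ms inter-lick intervals; and inhomogeneous-Poisson neurons whose rate
carries a transient, condition-selective Gaussian bump at a neuron-specific
latency.  "Switching" neurons carry two opposite-preference bumps within the
same epoch.  Bump spikes are drawn by superposition: a homogeneous baseline
process plus a Poisson number of Gaussian-distributed bump spikes per
matching trial, which is exact for rates of the form
lambda0 + sum_bumps amp * exp(-(t - mu)^2 / (2 sigma^2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import (
    CONCENTRATIONS, SUCROSE_CONCENTRATIONS, CORRECT, INCORRECT, SUCROSE, WATER,
    Session, SpikeTrain, Stimulus, Trial,
)

__all__ = [
    "BehaviorConfig", "Bump", "NeuronSpec",
    "simulate_behavior", "simulate_spikes", "make_population",
    "psychometric_probability",
]

# variable -> (alignment event, opposite-condition map)
_VARIABLE_ALIGN = {
    "stimulus_category": "stimulus_delivery_t",
    "choice": "last_central_lick_t",
    "outcome": "feedback_t",
}
_OPPOSITE = {WATER: SUCROSE, SUCROSE: WATER, CORRECT: INCORRECT, INCORRECT: CORRECT}


@dataclass(frozen=True)
class BehaviorConfig:
    """Parameters of the simulated behavior.

    The psychometric defaults (a=0.59, b=0.16) put the 50% point of the
    power-law choice rule near 0.35 %w/v and its 20% value near 0.95,
    matching a rat that categorizes the extreme concentrations reliably but
    confuses near-threshold sucrose with water.  ``eps`` is both the lapse
    clip and the false-alarm rate at c=0.
    """

    n_trials: int = 200
    water_fraction: float = 0.5
    a: float = 0.59
    b: float = 0.16
    eps: float = 0.05
    ili_mean: float = 140.0
    ili_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.eps < 0.5:
            raise ValueError("eps must lie in [0, 0.5)")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("psychometric parameters must be positive")
        if self.ili_sd < 0:
            raise ValueError("ILI sd must be non-negative")


def psychometric_probability(c: float, config: BehaviorConfig) -> float:
    """Generative p(sucrose choice | concentration c), clipped power law."""
    if c == 0:
        return config.eps
    return float(np.clip(config.a * c ** config.b, config.eps, 1 - config.eps))


@dataclass(frozen=True)
class Bump:
    preferred: str          # condition value that drives the bump
    amplitude: float        # Hz added at bump center
    mu: float               # ms relative to the epoch alignment event
    sigma: float            # ms

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.sigma <= 0:
            raise ValueError("bump amplitude must be >=0 and sigma > 0")


@dataclass(frozen=True)
class NeuronSpec:
    """Rate model of one simulated neuron: baseline plus tuned bumps."""

    neuron_id: int
    baseline_hz: float
    tuned_variable: str = "none"    # stimulus_category | choice | outcome | none
    bumps: tuple[Bump, ...] = ()

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ValueError("baseline rate must be non-negative")
        if self.tuned_variable != "none" and self.tuned_variable not in _VARIABLE_ALIGN:
            raise ValueError(f"unknown tuned variable {self.tuned_variable!r}")
        if self.tuned_variable == "none" and self.bumps:
            raise ValueError("untuned neuron cannot carry bumps")

    @property
    def is_switching(self) -> bool:
        return len({b.preferred for b in self.bumps}) > 1


def _truncated_ilis(rng: np.random.Generator, n: int, mean: float, sd: float,
                    floor: float = 60.0) -> np.ndarray:
    ilis = rng.normal(mean, sd, size=n)
    return np.maximum(ilis, floor)


def simulate_behavior(config: BehaviorConfig) -> list[Trial]:
    """Simulate the trial sequence of one session.

    Stimulus: water with probability ``water_fraction``, otherwise uniform
    over the five sucrose concentrations.  Choice: Bernoulli from the clipped
    power law.  Event times: the stimulus is delivered at the first central
    lick of 2-3 rhythmic central licks; after a movement delay the rat emits
    >=4 lateral licks, and feedback (reward delivery or omission) is the
    second lateral lick.
    """
    rng = np.random.default_rng(config.seed)
    trials: list[Trial] = []
    t_clock = 1000.0
    for k in range(config.n_trials):
        if rng.random() < config.water_fraction:
            conc = 0.0
        else:
            conc = float(rng.choice(SUCROSE_CONCENTRATIONS))
        p_suc = psychometric_probability(conc, config)
        choice = SUCROSE if rng.random() < p_suc else WATER
        stim = Stimulus(conc)
        outcome = CORRECT if choice == stim.category else INCORRECT

        n_central = int(rng.integers(2, 4))
        central = t_clock + np.concatenate(
            ([0.0], np.cumsum(_truncated_ilis(rng, n_central - 1,
                                              config.ili_mean, config.ili_sd))))
        movement = max(100.0, rng.normal(320.0, 60.0))
        n_lateral = int(rng.integers(4, 7))
        lat0 = central[-1] + movement
        lateral = lat0 + np.concatenate(
            ([0.0], np.cumsum(_truncated_ilis(rng, n_lateral - 1,
                                              config.ili_mean, config.ili_sd))))
        # stimulus delivered at the first central lick; nudge delivery just
        # before the lick so event order is strict
        trials.append(Trial(
            trial_id=k,
            stimulus=stim,
            choice=choice,
            outcome=outcome,
            rewarded=outcome == CORRECT,
            stimulus_delivery_t=float(central[0]) - 1e-3,
            central_lick_ts=[float(x) for x in central],
            lateral_lick_ts=[float(x) for x in lateral],
        ))
        t_clock = float(lateral[-1]) + rng.uniform(2500.0, 3500.0)
    return trials


def _condition_value(trial: Trial, variable: str) -> str:
    if variable == "stimulus_category":
        return trial.stimulus.category
    if variable == "choice":
        return trial.choice
    if variable == "outcome":
        return trial.outcome
    raise ValueError(variable)


def simulate_spikes(trials: list[Trial], specs: list[NeuronSpec], seed: int,
                    region: str = "aIC") -> list[SpikeTrain]:
    """Draw inhomogeneous-Poisson spike trains for every neuron spec."""
    if not trials:
        raise ValueError("no trials to simulate")
    t_end = max(max(t.lateral_lick_ts) for t in trials) + 2000.0
    root = np.random.SeedSequence(seed)
    trains: list[SpikeTrain] = []
    for spec, ss in zip(specs, root.spawn(len(specs))):
        rng = np.random.default_rng(ss)
        n_base = rng.poisson(spec.baseline_hz * t_end / 1000.0)
        spikes = [rng.uniform(0.0, t_end, size=n_base)]
        if spec.tuned_variable != "none":
            align_event = _VARIABLE_ALIGN[spec.tuned_variable]
            for trial in trials:
                if align_event == "feedback_t" and trial.aborted:
                    continue
                cond = _condition_value(trial, spec.tuned_variable)
                t0 = trial.align_time(align_event)
                for bump in spec.bumps:
                    if bump.preferred != cond:
                        continue
                    # integral of amp * gaussian = amp/1000 * sigma * sqrt(2pi)
                    mean_count = bump.amplitude / 1000.0 * bump.sigma * math.sqrt(2 * math.pi)
                    n = rng.poisson(mean_count)
                    if n:
                        spikes.append(rng.normal(t0 + bump.mu, bump.sigma, size=n))
        ts = np.sort(np.concatenate(spikes))
        ts = ts[ts >= 0]
        trains.append(SpikeTrain(neuron_id=spec.neuron_id, region=region,
                                 spike_ts=ts))
    return trains


# ---------------------------------------------------------------------------
# population templates
# ---------------------------------------------------------------------------

def _mixed_specs(rng: np.random.Generator) -> list[NeuronSpec]:
    """encoders_mixed manifest: 15 stimulus-, 20 choice- (4 switching),
    30 outcome-tuned and 35 untuned neurons, bump centers tiling [0, 700] ms
    of each variable's epoch."""
    specs: list[NeuronSpec] = []
    nid = 0

    def baseline() -> float:
        return float(rng.uniform(2.0, 8.0))

    for mu in np.linspace(40.0, 700.0, 15):
        pref = SUCROSE if nid % 2 == 0 else WATER
        specs.append(NeuronSpec(nid, baseline(), "stimulus_category",
                                (Bump(pref, 22.0, float(mu), 55.0),)))
        nid += 1
    for i, mu in enumerate(np.linspace(40.0, 700.0, 20)):
        pref = SUCROSE if i % 2 == 0 else WATER
        if i < 4:  # switching: opposite-preference second bump later in epoch
            bumps = (Bump(pref, 22.0, float(mu), 50.0),
                     Bump(_OPPOSITE[pref], 22.0, float(mu) + 280.0, 50.0))
        else:
            bumps = (Bump(pref, 22.0, float(mu), 55.0),)
        specs.append(NeuronSpec(nid, baseline(), "choice", bumps))
        nid += 1
    for i, mu in enumerate(np.linspace(40.0, 700.0, 30)):
        pref = CORRECT if i % 2 == 0 else INCORRECT
        specs.append(NeuronSpec(nid, baseline(), "outcome",
                                (Bump(pref, 22.0, float(mu), 55.0),)))
        nid += 1
    for _ in range(35):
        specs.append(NeuronSpec(nid, baseline()))
        nid += 1
    return specs


def make_population(template: str, seed: int, n_trials: int | None = None,
                    region: str = "aIC",
                    behavior: BehaviorConfig | None = None,
                    ) -> tuple[Session, pd.DataFrame]:
    """Build a synthetic session from a named template.

    Templates: ``null`` (50 untuned neurons), ``perfect_sequence`` (20
    sucrose-preferring neurons with narrow, non-overlapping bumps uniformly
    spaced over [0, 800] ms) and ``encoders_mixed`` (100 neurons with known
    tuned counts; see the manifest in the returned ground-truth table).

    Returns the session and a per-neuron ground-truth table
    (neuron_id, tuned_variable, preferred, mu_ms, switch).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA5)))
    if template == "null":
        specs = [NeuronSpec(i, float(rng.uniform(1.0, 8.0))) for i in range(50)]
        default_trials = 200
    elif template == "perfect_sequence":
        specs = [
            NeuronSpec(i, 0.5, "stimulus_category",
                       (Bump(SUCROSE, 45.0, float(mu), 15.0),))
            for i, mu in enumerate(np.linspace(0.0, 800.0, 20))
        ]
        default_trials = 200
    elif template == "encoders_mixed":
        specs = _mixed_specs(rng)
        default_trials = 200
    else:
        raise ValueError(f"unknown template {template!r}")

    if behavior is None:
        behavior = BehaviorConfig(n_trials=n_trials or default_trials, seed=seed)
    trials = simulate_behavior(behavior)
    trains = simulate_spikes(trials, specs, seed=seed + 1, region=region)

    truth = pd.DataFrame([
        dict(neuron_id=s.neuron_id,
             tuned_variable=s.tuned_variable,
             preferred=(s.bumps[0].preferred if s.bumps else ""),
             mu_ms=(s.bumps[0].mu if s.bumps else np.nan),
             switch=s.is_switching)
        for s in specs
    ])
    session = Session(
        session_id=f"synthetic-{template}-{seed}", region=region,
        trials=trials, spike_trains=trains,
        rat_id="synthetic", seed=seed,
        notes=f"template={template}",
    ).validate()
    return session, truth
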