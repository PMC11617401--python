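"""Psychometric power-law fits and single-neuron neurometric curves.

Behavior is summarized by the probability of a "sucrose" report at each
concentration; a power function f(x) = a * x**b is fitted to the positive
concentrations (x = 0 is excluded: 0**b is degenerate) and the *absolute
threshold* is the concentration where the fit crosses 0.5,
x* = (0.5 / a)**(1/b).  A neuron's neurometric curve classifies each trial
as a water or sucrose response by whether its rate in the best encoding
window crosses the firing-rate threshold that maximizes correct
classification; the per-concentration fraction of "sucrose" classifications
is then directly comparable to the animal's psychometric curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .session import CONCENTRATIONS, SUCROSE, Session

__all__ = [
    "PsychometricFit", "NeurometricCurve",
    "fit_power_psychometric", "empirical_psychometric", "optimal_threshold",
    "neurometric_curve",
]


@dataclass(frozen=True)
class PsychometricFit:
    a: float
    b: float
    r2: float

    @property
    def threshold(self) -> float:
        """Concentration with fitted p = 0.5 (absolute threshold)."""
        return float((0.5 / self.a) ** (1.0 / self.b))

    def __call__(self, x):
        return self.a * np.asarray(x, dtype=float) ** self.b


@dataclass(frozen=True)
class NeurometricCurve:
    concentrations: np.ndarray
    p_sucrose: np.ndarray           # NaN where a concentration had no trials
    threshold_hz: float
    direction: str                  # high_sucrose | low_sucrose
    accuracy: float


def fit_power_psychometric(concentrations: np.ndarray,
                           p_sucrose: np.ndarray) -> PsychometricFit:
    """Least-squares power-law fit in linear probability space.

    Requires at least two positive concentrations with unequal
    probabilities; the initial guess comes from a log-log regression.
    """
    x = np.asarray(concentrations, dtype=float)
    p = np.asarray(p_sucrose, dtype=float)
    pos = x > 0
    x, p = x[pos], p[pos]
    if x.size < 2:
        raise ValueError("need >=2 positive concentrations")
    if np.ptp(p) == 0:
        raise ValueError("all probabilities equal: exponent unidentifiable")

    safe = p > 0
    if safe.sum() >= 2:
        slope, intercept = np.polyfit(np.log(x[safe]), np.log(p[safe]), 1)
        p0 = (float(np.exp(intercept)), float(max(slope, 1e-3)))
    else:
        p0 = (0.5, 0.2)
    popt, _ = curve_fit(lambda xx, a, b: a * xx**b, x, p, p0=p0,
                        maxfev=20_000)
    a, b = float(popt[0]), float(popt[1])
    resid = p - a * x**b
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((p - p.mean())**2))
    r2 = 1.0 - ss_res / ss_tot
    return PsychometricFit(a=a, b=b, r2=r2)


def empirical_psychometric(session: Session) -> pd.DataFrame:
    """Per-concentration fraction of sucrose responses for one session."""
    tt = session.trial_table()
    rows = []
    for c in CONCENTRATIONS:
        sub = tt[tt["concentration"] == c]
        rows.append(dict(concentration=c, n_trials=len(sub),
                         p_sucrose=(np.nan if len(sub) == 0 else
                                    float((sub["choice"] == SUCROSE).mean()))))
    return pd.DataFrame(rows)


def optimal_threshold(rates: np.ndarray, labels: np.ndarray,
                      ) -> tuple[float, str, float]:
    """Firing-rate threshold maximizing correct classification.

    Exhaustive search over midpoints of adjacent sorted unique rates plus
    the +/-inf endpoints (the one-class classifiers), in both directions
    (high rates -> sucrose, or low rates -> sucrose).  Ties resolve to the
    smallest threshold and the high_sucrose direction.  Returns
    (threshold, direction, accuracy).
    """
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray(labels, dtype=bool)     # True = sucrose
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(rates)
    cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0
                            if uniq.size > 1 else [], [np.inf]))
    best_acc, best_theta, best_dir = -1.0, np.inf, ""
    n = labels.size
    # thetas ascend and high_sucrose precedes low_sucrose, so with a strict
    # comparison the first maximizer realizes the documented tie-break
    for theta in cands:
        high = rates > theta
        for direction, pred in (("high_sucrose", high), ("low_sucrose", ~high)):
            acc = float((pred == labels).sum()) / n
            if acc > best_acc + 1e-12:
                best_acc, best_theta, best_dir = acc, theta, direction
    return float(best_theta), best_dir, float(best_acc)


def neurometric_curve(window_rates: np.ndarray, trials_conc: np.ndarray,
                      choice_is_sucrose: np.ndarray) -> NeurometricCurve:
    """Neurometric curve of one neuron from its best-window trial rates.

    The optimal threshold is derived from the rates against the animal's
    responses; each trial is then classified by the threshold, and the
    fraction classified "sucrose" is reported per concentration (NaN where
    a concentration had no trials).
    """
    window_rates = np.asarray(window_rates, dtype=float)
    trials_conc = np.asarray(trials_conc, dtype=float)
    theta, direction, acc = optimal_threshold(window_rates, choice_is_sucrose)
    pred = window_rates > theta if direction == "high_sucrose" else ~(window_rates > theta)
    p = []
    for c in CONCENTRATIONS:
        m = trials_conc == c
        p.append(float(pred[m].mean()) if m.any() else np.nan)
    return NeurometricCurve(concentrations=np.asarray(CONCENTRATIONS),
                            p_sucrose=np.asarray(p), threshold_hz=theta,
                            direction=direction, accuracy=acc)
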