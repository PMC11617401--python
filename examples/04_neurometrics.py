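"""Psychometric fit and a single neuron's neurometric curve.

Fits the power-law psychometric p(sucrose) = a * c**b to a simulated
session, reports the absolute threshold (the concentration at p = 0.5),
and builds the neurometric curve of a choice-locked neuron via its optimal
firing-rate threshold.
"""

import numpy as np

from tastedyn import (BehaviorConfig, empirical_psychometric,
                      fit_power_psychometric, neurometric_curve,
                      simulate_behavior)
from tastedyn.session import Session

trials = simulate_behavior(BehaviorConfig(n_trials=2000, seed=0))
session = Session("demo", "aIC", trials, [])
emp = empirical_psychometric(session)
print(emp.to_string(index=False))

fit = fit_power_psychometric(emp["concentration"].to_numpy(),
                             emp["p_sucrose"].to_numpy())
print(f"\npower fit: a={fit.a:.3f}, b={fit.b:.3f}, R^2={fit.r2:.3f}")
print(f"absolute threshold (p=0.5): {fit.threshold:.2f} %w/v")

# a neuron whose rate follows the animal's choice reproduces the
# psychometric curve exactly through its optimal threshold classifier
choice = np.array([t.choice == "sucrose" for t in trials])
conc = np.array([t.stimulus.concentration for t in trials])
rng = np.random.default_rng(0)
rates = np.where(choice, rng.normal(18, 2, choice.size),
                 rng.normal(4, 2, choice.size))
curve = neurometric_curve(rates, conc, choice)
print(f"\nneurometric threshold {curve.threshold_hz:.1f} Hz "
      f"({curve.direction}), classification accuracy {curve.accuracy:.3f}")
print("p(classified sucrose) per concentration:",
      np.round(curve.p_sucrose, 3))
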