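import numpy as np
import pytest

from tastedyn import make_population
from tastedyn.session import Session, SpikeTrain, Stimulus, Trial


def toy_trial(trial_id=0, conc=0.0, choice="water", t0=1000.0,
              n_lateral=4) -> Trial:
    outcome = "correct" if ((conc == 0) == (choice == "water")) else "incorrect"
    central = [t0, t0 + 140.0, t0 + 280.0]
    lateral = [t0 + 600.0 + 140.0 * k for k in range(n_lateral)]
    return Trial(trial_id=trial_id, stimulus=Stimulus(conc), choice=choice,
                 outcome=outcome, rewarded=outcome == "correct",
                 stimulus_delivery_t=t0 - 1.0, central_lick_ts=central,
                 lateral_lick_ts=lateral)


@pytest.fixture
def toy_session() -> Session:
    trials = [
        toy_trial(0, 0.0, "water", 1000.0),
        toy_trial(1, 20.0, "sucrose", 5000.0),
        toy_trial(2, 1.3, "water", 9000.0),
    ]
    trains = [
        SpikeTrain(0, "aIC", np.array([1010.0, 1055.0, 1090.0, 5200.0])),
        SpikeTrain(1, "aIC", np.array([])),
    ]
    return Session(session_id="toy", region="aIC", trials=trials,
                   spike_trains=trains, rat_id="r0").validate()


@pytest.fixture(scope="session")
def mixed_population():
    return make_population("encoders_mixed", seed=11)


@pytest.fixture(scope="session")
def sequence_population():
    return make_population("perfect_sequence", seed=11)
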