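import numpy as np
import pandas as pd
import pytest

import omapop as op
from omapop.synthetic import UnitSpec, generate_control_dataset, make_population


@pytest.fixture(scope="session")
def mixed_session():
    """Small main session with one unit of several generative classes."""
    pop = op.make_population(
        {"multiplicative_stable": 3, "additive": 2, "mixed_unstable": 2,
         "format_only": 1, "untuned": 2},
        seed=11,
    )
    rec = op.generate_main_dataset(pop, seed=101)
    return rec


@pytest.fixture(scope="session")
def mult_session():
    """Main session of purely multiplicative, rank-stable units."""
    pop = make_population({"multiplicative_stable": 12}, seed=21)
    return op.generate_main_dataset(pop, seed=201)


@pytest.fixture(scope="session")
def mixed_unstable_session():
    pop = make_population({"mixed_unstable": 12}, seed=31)
    return op.generate_main_dataset(pop, seed=301)


@pytest.fixture(scope="session")
def control_session():
    pop = make_population({"motion_coupled": 3, "untuned": 3}, seed=41)
    rec, cov = generate_control_dataset(pop, seed=401)
    return rec, cov


@pytest.fixture()
def single_spike_recording():
    """One unit, one trial, one spike at t = 0.05 s."""
    units = pd.DataFrame({"unit_id": ["u0"], "isolation": ["single"]})
    trials = pd.DataFrame(
        {
            "trial_id": [0], "exemplar": ["drag"], "format": ["stand_lateral"],
            "posture": ["standing"], "viewpoint": ["lateral"], "actor": ["m"],
            "object": ["a"], "repetition": [1],
        }
    )
    spikes = pd.DataFrame({"unit_id": ["u0"], "trial_id": [0], "time_s": [0.05]})
    return op.RecordingSet(units=units, trials=trials, spikes=spikes)


def trial_rates_for_unit(rec, unit_id, window=(0.3, 1.5)):
    """Per-trial epoch rates of one unit joined with condition labels."""
    er = op.epoch_rates(rec, {"w": window})
    df = er[er.unit_id == unit_id].merge(
        rec.trials[["trial_id", "format", "exemplar"]], on="trial_id"
    )
    return df
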