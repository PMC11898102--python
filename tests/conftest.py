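import numpy as np
import pytest

from thresholdgame import GameConfig, ThresholdBelief, generate_experiment


@pytest.fixture(scope="session")
def config():
    return GameConfig()


@pytest.fixture(scope="session")
def beliefs():
    """The four canonical threshold beliefs."""
    return {
        "certainty": ThresholdBelief.point(120.0),
        "uncertainty": ThresholdBelief.uniform(0.0, 240.0),
        "warning_wide": ThresholdBelief.uniform(84.0, 156.0),
        "warning_narrow": ThresholdBelief.uniform(108.0, 132.0),
    }


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded 4-treatment dataset with 5 groups per treatment."""
    return generate_experiment({t: 5 for t in
                                ("certainty", "uncertainty", "warning_wide", "warning_narrow")},
                               seed=123)


@pytest.fixture(scope="session")
def default_dataset():
    """The study-sized design: 10 groups in each of the four treatments."""
    return generate_experiment(seed=2024)
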