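import numpy as np
import pytest

from neuromux.coding import CodingClassifier
from neuromux.io import AnalysisConfig
from neuromux.synth import CodingProfile, SessionSpec, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact mixed session shared by mechanics-oriented tests.

    Small trial counts keep it fast; calibration-sensitive tests build their
    own sessions at the full study conditions.
    """
    profiles = [
        CodingProfile(kind="early_choice", effect_gain=12.0, baseline_rate=10.0),
        CodingProfile(kind="late_choice", effect_gain=12.0, baseline_rate=8.0),
        CodingProfile(kind="value_coder", effect_gain=12.0, baseline_rate=12.0),
        CodingProfile(kind="null", baseline_rate=10.0),
    ]
    spec = SessionSpec(n_trials_per_stimulus=30, neurons=profiles)
    trials, spikes = generate_session(spec, seed=42)
    return spec, trials, spikes


@pytest.fixture(scope="session")
def fitted_complex(small_session):
    _, trials, spikes = small_session
    return CodingClassifier(stim_class="complex", config=AnalysisConfig()).fit(trials, spikes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
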