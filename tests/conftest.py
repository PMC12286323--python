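import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nirsax.trial_io import Trial, TrialSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trial(
    trial_id="t1",
    participant_id="p1",
    chromophore="OxyHb",
    n_channels=3,
    n_samples=50,
    sas=9,
    mc_correct=True,
    fs=10.1725,
    rng=None,
    data=None,
):
    if data is None:
        rng = rng or np.random.default_rng(0)
        data = rng.standard_normal((n_channels, n_samples))
    return Trial(
        trial_id=trial_id,
        participant_id=participant_id,
        chromophore=chromophore,
        data=data,
        fs=fs,
        s1=2,
        s2=data.shape[1] - 2,
        sas=sas,
        mc_correct=mc_correct,
    )


@pytest.fixture
def small_set():
    rng = np.random.default_rng(7)
    trials = [
        make_trial(trial_id=f"t{i}", sas=s, mc_correct=m, rng=rng)
        for i, (s, m) in enumerate([(9, True), (3, False), (6, True), (2, True)])
    ]
    return TrialSet(trials)
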