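import dataclasses

import pytest

from exertvalue import cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded 58-participant cohort shared across read-only tests."""
    return cohort.make_cohort(58, seed=1)


@pytest.fixture()
def quiet_profile(default_cohort):
    """A TR-arm participant with all observation noise switched off."""
    prof = next(p for p in default_cohort if p.group == "TR")
    return dataclasses.replace(prof, rating_noise_sd=0.0, choice_noise=0.0)
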