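import pytest

from cogbattery import cohort, scoring


@pytest.fixture(scope="session")
def small_cohort():
    """8 participants, two days, all seven tasks; null day effect."""
    profiles = cohort.sample_cohort(8, seed=11)
    sessions = cohort.simulate_study(profiles, seed=12)
    return profiles, sessions


@pytest.fixture(scope="session")
def small_sessions(small_cohort):
    return small_cohort[1]


@pytest.fixture(scope="session")
def small_scores(small_sessions):
    return scoring.score_table(small_sessions)
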