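import pytest

from ldctbio.synthetic_data import PhantomConfig, RosterConfig, make_phantom, make_roster


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic thorax phantom shared across read-only tests."""
    return make_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def default_roster():
    """The default synthetic roster (printed stratum counts)."""
    return make_roster(RosterConfig(seed=123))


@pytest.fixture()
def small_roster_config():
    """A fast, small roster for pipeline-level tests."""
    return dict(
        survivor_stage_counts={"I": 60, "II": 20, "III": 12, "IV": 2},
        nonsurvivor_stage_counts={"I": 25, "II": 12, "III": 15, "IV": 4},
        survivor_missing_stage=2,
        unrelated_death_count=4,
        indeterminate_count=3,
        non_screen_detected_count=3,
    )
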