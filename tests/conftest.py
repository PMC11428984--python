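import pytest

from apsi import (
    SyntheticPanelConfig,
    default_battery,
    generate_panel,
    load_table3,
    tier_profile,
)


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def battery():
    return default_battery()


@pytest.fixture(scope="session")
def a6_profile():
    return tier_profile("A6")


@pytest.fixture(scope="session")
def fzb42_profile():
    return tier_profile("FZB42")


@pytest.fixture(scope="session")
def small_noisy_panel(fzb42_profile):
    """One mid-range candidate plus controls, modest noise."""
    cfg = SyntheticPanelConfig(
        strains={"X": fzb42_profile}, replicates=4, noise_cv=0.05, seed=11
    )
    return generate_panel(cfg)
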