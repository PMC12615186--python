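import pytest

from clampforge import wheat_panel
from clampforge.alignment_profile import MultipleAlignment, build_profile
from clampforge.clamp_design import PrimerPair
from clampforge.fixtures import FixtureSpec, simulate_panel


@pytest.fixture(scope="session")
def panel_seed1():
    """Default synthetic panel (320 bp host insertion) with ground truth."""
    return simulate_panel(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def recovery_panel_seed1():
    """Insertion-free panel: the planted site is the unique divergent optimum."""
    return simulate_panel(FixtureSpec(seed=1, insertion_length=0, locus_length=300))


@pytest.fixture(scope="session")
def profile_seed1(panel_seed1):
    records, _ = panel_seed1
    return build_profile(MultipleAlignment(tuple(records)))


@pytest.fixture(scope="session")
def v5v7_pair():
    return PrimerPair(wheat_panel.PRIMERS["799F"], wheat_panel.PRIMERS["1193R"])
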