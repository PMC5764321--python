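import pytest

from ctlscan import builtin_profiles, yeell_pattern


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def canonical(profiles):
    return profiles["canonical"]


@pytest.fixture(scope="session")
def yeell():
    return yeell_pattern()


#: a YEELL-consensus window with zero mismatches at constrained positions
EXACT_YEELL = "DAASYEELLALAEALGAVAAG"
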