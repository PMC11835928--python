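import pytest

from photorestrict import Conductances, load_fixture


@pytest.fixture(scope="session")
def healthy():
    return load_fixture("healthy")


@pytest.fixture(scope="session")
def treated():
    return load_fixture("treated")


@pytest.fixture(scope="session")
def healthy_g():
    """Operational conductances of the healthy plant as printed in the
    worked examples (g_s rounded to 0.063)."""
    return Conductances(g_s=0.063, g_m=0.35)


@pytest.fixture(scope="session")
def treated_g():
    return Conductances(g_s=0.055, g_m=0.25)
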