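import pytest

from neoscreen.epi import load_default_cases, load_default_yearly
from neoscreen.panel import load_default_panel
from neoscreen.variants import load_default_genotypes, load_default_variants


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def cases():
    return load_default_cases()


@pytest.fixture(scope="session")
def yearly():
    return load_default_yearly()


@pytest.fixture(scope="session")
def variant_records():
    return load_default_variants()


@pytest.fixture(scope="session")
def genotypes():
    return load_default_genotypes()


@pytest.fixture()
def midpoint_profile(panel):
    """Every analyte at the midpoint of its healthy reference interval."""
    return {i.abbr: (i.lower + i.upper) / 2 for i in panel.analytes}
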