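import numpy as np
import pytest

from pgxpop import (
    load_definitions,
    load_greek_frequencies,
    load_panel,
    load_rule_tables,
)


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def greek_freqs():
    return load_greek_frequencies()


@pytest.fixture(scope="session")
def definitions():
    return load_definitions()


@pytest.fixture(scope="session")
def rule_tables():
    return load_rule_tables("bundled")


@pytest.fixture(scope="session")
def greek_cohort_3011(panel, greek_freqs):
    """The default-seed synthetic study cohort used by the acceptance checks."""
    from pgxpop import sample_greek_style_cohort

    return sample_greek_style_cohort(greek_freqs, "Greek", 3011, 42, panel)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
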