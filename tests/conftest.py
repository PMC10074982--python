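import numpy as np
import pytest

from ctgml.cohort import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (no signals) for fast model/screen tests."""
    config = GeneratorConfig(n_asphyxia=15, n_non_asphyxia=150, seed=42)
    table, _ = generate_cohort(config, with_signals=False)
    return table


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort table (no signals)."""
    table, _ = generate_cohort(GeneratorConfig(seed=7), with_signals=False)
    return table
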