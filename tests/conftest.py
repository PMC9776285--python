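import numpy as np
import pytest

from renalnmp import (
    GeneratorConfig,
    derive_marker_table,
    simulate_cohort,
)

# small, fast study conditions for unit tests: 1 s hemodynamic sampling
# (the windowing operator is sampling-rate agnostic) and a reduced cohort
FAST = dict(dt_s=1.0)


@pytest.fixture(scope="session")
def fast_cfg():
    return GeneratorConfig(**FAST)


@pytest.fixture(scope="session")
def cohort(fast_cfg):
    """18-kidney cohort (4/6/8) for unit tests of the downstream stages."""
    return simulate_cohort((4, 6, 8), seed=11, params=fast_cfg)


@pytest.fixture(scope="session")
def tables(cohort):
    return [derive_marker_table(r) for r in cohort]


@pytest.fixture(scope="session")
def clean_cohort():
    """Fully observed cohort (no dropout) for missingness-sensitive tests."""
    cfg = GeneratorConfig(dt_s=1.0, panel_dropout=0.0,
                          panel_dropout_by_class=None)
    return simulate_cohort((3, 4, 5), seed=5, params=cfg)


@pytest.fixture(scope="session")
def clean_tables(clean_cohort):
    return [derive_marker_table(r) for r in clean_cohort]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
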