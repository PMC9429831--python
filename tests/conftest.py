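import numpy as np
import pytest

from apcmort import (
    SyntheticConfig,
    build_design,
    fit_intrinsic_estimator,
    generate_study_bundle,
)


@pytest.fixture(scope="session")
def study_design():
    """Design on the full study grid: ages 25-84, periods 1999-2018."""
    return build_design(np.arange(25, 85), np.arange(1999, 2019))


@pytest.fixture(scope="session")
def small_grid():
    """A fast 10-age x 8-period grid for oracle-equivalence tests."""
    cfg = SyntheticConfig(ages=(60, 69), periods=(2000, 2007),
                          population_per_cell=1e6)
    return generate_study_bundle(cfg)


@pytest.fixture(scope="session")
def paradox_bundle():
    """Full default synthetic study (declining cohorts, post-2007 period rise)."""
    return generate_study_bundle(SyntheticConfig())


@pytest.fixture(scope="session")
def paradox_fit(paradox_bundle):
    return fit_intrinsic_estimator(paradox_bundle["surface"])
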