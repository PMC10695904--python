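import warnings

import numpy as np
import pytest
from hypothesis import settings

from lungafc import ScannerModel, build_phantom, default_spec_2d
from lungafc.grids import Grid
from lungafc.pipeline import RunConfig, run_experiment

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    """Default 2D thorax phantom (fixed seed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_phantom(default_spec_2d(1234))


@pytest.fixture(scope="session")
def study_report():
    """The full simulation study: phantom, MLEM, all three kernel methods,
    per-VOI and global AFC quantification."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_experiment(RunConfig(seed=1234))


@pytest.fixture(scope="session")
def small_scanner():
    """Coarse geometry for fast reconstruction tests."""
    return ScannerModel(n_angles=60, n_radial=48, radial_spacing=3.0,
                        pet_spacing=(3.0, 3.0))


@pytest.fixture(scope="session")
def small_grid():
    return Grid((40, 40), (3.0, 3.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
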