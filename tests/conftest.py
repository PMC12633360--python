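import numpy as np
import pytest

from twdfc import PhantomConfig, VolumeGrid, make_cohort
from twdfc.pipeline import preprocess, subject_twdfc


@pytest.fixture(scope="session")
def grid8():
    """Small 8^3 grid at 2 mm, origin at zero."""
    return VolumeGrid.isotropic((8, 8, 8), 2.0)


@pytest.fixture(scope="session")
def default_cohort():
    """Five subjects of the default state-switching phantom (master seed 42)."""
    cfg = PhantomConfig()
    phantom, subjects = make_cohort(cfg, 5, 42)
    return cfg, phantom, subjects


@pytest.fixture(scope="session")
def cohort_maps(default_cohort):
    """Per-subject TW-dFC maps after standard pre-processing (6 mm FWHM,
    0.01-0.1 Hz), seed-restricted to the phantom's bilateral seed."""
    _, phantom, subjects = default_cohort
    maps = [
        subject_twdfc(preprocess(s["bold"]), s["tractogram"], phantom.seed_mask)
        for s in subjects
    ]
    return phantom, maps


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
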