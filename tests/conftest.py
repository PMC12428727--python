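import numpy as np
import pytest

import rbcflow as rf


@pytest.fixture(scope="session")
def crbc_model():
    """Population model calibrated to a real cord-blood unit's profile
    (MER 1.55, %UDFC 1.12, %HDFC 6.14)."""
    return rf.calibrate_population(1.55, 1.12, 6.14)


@pytest.fixture(scope="session")
def small_field(crbc_model):
    """One noise-free rendered field of 60 cells with its ground truth."""
    sample = rf.simulate_er_population(crbc_model, 60, seed=42)
    return rf.render_field(sample.values, rf.ImagingParams(seed=7),
                           field_id="fix_field")


@pytest.fixture(scope="session")
def proteomics_table():
    return rf.simulate_proteomics(rf.ProteomicsSimParams(seed=3))


def make_profile(mer: float, **kw) -> rf.DeformabilityProfile:
    """Minimal profile carrier for ranking/comparison tests."""
    defaults = dict(aer=mer, pct_udfc=0.0, pct_ldfc=0.0, pct_mid=0.0,
                    pct_hdfc=0.0, n_cells=1)
    defaults.update(kw)
    return rf.DeformabilityProfile(mer=mer, **defaults)
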