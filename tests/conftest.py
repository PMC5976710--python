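import numpy as np
import pytest

from ablafuse import Volume
from ablafuse.phantom import PhantomConfig, degrade_to_cbct, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.normal(100.0, 20.0, size=(16, 16, 16)),
                  (0.5, 0.5, 2.5), (1.25, -2.0, 3.0))


@pytest.fixture(scope="session")
def tiny_phantom_pair():
    """A small, fully deformed CECT/CBCT pair with ground truth, shared by
    the tests that only need a realistic case (not recovery accuracy)."""
    cfg = PhantomConfig.coarse(seed=7)
    cect, truth = make_phantom(cfg)
    cbct, truth = degrade_to_cbct(cect, truth, cfg)
    return cect, cbct, truth


@pytest.fixture(scope="session")
def recovery_phantom_pair():
    """The standard registration-recovery phantom: full deformation (rigid
    ~5 mm/5 deg + 3% scale + 8 mm nonrigid), CBCT degradation on, no
    ablation zone (the tumor must stay observable for recovery scoring)."""
    cfg = PhantomConfig(ablation_radius_mm=0.0)
    cect, truth = make_phantom(cfg)
    cbct, truth = degrade_to_cbct(cect, truth, cfg)
    return cect, cbct, truth
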