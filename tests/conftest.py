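import numpy as np
import pytest

from kneecart import LabelMask, PhantomSpec, RunConfig, make_phantom


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def annulus_phantom():
    """Noise-free half-annulus (femoral) phantom: ring width 10 px @ 0.4 mm."""
    spec = PhantomSpec(kind="half_annulus", row_spacing=0.4, col_spacing=0.4)
    return make_phantom(spec)


@pytest.fixture
def slab_phantom():
    """Noise-free tibial slab: 10 px tall @ 0.5 mm row spacing."""
    spec = PhantomSpec(kind="slab", slab_height=10, row_spacing=0.5, col_spacing=0.5)
    return make_phantom(spec)


@pytest.fixture
def composite_phantom():
    spec = PhantomSpec(kind="composite", row_spacing=0.4, col_spacing=0.4)
    return make_phantom(spec)


def random_label_mask(rng, shape=(40, 40), p=(0.55, 0.25, 0.20)):
    """Small random 3-class mask for oracle-equivalence checks."""
    return LabelMask(rng.choice([0, 1, 2], size=shape, p=list(p)).astype(np.uint8))
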