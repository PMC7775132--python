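import numpy as np
import pytest

from spicseg import (
    FieldParams,
    Image2D,
    ImageStack,
    Mask2D,
    PhantomSpec,
    compute_corner_field,
    compute_edge_map,
    make_nodule,
)


@pytest.fixture(scope="session")
def disk_phantom():
    """Noise-free smooth nodule phantom (stack, truth masks)."""
    spec = PhantomSpec(noise_sigma=0.0)
    stack, truth, label = make_nodule(spec)
    assert label == 0
    return spec, stack, truth


@pytest.fixture(scope="session")
def disk_edge(disk_phantom):
    """Edge map and corner field of the central disk slice."""
    spec, stack, _ = disk_phantom
    img = stack.slices[spec.center[2]]
    return compute_edge_map(img, 1.0), compute_corner_field(img, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_stack(rng, n_slices=5, height=8, width=8):
    return ImageStack.from_array(rng.random((n_slices, height, width)))


@pytest.fixture()
def checkerboard_mask():
    rr, cc = np.mgrid[0:6, 0:6]
    return Mask2D(((rr + cc) % 2).astype(np.uint8))
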