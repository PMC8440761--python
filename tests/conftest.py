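import numpy as np
import pytest

from seguq import (
    ProbabilityMap,
    SegmentationSampleStack,
    compute_probability_map,
    make_planar_interface,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def planar_scene():
    """Blurred planar interface at x0 = 16 with blur width 3 voxels."""
    return make_planar_interface((6, 8, 48), x0=16.0, w=3.0)


@pytest.fixture
def planar_pmap(planar_scene):
    """The scene's analytic probability map wrapped as a binary ProbabilityMap."""
    return ProbabilityMap(eps=planar_scene.analytic_probmap, classes=(1,),
                          n_classes=2)


@pytest.fixture
def random_binary_stack(rng):
    samples = (rng.random((7, 4, 4, 4)) < 0.5).astype(np.int8)
    return SegmentationSampleStack(samples=samples, classes=(0, 1))


@pytest.fixture
def random_binary_pmap(rng):
    eps = rng.random((16, 16, 16))
    return ProbabilityMap(eps=eps, classes=(1,), n_classes=2)


def brute_force_probability_map(samples: np.ndarray, classes) -> np.ndarray:
    """Nested-loop sample mean — the independent oracle for the map formula."""
    n, dz, dy, dx = samples.shape
    eps = np.zeros((len(classes), dz, dy, dx))
    for j, c in enumerate(classes):
        for k in range(n):
            for z in range(dz):
                for y in range(dy):
                    for x in range(dx):
                        if samples[k, z, y, x] == c:
                            eps[j, z, y, x] += 1.0
    return eps / n
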