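import numpy as np
import pytest

from gearmorph.procrustes import AlignedDataset
from gearmorph.synthetic import SynthParams, simulate_cohort
from gearmorph.tps_io import LandmarkConfiguration, LandmarkDataset


@pytest.fixture(scope="session")
def small_cohort():
    """40-fish trawl cohort with moderate vulnerability shape effect."""
    return simulate_cohort(SynthParams(seed=11, n_fish=40))


@pytest.fixture()
def triangle_dataset():
    """Two distinct triangles (k=3) for tiny GPA checks."""
    a = LandmarkConfiguration(points=np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]]), specimen_id="a")
    b = LandmarkConfiguration(points=np.array([[0.0, 0.0], [1.2, 0.1], [0.4, 0.9]]), specimen_id="b")
    return LandmarkDataset(configurations=[a, b])


def random_aligned(rng: np.random.Generator, n: int = 30, k: int = 8) -> AlignedDataset:
    """Pure-noise aligned dataset (centred, unit centroid size)."""
    coords = rng.normal(size=(n, k, 2))
    coords -= coords.mean(axis=1, keepdims=True)
    coords /= np.sqrt((coords**2).sum(axis=(1, 2)))[:, None, None]
    return AlignedDataset(
        shape_coordinates=coords,
        centroid_sizes=np.abs(rng.normal(10.0, 1.0, n)),
        consensus=coords.mean(axis=0),
        ids=[f"f{i:03d}" for i in range(n)],
    )
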