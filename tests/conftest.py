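import numpy as np
import pytest

from moviemvpa import (
    GeneratorConfig,
    RunMatrix,
    StudyDataset,
    generate_dataset,
    preprocess_dataset,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Small but non-trivial study: 4 runs, 50 classes, 600 voxels."""
    return GeneratorConfig(
        n_runs=4,
        n_timepoints=50,
        grid_shape=(10, 10, 6),
        n_components=6,
        snr=1.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    dataset, truth = small_dataset
    return preprocess_dataset(dataset), truth


def make_runs(arrays, tr=2.0):
    """Wrap a list of (T, V) arrays as RunMatrix objects with 0..T-1 labels."""
    t = np.asarray(arrays[0]).shape[0]
    return [
        RunMatrix(data=np.asarray(a, dtype=float), run_id=i, tr=tr, labels=np.arange(t))
        for i, a in enumerate(arrays)
    ]


@pytest.fixture()
def toy_runs():
    """3 runs, 3 classes, 5 voxels with distinct values — the brute-force arena."""
    rng = np.random.default_rng(42)
    base = rng.standard_normal((3, 5))
    return make_runs([base + 0.3 * rng.standard_normal((3, 5)) for _ in range(3)])


@pytest.fixture()
def toy_dataset(toy_runs):
    return StudyDataset(runs=toy_runs)
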