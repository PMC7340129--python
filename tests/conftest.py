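import numpy as np
import pytest

from omicsfusion.io import LabelVector, MultiOmicsDataset, OmicsLayer, assemble_dataset
from omicsfusion.synthetic import LayerSpec, SyntheticConfig, generate_synthetic_dataset


@pytest.fixture(scope="session")
def benchmark_dataset() -> MultiOmicsDataset:
    """The full 380-sample, three-layer synthetic benchmark (default config)."""
    return generate_synthetic_dataset()


@pytest.fixture(scope="session")
def small_dataset() -> MultiOmicsDataset:
    """A reduced two-layer dataset for fast pipeline-level tests."""
    cfg = SyntheticConfig(
        n_samples=120,
        class_weights=(0.7, 0.3),
        layer_specs=(
            LayerSpec("l1", 20, 5, class_sep=1.5, random_state=1),
            LayerSpec("l2", 15, 4, class_sep=1.5, scale_factor=10.0, random_state=2),
        ),
    )
    return generate_synthetic_dataset(cfg)


@pytest.fixture()
def two_cluster_dataset() -> tuple[MultiOmicsDataset, np.ndarray]:
    """Two well-separated sample clusters, two layers; returns (dataset, truth)."""
    rng = np.random.default_rng(42)
    x = np.r_[rng.normal(0, 1, (10, 3)), rng.normal(50, 1, (10, 3))]
    truth = np.r_[np.ones(10, dtype=int), 2 * np.ones(10, dtype=int)]
    sids = tuple(f"s{i}" for i in range(20))
    fids = ("a", "b", "c")
    layers = [
        OmicsLayer("x", sids, fids, x),
        OmicsLayer("y", sids, fids, x + rng.normal(0, 0.1, x.shape)),
    ]
    labels = LabelVector(tuple(str(t) for t in truth), None)
    return assemble_dataset(layers, labels), truth
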