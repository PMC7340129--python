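"""Synthetic multi-layer classification data.

Emulates the study's benchmark dataset: 380 samples in two classes (70/30),
three pseudo-omics layers of 100/50/250 features with 10/5/25 informative
features, per-layer class separations 1.0/1.2/0.8, a x10 multiplicative
factor on layer 3, per-layer random states 1/2/3, no label noise and no
shuffling of feature order.

Each layer is drawn with scikit-learn's ``make_classification``: informative
columns come from class-conditional Gaussian clusters whose centres sit on
hypercube vertices at half-side ``class_sep``; the remaining columns are
standard Gaussian noise. Redundant/repeated feature counts are zero and one
cluster per class is used, so with ``shuffle=False`` the leading
``n_informative`` columns carry all the class signal — which makes signal
recovery exactly testable downstream. All of a layer's values are multiplied
by its ``scale_factor``, creating the cross-layer scale heterogeneity the
similarity kernel's local scaling must absorb.

Class assignment is drawn once and shared by every layer (all layers
describe the same patients): with ``shuffle=False`` the generator emits
block-ordered labels whose counts follow largest-remainder rounding of the
class weights, identically for every layer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.datasets import make_classification

from .io import LabelVector, MultiOmicsDataset, OmicsLayer, assemble_dataset
from .utils import derive_seed, largest_remainder

__all__ = [
    "LayerSpec",
    "SyntheticConfig",
    "default_config",
    "generate_labels",
    "generate_layer",
    "generate_synthetic_dataset",
    "informative_feature_ids",
]


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class LayerSpec:
    name: str
    n_features: int
    n_informative: int
    class_sep: float = 1.0
    scale_factor: float = 1.0
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ConfigError(
                f"layer {self.name!r}: n_informative ({self.n_informative}) > "
                f"n_features ({self.n_features})"
            )
        if self.n_informative < 1 or self.n_features < 1:
            raise ConfigError(f"layer {self.name!r}: feature counts must be positive")
        if self.scale_factor <= 0 or self.class_sep <= 0:
            raise ConfigError(f"layer {self.name!r}: scale_factor and class_sep must be > 0")


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 380
    class_weights: tuple[float, ...] = (0.7, 0.3)
    layer_specs: tuple[LayerSpec, ...] = field(default_factory=tuple)
    label_noise: float = 0.0
    shuffle: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ConfigError(f"class weights must sum to 1, got {self.class_weights}")
        if not 0 <= self.label_noise < 1:
            raise ConfigError("label_noise must lie in [0, 1)")
        if self.n_samples < 4:
            raise ConfigError("need at least 4 samples")


def default_config() -> SyntheticConfig:
    """The benchmark dataset: 380 samples, 70/30 classes, three layers."""
    return SyntheticConfig(
        n_samples=380,
        class_weights=(0.7, 0.3),
        layer_specs=(
            LayerSpec("layer1", 100, 10, class_sep=1.0, scale_factor=1.0, random_state=1),
            LayerSpec("layer2", 50, 5, class_sep=1.2, scale_factor=1.0, random_state=2),
            LayerSpec("layer3", 250, 25, class_sep=0.8, scale_factor=10.0, random_state=3),
        ),
        label_noise=0.0,
        shuffle=False,
    )


def generate_labels(n_samples: int, class_weights) -> LabelVector:
    """Block-ordered class assignment with largest-remainder counts."""
    counts = largest_remainder(class_weights, n_samples)
    labels: list[str] = []
    for k, c in enumerate(counts):
        labels.extend([str(k + 1)] * c)
    return LabelVector(tuple(labels))


def generate_layer(spec: LayerSpec, n_samples: int,
                   class_assignment: LabelVector,
                   shuffle: bool = False) -> OmicsLayer:
    """One pseudo-omics layer conditioned on a fixed class assignment.

    Deterministic given (spec, class_assignment). The class assignment must
    be block-ordered (all of class 1 first, then class 2, ...), which is how
    :func:`generate_labels` emits it and how the unshuffled generator orders
    its own labels.
    """
    codes = class_assignment.codes()
    if len(codes) != n_samples:
        raise ConfigError("class_assignment length does not match n_samples")
    if np.any(np.diff(codes) < 0):
        raise ConfigError("class_assignment must be block-ordered")
    counts = np.bincount(codes, minlength=class_assignment.n_classes)
    # +0.5/n makes make_classification's int(w*n) floor reproduce `counts`
    # exactly, with no leftover redistribution.
    weights = [(c + 0.5) / n_samples for c in counts]
    values, y = make_classification(
        n_samples=n_samples,
        n_features=spec.n_features,
        n_informative=spec.n_informative,
        n_redundant=0,
        n_repeated=0,
        n_classes=len(counts),
        n_clusters_per_class=1,
        weights=weights,
        flip_y=0.0,
        class_sep=spec.class_sep,
        scale=spec.scale_factor,
        shuffle=False,
        random_state=spec.random_state,
    )
    if not np.array_equal(y, codes):
        raise ConfigError(
            f"layer {spec.name!r}: generator labels disagree with the shared assignment"
        )
    feature_ids = [f"f{j + 1}" for j in range(spec.n_features)]
    if shuffle:
        rng = np.random.default_rng(derive_seed(spec.random_state, "shuffle", spec.name))
        perm = rng.permutation(spec.n_features)
        values = values[:, perm]
        feature_ids = [feature_ids[j] for j in perm]
    sample_ids = tuple(f"s{i + 1}" for i in range(n_samples))
    return OmicsLayer(spec.name, sample_ids, tuple(feature_ids), values)


def generate_synthetic_dataset(config: SyntheticConfig | None = None) -> MultiOmicsDataset:
    """Generate the full multi-layer dataset (bit-reproducible from config)."""
    if config is None:
        config = default_config()
    if not config.layer_specs:
        config = replace(config, layer_specs=default_config().layer_specs)
    labels = generate_labels(config.n_samples, config.class_weights)
    layers = [
        generate_layer(spec, config.n_samples, labels, shuffle=config.shuffle)
        for spec in config.layer_specs
    ]
    if config.label_noise > 0:
        # Noise flips the reported phenotype only; the features keep the
        # original class-conditional signal (the layers stay in sync).
        rng = np.random.default_rng(
            derive_seed(config.layer_specs[0].random_state, "label_noise"))
        n_flip = int(round(config.label_noise * config.n_samples))
        flip = rng.choice(config.n_samples, size=n_flip, replace=False)
        classes = labels.classes
        noisy = list(labels.labels)
        for i in flip:
            others = [c for c in classes if c != noisy[i]]
            noisy[i] = others[rng.integers(len(others))]
        labels = LabelVector(tuple(noisy), None, classes)
    return assemble_dataset(layers, labels)


def informative_feature_ids(config: SyntheticConfig | None = None) -> dict[str, list[str]]:
    """Prefixed ids of the class-informative columns, per layer.

    Valid for unshuffled configurations, where the informative columns are
    the leading ones.
    """
    if config is None:
        config = default_config()
    if config.shuffle:
        raise ConfigError("informative positions are only fixed when shuffle=False")
    return {
        spec.name: [f"{spec.name}:f{j + 1}" for j in range(spec.n_informative)]
        for spec in config.layer_specs
    }
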