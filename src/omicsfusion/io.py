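"""Tabular I/O for multi-omics datasets.

One tab-separated matrix per omics layer (samples on rows, features on
columns, both with identifiers) plus a single-column, headerless label
file. Layers are assembled into a sample-aligned :class:`MultiOmicsDataset`
whose feature identifiers carry layer provenance via a ``<layer>:`` prefix.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "AlignmentError",
    "OmicsLayer",
    "LabelVector",
    "MultiOmicsDataset",
    "read_omics_layer",
    "write_omics_layer",
    "read_labels",
    "write_labels",
    "assemble_dataset",
    "juxtapose",
]


class FormatError(ValueError):
    """A file violates the tabular format contract."""


class AlignmentError(ValueError):
    """Sample identifiers do not line up across layers and labels."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class OmicsLayer:
    """A single omics layer: a real-valued (samples x features) matrix."""

    name: str
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise FormatError(f"layer {self.name!r}: values must be 2-D")
        n, p = values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise FormatError(
                f"layer {self.name!r}: matrix shape {values.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.feature_ids)} features)"
            )
        if n == 0 or p == 0:
            raise FormatError(f"layer {self.name!r}: empty data region")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"layer {self.name!r}: non-finite value at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def reorder_samples(self, sample_ids: Sequence[str]) -> "OmicsLayer":
        """Return a copy with rows permuted into the given sample order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        extra = [s for s in self.sample_ids if s not in set(sample_ids)]
        if missing or extra:
            raise AlignmentError(
                f"layer {self.name!r}: sample mismatch; missing={missing}, extra={extra}"
            )
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return OmicsLayer(self.name, tuple(sample_ids), self.feature_ids, self.values[idx])

    def with_prefixed_features(self) -> "OmicsLayer":
        prefixed = tuple(
            f if f.startswith(self.name + ":") else f"{self.name}:{f}"
            for f in self.feature_ids
        )
        return OmicsLayer(self.name, self.sample_ids, prefixed, self.values)


@dataclass(frozen=True)
class LabelVector:
    """Class label per sample; classes kept in first-appearance order."""

    labels: tuple[str, ...]
    sample_ids: tuple[str, ...] | None = None
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.classes:
            seen: list[str] = []
            for lab in self.labels:
                if lab not in seen:
                    seen.append(lab)
            object.__setattr__(self, "classes", tuple(seen))
        if self.sample_ids is not None and len(self.sample_ids) != len(self.labels):
            raise AlignmentError("sample_ids and labels differ in length")
        if len(self.classes) < 2:
            raise FormatError("at least 2 classes required")
        counts = self.class_counts()
        small = [c for c, k in counts.items() if k < 2]
        if small:
            raise FormatError(f"every class needs >=2 samples; too small: {small}")

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for lab in self.labels:
            counts[lab] += 1
        return counts

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def codes(self) -> np.ndarray:
        """Integer class codes (0-based, in class-discovery order)."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[lab] for lab in self.labels], dtype=int)

    def with_sample_ids(self, sample_ids: Sequence[str]) -> "LabelVector":
        return LabelVector(self.labels, tuple(sample_ids), self.classes)


@dataclass(frozen=True)
class MultiOmicsDataset:
    """Sample-aligned collection of omics layers plus labels."""

    layers: tuple[OmicsLayer, ...]
    labels: LabelVector

    def __post_init__(self) -> None:
        if not self.layers:
            raise FormatError("at least one layer required")
        ref = self.layers[0].sample_ids
        for layer in self.layers:
            if layer.sample_ids != ref:
                raise AlignmentError(f"layer {layer.name!r} not in canonical sample order")
        if self.labels.sample_ids is not None and self.labels.sample_ids != ref:
            raise AlignmentError("labels not in canonical sample order")
        all_ids = [f for layer in self.layers for f in layer.feature_ids]
        _check_unique(all_ids, "global feature")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.layers[0].sample_ids

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(layer.name for layer in self.layers)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def layer(self, name: str) -> OmicsLayer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(f"unknown layer {name!r}; have {self.layer_names}")

    def subset_layers(self, names: Sequence[str]) -> "MultiOmicsDataset":
        return MultiOmicsDataset(tuple(self.layer(n) for n in names), self.labels)


def layer_of(feature_id: str) -> str:
    """Layer provenance of a prefixed feature identifier."""
    return feature_id.split(":", 1)[0]


def read_omics_layer(path: str | Path, name: str | None = None) -> OmicsLayer:
    """Read one tab-separated omics matrix (header row + id column)."""
    path = Path(path)
    name = name if name is not None else path.stem
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        feature_ids = header.rstrip("\n").split("\t")[1:]
        if not feature_ids:
            raise FormatError(f"{path}: no feature columns in header")
        body = fh.read()
    if not body.strip():
        raise FormatError(f"{path}: empty data region (header only)")
    df = pd.read_csv(
        _stdio.StringIO(body), sep="\t", header=None, index_col=0, dtype=str,
        keep_default_na=False,
    )
    sample_ids = [str(s) for s in df.index]
    if df.shape[1] != len(feature_ids):
        raise FormatError(
            f"{path}: rows carry {df.shape[1]} values but header names "
            f"{len(feature_ids)} features"
        )
    raw = df.to_numpy()
    probe = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy()
    bad = ~np.isfinite(probe)
    if bad.any():
        flat = int(np.argmax(bad))
        i, j = divmod(flat, len(feature_ids))
        raise FormatError(
            f"{path}: non-numeric or missing cell at row {sample_ids[i]!r}, "
            f"column {feature_ids[j]!r} (value {raw[i, j]!r})"
        )
    # numpy's strtod is correctly rounded, so write->read round-trips bit-exactly
    values = raw.astype(np.float64)
    return OmicsLayer(name, tuple(sample_ids), tuple(feature_ids), values)


def write_omics_layer(layer: OmicsLayer, path: str | Path) -> None:
    """Write a layer as TSV with full-precision floats (round-trip safe)."""
    df = pd.DataFrame(layer.values, index=list(layer.sample_ids),
                      columns=list(layer.feature_ids))
    df.to_csv(path, sep="\t", float_format=None, encoding="utf-8")


def read_labels(path: str | Path, with_sample_ids: bool = False) -> LabelVector:
    """Read the label file.

    Default format is a single headerless column, one phenotype per line,
    matched positionally to the canonical sample order. With
    ``with_sample_ids=True`` a two-column ``sample_id<TAB>label`` variant is
    accepted instead.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise FormatError(f"{path}: empty label file")
    if with_sample_ids:
        pairs = [ln.split("\t") for ln in lines]
        if any(len(p) != 2 for p in pairs):
            raise FormatError(f"{path}: expected two tab-separated columns")
        ids, labels = zip(*pairs)
        _check_unique(ids, "sample")
        return LabelVector(tuple(labels), tuple(ids))
    return LabelVector(tuple(lines), None)


def write_labels(labels: LabelVector, path: str | Path,
                 with_sample_ids: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, lab in enumerate(labels.labels):
            if with_sample_ids:
                if labels.sample_ids is None:
                    raise AlignmentError("labels carry no sample ids")
                fh.write(f"{labels.sample_ids[i]}\t{lab}\n")
            else:
                fh.write(f"{lab}\n")


def assemble_dataset(layers: Iterable[OmicsLayer], labels: LabelVector) -> MultiOmicsDataset:
    """Align layers to the label sample order and prefix feature ids.

    When the label file carries no sample identifiers they are assigned
    positionally from the first layer's row order (the canonical order).
    """
    layers = list(layers)
    if not layers:
        raise FormatError("at least one layer required")
    if labels.sample_ids is None:
        if len(labels) != layers[0].n_samples:
            raise AlignmentError(
                f"{len(labels)} labels for {layers[0].n_samples} samples in layer "
                f"{layers[0].name!r}"
            )
        labels = labels.with_sample_ids(layers[0].sample_ids)
    order = labels.sample_ids
    assert order is not None
    aligned = tuple(layer.reorder_samples(order).with_prefixed_features()
                    for layer in layers)
    return MultiOmicsDataset(aligned, labels)


def juxtapose(dataset: MultiOmicsDataset,
              layer_subset: Sequence[str] | None = None) -> OmicsLayer:
    """Column-wise concatenation of the given layers (early integration)."""
    names = list(layer_subset) if layer_subset is not None else list(dataset.layer_names)
    if not names:
        raise KeyError("layer_subset must be non-empty")
    chosen = [dataset.layer(n) for n in names]
    values = np.concatenate([layer.values for layer in chosen], axis=1)
    feature_ids = tuple(f for layer in chosen for f in layer.feature_ids)
    return OmicsLayer("+".join(names), dataset.sample_ids, feature_ids, values)
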