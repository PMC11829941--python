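"""Feature-bag containers for multiple-instance slide classification.

A *bag* is one whole-slide image reduced to an ``M x d`` matrix of patch
feature vectors, optionally with the 0-based ``(row, col)`` tile-grid
coordinate of each patch and a slide-level class label.  Bags are stored
on disk as one HDF5 group per slide with datasets ``features`` (float32,
``M x d``) and ``coords`` (int, ``M x 2``) and attributes ``slide_id``,
``label``, ``magnification``; the synthetic generator additionally writes
a per-patch ``signal_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import h5py
import numpy as np

from .errors import FormatError, ShapeError, ValidationError

MAGNIFICATIONS = ("x10", "x20", "synthetic")


@dataclass
class FeatureBag:
    """One slide as an unordered bag of patch feature vectors."""

    features: np.ndarray  # (M, d) float
    coords: np.ndarray | None = None  # (M, 2) int, 0-based tile grid
    slide_id: str = ""
    label: int | None = None
    magnification: str = "synthetic"
    patient_id: str | None = None
    signal_mask: np.ndarray | None = None  # (M,) bool, synthetic ground truth

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ShapeError(
                f"bag '{self.slide_id}': features must be 2-D (M x d), got ndim={self.features.ndim}"
            )
        if self.features.shape[0] < 1:
            raise ValidationError(
                f"bag '{self.slide_id}': M=0 — a slide with no tissue tiles is not classifiable"
            )
        if not np.isfinite(self.features).all():
            raise ValidationError(f"bag '{self.slide_id}': non-finite feature values")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.int64)
            if self.coords.shape != (self.features.shape[0], 2):
                raise ShapeError(
                    f"bag '{self.slide_id}': coords must be (M, 2)="
                    f"({self.features.shape[0]}, 2), got {self.coords.shape}"
                )
            if (self.coords < 0).any():
                raise ValidationError(f"bag '{self.slide_id}': negative tile coordinates")
            uniq = {tuple(rc) for rc in self.coords.tolist()}
            if len(uniq) != len(self.coords):
                raise ValidationError(
                    f"bag '{self.slide_id}': duplicate (row, col) tile coordinates"
                )
        if self.magnification not in MAGNIFICATIONS:
            raise ValidationError(
                f"bag '{self.slide_id}': magnification must be one of {MAGNIFICATIONS}"
            )
        if self.signal_mask is not None:
            self.signal_mask = np.asarray(self.signal_mask, dtype=bool)
            if self.signal_mask.shape != (self.features.shape[0],):
                raise ShapeError(f"bag '{self.slide_id}': signal_mask must be (M,)")

    @property
    def M(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def permuted(self, perm: np.ndarray) -> "FeatureBag":
        """Return a copy with rows (and coords/mask) reordered by ``perm``."""
        perm = np.asarray(perm)
        return FeatureBag(
            features=self.features[perm],
            coords=None if self.coords is None else self.coords[perm],
            slide_id=self.slide_id,
            label=self.label,
            magnification=self.magnification,
            patient_id=self.patient_id,
            signal_mask=None if self.signal_mask is None else self.signal_mask[perm],
        )


@dataclass
class BagDataset:
    """An in-memory collection of bags sharing one feature width."""

    bags: list[FeatureBag] = field(default_factory=list)

    def __post_init__(self):
        widths = {b.d for b in self.bags}
        if len(widths) > 1:
            raise ValidationError(f"bags disagree on feature width d: {sorted(widths)}")

    def __len__(self):
        return len(self.bags)

    def __iter__(self) -> Iterator[FeatureBag]:
        return iter(self.bags)

    def __getitem__(self, i) -> FeatureBag:
        return self.bags[i]

    @property
    def d(self) -> int:
        return self.bags[0].d

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.bags])


def write_bags(path, dataset: BagDataset | list[FeatureBag], attention: dict | None = None) -> None:
    """Write bags to an HDF5 container, one group per slide.

    ``attention`` may map slide_id -> (k, S, M) array, stored as the
    optional ``seqshort_attention`` dataset.
    """
    bags = dataset.bags if isinstance(dataset, BagDataset) else dataset
    with h5py.File(path, "w") as f:
        for bag in bags:
            grp = f.create_group(bag.slide_id)
            grp.create_dataset("features", data=bag.features.astype(np.float32))
            if bag.coords is not None:
                grp.create_dataset("coords", data=bag.coords.astype(np.int64))
            if bag.signal_mask is not None:
                grp.create_dataset("signal_mask", data=bag.signal_mask)
            grp.attrs["slide_id"] = bag.slide_id
            if bag.label is not None:
                grp.attrs["label"] = int(bag.label)
            grp.attrs["magnification"] = bag.magnification
            if bag.patient_id is not None:
                grp.attrs["patient_id"] = bag.patient_id
            if attention and bag.slide_id in attention:
                grp.create_dataset("seqshort_attention", data=attention[bag.slide_id])


def _load_group(name: str, grp: h5py.Group) -> FeatureBag:
    if "features" not in grp:
        raise FormatError(f"slide group '{name}': missing dataset 'features'")
    feats = np.asarray(grp["features"], dtype=np.float64)
    if not np.isfinite(feats).all():
        raise ValidationError(f"slide group '{name}': NaN or infinite feature values")
    coords = np.asarray(grp["coords"]) if "coords" in grp else None
    mask = np.asarray(grp["signal_mask"], dtype=bool) if "signal_mask" in grp else None
    label = int(grp.attrs["label"]) if "label" in grp.attrs else None
    try:
        return FeatureBag(
            features=feats,
            coords=coords,
            slide_id=str(grp.attrs.get("slide_id", name)),
            label=label,
            magnification=str(grp.attrs.get("magnification", "synthetic")),
            patient_id=(str(grp.attrs["patient_id"]) if "patient_id" in grp.attrs else None),
            signal_mask=mask,
        )
    except ValidationError as e:
        raise type(e)(f"slide group '{name}': {e}") from e


def iter_bags(path) -> Iterator[FeatureBag]:
    """Stream bags lazily from an HDF5 container, validating each on load."""
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            yield _load_group(name, f[name])


def read_bags(path) -> BagDataset:
    """Load and validate all bags from an HDF5 container."""
    return BagDataset(list(iter_bags(path)))
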