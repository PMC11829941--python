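"""Synthetic feature bags with planted multiple-instance structure.

Each bag mimics a slide after patch embedding: most patches are drawn
(with replacement) from one fixed pool of isotropic Gaussian
"background" vectors shared across classes — reproducing the redundancy
real bags exhibit — while a small Binomial(M, pi) subset of "signal"
patches are the same pool vectors shifted along a class-specific unit
direction by ``signal_strength`` noise standard deviations.  Directions
of distinct classes are mutually orthogonal.  Ground-truth per-patch
signal indicators are kept so interpretability claims can be scored.

The generator tests mechanism, not biology: it does not mimic real
histology feature statistics, spatial correlation between neighboring
tiles, or staining variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bags import BagDataset, FeatureBag
from .errors import ValidationError

__all__ = ["SyntheticSpec", "generate_dataset", "linear_probe_oracle"]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    num_classes: int = 2
    num_bags: int = 200
    bag_size_mean: float = 200.0
    bag_size_dispersion: float = 0.25  # coefficient of variation of bag sizes
    bag_size_min: int = 8
    d: int = 32
    signal_fraction: float = 0.05  # pi: expected fraction of signal patches
    signal_strength: float = 4.0  # mean shift in units of noise std
    pool_size: int = 2000
    noise_std: float = 1.0
    seed: int = 0
    slides_per_patient: int = 1
    independent_draw: bool = False  # draw signal fresh instead of shifting pool vectors

    def __post_init__(self):
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValidationError("signal_fraction must be in [0, 1]")
        if self.num_classes < 2 or self.num_classes > self.d:
            raise ValidationError("need 2 <= num_classes <= d (orthogonal directions)")
        if self.bag_size_min < 1 or self.bag_size_mean < self.bag_size_min:
            raise ValidationError("bag sizes must be >= bag_size_min >= 1")


def _class_directions(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Mutually orthogonal unit directions, one per class (seeded rotation)."""
    a = rng.normal(size=(spec.d, spec.d))
    q, _ = np.linalg.qr(a)
    return q[:, : spec.num_classes].T  # (C, d)


def generate_dataset(spec: SyntheticSpec) -> BagDataset:
    """Deterministic labeled dataset of feature bags with signal indicators.

    Labels cycle through the classes so the dataset is balanced up to
    rounding; each bag's ``signal_mask`` marks the planted patches.
    """
    rng = np.random.default_rng(spec.seed)
    pool = rng.normal(0.0, spec.noise_std, size=(spec.pool_size, spec.d))
    dirs = _class_directions(spec, rng)
    shift = spec.signal_strength * spec.noise_std
    bags = []
    for b in range(spec.num_bags):
        label = b % spec.num_classes
        m = max(
            spec.bag_size_min,
            int(round(rng.normal(spec.bag_size_mean, spec.bag_size_dispersion * spec.bag_size_mean))),
        )
        idx = rng.integers(0, spec.pool_size, size=m)
        feats = pool[idx].copy()
        n_signal = rng.binomial(m, spec.signal_fraction)
        mask = np.zeros(m, dtype=bool)
        if n_signal:
            pos = rng.choice(m, size=n_signal, replace=False)
            mask[pos] = True
            if spec.independent_draw:
                feats[pos] = rng.normal(0.0, spec.noise_std, size=(n_signal, spec.d))
            feats[pos] += shift * dirs[label]
        side = int(np.ceil(np.sqrt(m)))
        coords = np.stack([np.arange(m) // side, np.arange(m) % side], axis=1)
        patient = b // spec.slides_per_patient
        bags.append(
            FeatureBag(
                features=feats,
                coords=coords,
                slide_id=f"synthetic_{b:04d}",
                label=label,
                magnification="synthetic",
                patient_id=f"patient_{patient:04d}",
                signal_mask=mask,
            )
        )
    return BagDataset(bags)


def linear_probe_oracle(dataset: BagDataset, seed: int = 0) -> float:
    """Independent separability baseline for generated datasets.

    Mean-pools each bag, fits a least-squares linear classifier on a
    random half of the bags and reports AUROC on the other half.  Serves
    as the oracle against which the generator's planted signal level is
    judged; it shares no code with the attention model.
    """
    from .training import evaluate_auroc

    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise ValidationError("linear probe needs at least two classes present")
    x = np.stack([b.features.mean(axis=0) for b in dataset])
    x = np.hstack([x, np.ones((len(x), 1))])  # bias column
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    half = len(x) // 2
    tr, te = order[:half], order[half:]
    if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
        raise ValidationError("both probe halves must contain two classes")
    classes = np.unique(labels)
    onehot = (labels[tr, None] == classes[None, :]).astype(float)
    w, *_ = np.linalg.lstsq(x[tr], onehot, rcond=None)
    scores = x[te] @ w
    if len(classes) == 2:
        return evaluate_auroc(scores[:, 1], labels[te])
    return evaluate_auroc(scores, labels[te])
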