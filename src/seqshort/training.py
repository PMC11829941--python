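"""Training loop, learning-rate schedule, AUROC and cross-validation.

The schedule is a linear warm-up from 0 to ``max_lr`` followed by one or
more half-cosine decay cycles that partition the remaining epochs
equally; each cycle restarts at ``max_lr`` and decays to 0.  Optimization
is Adam on the trainable parameter selection only; frozen parameters are
bit-identical before and after a run.  Bags of unequal size are handled
one per forward pass with gradient accumulation up to the configured
batch size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from ._autograd import log_softmax
from .bags import BagDataset
from .errors import ValidationError
from .model import Model, TrainableSelection, select_trainable

__all__ = [
    "TrainingPlan",
    "TRAINING_PRESETS",
    "lr_at",
    "train",
    "evaluate_auroc",
    "crossval_split",
    "stratified_split",
    "AdamOptimizer",
]


@dataclass
class TrainingPlan:
    """Schedule and optimizer settings for one run."""

    epochs: int = 200
    warmup_epochs: int = 5
    cosine_cycles: int = 1
    max_lr: float = 1e-4
    batch_size: int = 16
    optimizer: str = "adam"
    seed: int = 0
    preset: str = ""

    def __post_init__(self):
        if self.warmup_epochs >= self.epochs:
            raise ValidationError("warmup_epochs must be smaller than epochs")
        if self.cosine_cycles < 1:
            raise ValidationError("cosine_cycles must be >= 1")
        if self.max_lr <= 0:
            raise ValidationError("max_lr must be positive")


#: schedules of the two benchmark tasks
TRAINING_PRESETS = {
    "lnm": TrainingPlan(epochs=200, warmup_epochs=5, cosine_cycles=1, max_lr=1e-4, batch_size=16, preset="lnm"),
    "subtype": TrainingPlan(epochs=200, warmup_epochs=10, cosine_cycles=2, max_lr=5e-5, batch_size=32, preset="subtype"),
}


def lr_at(plan: TrainingPlan, epoch: float) -> float:
    """Learning rate at a (possibly fractional) epoch position.

    Ramps linearly 0 -> ``max_lr`` over the warm-up, then decays
    ``max_lr`` -> 0 over each of ``cosine_cycles`` equal half-cosine
    cycles, restarting at ``max_lr`` at every cycle boundary.
    """
    if not 0.0 <= epoch <= plan.epochs:
        raise ValidationError(f"epoch {epoch} outside [0, {plan.epochs}]")
    if epoch < plan.warmup_epochs:
        return plan.max_lr * epoch / plan.warmup_epochs
    if epoch == plan.epochs:
        return 0.0
    cycle_len = (plan.epochs - plan.warmup_epochs) / plan.cosine_cycles
    t = ((epoch - plan.warmup_epochs) % cycle_len) / cycle_len
    return plan.max_lr * 0.5 * (1.0 + np.cos(np.pi * t))


class AdamOptimizer:
    """Adam with bias correction on a named subset of model parameters."""

    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self, lr: float, grad_scale: float = 1.0) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, tensor in self.params.items():
            if tensor.grad is None:
                continue
            g = tensor.grad * grad_scale
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            tensor.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for tensor in self.params.values():
            tensor.grad = None


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    lr: float
    val_auroc: float | None = None


def evaluate_auroc(scores, labels) -> float:
    """Area under the ROC curve; rank-based, ties counted half.

    1-D scores: binary AUROC of the positive class.  2-D scores (one
    column per class): unweighted mean of one-vs-rest areas.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("AUROC undefined with a single class present")
    if scores.ndim == 1:
        if classes.size != 2:
            raise ValidationError("1-D scores require exactly two classes")
        return float(roc_auc_score(labels == classes[1], scores))
    aucs = [
        roc_auc_score(labels == c, scores[:, int(c)]) for c in classes
    ]
    return float(np.mean(aucs))


def _bag_scores(model: Model, dataset: BagDataset) -> np.ndarray:
    from .model import classify

    return np.stack([classify(model, bag)[0] for bag in dataset])


def train(
    model: Model,
    dataset: BagDataset,
    plan: TrainingPlan,
    selection: TrainableSelection | None = None,
    val_dataset: BagDataset | None = None,
) -> tuple[dict, list[EpochRecord]]:
    """Train the flagged parameters with cross-entropy; fully seeded.

    Returns the final parameter state and the per-epoch log (epoch, mean
    loss, learning rate at the last step, validation AUROC if a
    validation set was given).
    """
    labels = dataset.labels
    present = set(int(l) for l in labels)
    missing = set(range(model.config.num_classes)) - present
    if missing:
        raise ValidationError(f"classes {sorted(missing)} absent from the training labels")
    if selection is None:
        selection = select_trainable(model, model.config.trainability_policy)
    opt = AdamOptimizer(
        {name: model.params[name] for name in selection.trainable_names()}
    )
    rng = np.random.default_rng(plan.seed)
    n = len(dataset)
    log: list[EpochRecord] = []
    for epoch in range(plan.epochs):
        order = rng.permutation(n)
        losses = []
        lr = 0.0
        pending = 0
        for j, idx in enumerate(order):
            bag = dataset[idx]
            logits, _ = model.forward(bag)
            loss = -log_softmax(logits.reshape(1, -1), axis=-1)[0, int(bag.label)]
            losses.append(float(loss.data))
            loss.backward()
            pending += 1
            if pending == plan.batch_size or j == n - 1:
                lr = lr_at(plan, min(epoch + (j + 1) / n, plan.epochs))
                opt.step(lr, grad_scale=1.0 / pending)
                opt.zero_grad()
                pending = 0
        rec = EpochRecord(epoch=epoch, loss=float(np.mean(losses)), lr=lr)
        if val_dataset is not None:
            scores = _bag_scores(model, val_dataset)
            if model.config.num_classes == 2:
                rec.val_auroc = evaluate_auroc(scores[:, 1], val_dataset.labels)
            else:
                rec.val_auroc = evaluate_auroc(scores, val_dataset.labels)
        log.append(rec)
    return model.state_dict(), log


def crossval_split(
    dataset: BagDataset,
    folds: int = 10,
    patient_ids: list[str] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Patient-level stratified fold assignment, one fold index per bag.

    Every patient lands in exactly one fold (all their slides together);
    within each class, patients are dealt round-robin after a seeded
    shuffle, so per-fold class counts differ from perfect stratification
    by at most one patient.  A class with fewer patients than folds
    triggers a warning and best-effort assignment.
    """
    if patient_ids is None:
        patient_ids = [b.patient_id or b.slide_id for b in dataset]
    labels = dataset.labels
    pat_label: dict[str, int] = {}
    for pid, lab in zip(patient_ids, labels):
        if lab is None:
            raise ValidationError(f"patient '{pid}' has a bag without a label")
        pat_label.setdefault(pid, int(lab))
    rng = np.random.default_rng(seed)
    pat_fold: dict[str, int] = {}
    offset = 0
    for cls in sorted(set(pat_label.values())):
        pats = sorted(p for p, l in pat_label.items() if l == cls)
        if len(pats) < folds:
            warnings.warn(
                f"class {cls} has {len(pats)} patients for {folds} folds; "
                "stratification is best-effort"
            )
        pats = [pats[i] for i in rng.permutation(len(pats))]
        for i, p in enumerate(pats):
            pat_fold[p] = (i + offset) % folds
        offset += len(pats)
    return np.array([pat_fold[p] for p in patient_ids])


def stratified_split(
    dataset: BagDataset, test_fraction: float = 0.25, seed: int = 0
) -> tuple[BagDataset, BagDataset]:
    """Seeded stratified train/test split at bag level."""
    labels = dataset.labels
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test].tolist())
    test_set = set(test_idx)
    train = BagDataset([b for i, b in enumerate(dataset) if i not in test_set])
    test = BagDataset([b for i, b in enumerate(dataset) if i in test_set])
    return train, test
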