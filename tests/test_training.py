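"""Learning-rate schedule, training loop contracts, AUROC, cross-validation."""

import numpy as np
import pytest

from seqshort import (
    BagDataset,
    ModelConfig,
    TrainingPlan,
    ValidationError,
    assemble,
    crossval_split,
    evaluate_auroc,
    lr_at,
    select_trainable,
    train,
)
from seqshort.synthetic import SyntheticSpec, generate_dataset
from seqshort.training import TRAINING_PRESETS


class TestSchedule:
    def test_published_preset_anchors(self):
        lnm = TRAINING_PRESETS["lnm"]
        sub = TRAINING_PRESETS["subtype"]
        assert lr_at(lnm, 5) == pytest.approx(1e-4)  # warm-up peak
        assert lr_at(lnm, 200) == 0.0  # end of the single cycle
        assert lr_at(sub, 10) == pytest.approx(5e-5)
        assert lr_at(sub, 105) == pytest.approx(5e-5)  # restart between cycles
        assert lr_at(sub, 200) == 0.0

    def test_warmup_is_linear_from_zero(self):
        plan = TrainingPlan(epochs=20, warmup_epochs=4, cosine_cycles=1, max_lr=2e-3)
        assert lr_at(plan, 0) == 0.0
        assert lr_at(plan, 2) == pytest.approx(1e-3)
        eps = 1e-6
        assert lr_at(plan, 4 - eps) == pytest.approx(lr_at(plan, 4), rel=1e-4)

    def test_cycles_peak_and_vanish(self):
        plan = TrainingPlan(epochs=26, warmup_epochs=2, cosine_cycles=3, max_lr=1.0)
        for boundary in (2, 10, 18):  # cycle starts
            assert lr_at(plan, boundary) == pytest.approx(1.0)
        for end in (10, 18, 26):  # cycle ends approached from the left
            assert lr_at(plan, end - 1e-9) == pytest.approx(0.0, abs=1e-8)
        mid = lr_at(plan, 6)  # halfway through a cycle: half of max
        assert mid == pytest.approx(0.5)

    def test_epoch_out_of_range(self):
        plan = TrainingPlan(epochs=10, warmup_epochs=1)
        with pytest.raises(ValidationError):
            lr_at(plan, -0.1)
        with pytest.raises(ValidationError):
            lr_at(plan, 10.1)

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValidationError):
            TrainingPlan(epochs=5, warmup_epochs=5)
        with pytest.raises(ValidationError):
            TrainingPlan(cosine_cycles=0)
        with pytest.raises(ValidationError):
            TrainingPlan(max_lr=0.0)


def tiny_setup(seed=0, n_bags=24):
    spec = SyntheticSpec(num_bags=n_bags, bag_size_mean=20, bag_size_min=5,
                         d=8, signal_fraction=0.3, signal_strength=4.0,
                         pool_size=100, seed=seed)
    ds = generate_dataset(spec)
    config = ModelConfig(S=4, h=8, k=2, d=8, encoder_layers=1, encoder_heads=2,
                         encoder_ffn_width=16, num_classes=2, seed=seed)
    return ds, assemble(config)


class TestTrainLoop:
    PLAN = TrainingPlan(epochs=4, warmup_epochs=1, cosine_cycles=1,
                        max_lr=3e-3, batch_size=8, seed=0)

    def test_loss_decreases_on_strong_signal(self):
        ds, model = tiny_setup()
        _, log = train(model, ds, self.PLAN)
        assert log[-1].loss < log[0].loss

    def test_same_seed_identical_logs(self):
        ds, model_a = tiny_setup()
        _, log_a = train(model_a, ds, self.PLAN)
        ds2, model_b = tiny_setup()
        _, log_b = train(model_b, ds2, self.PLAN)
        assert [(r.epoch, r.loss, r.lr) for r in log_a] == [
            (r.epoch, r.loss, r.lr) for r in log_b
        ]

    def test_frozen_backbone_is_bit_identical(self):
        ds, model = tiny_setup()
        sel = select_trainable(model, "normalization-only")
        frozen_before = {
            n: model.params[n].data.copy()
            for n in sel.groups["encoder_backbone"]["names"]
        }
        head_before = model.params["head.w2"].data.copy()
        train(model, ds, self.PLAN, selection=sel)
        for n, before in frozen_before.items():
            assert np.array_equal(model.params[n].data, before)
        # while the trainable head actually moved
        assert not np.array_equal(model.params["head.w2"].data, head_before)

    def test_missing_class_rejected(self):
        ds, model = tiny_setup()
        one_class = BagDataset([b for b in ds if b.label == 0])
        with pytest.raises(ValidationError, match="absent"):
            train(model, one_class, self.PLAN)


class TestAuroc:
    def test_perfect_separation(self):
        assert evaluate_auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert evaluate_auroc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_printed_four_item_example(self):
        assert evaluate_auroc([0.1, 0.6, 0.4, 0.9], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        base = evaluate_auroc(scores, labels)
        assert evaluate_auroc(np.exp(3 * scores), labels) == pytest.approx(base)
        assert evaluate_auroc(2 * scores - 7, labels) == pytest.approx(base)

    def test_multiclass_macro_average(self, rng):
        labels = np.array([0, 0, 1, 1, 2, 2])
        scores = np.eye(3)[labels] + rng.normal(0, 0.05, size=(6, 3))
        assert evaluate_auroc(scores, labels) > 0.9

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_auroc([0.1, 0.2], [1, 1])


class TestCrossval:
    def balanced_dataset(self):
        spec = SyntheticSpec(num_bags=100, bag_size_mean=5, bag_size_min=2, d=4,
                             signal_fraction=0.2, pool_size=50, seed=1)
        return generate_dataset(spec)

    def test_perfect_stratification_when_divisible(self):
        ds = self.balanced_dataset()  # 50 + 50 patients, one per bag
        folds = crossval_split(ds, folds=10, seed=0)
        labels = ds.labels
        for f in range(10):
            in_fold = labels[folds == f]
            assert (in_fold == 0).sum() == 5 and (in_fold == 1).sum() == 5

    def test_patients_stay_together(self):
        spec = SyntheticSpec(num_bags=60, bag_size_mean=5, bag_size_min=2, d=4,
                             signal_fraction=0.2, pool_size=50, seed=2,
                             slides_per_patient=3)
        ds = generate_dataset(spec)
        folds = crossval_split(ds, folds=5, seed=0)
        for pid in {b.patient_id for b in ds}:
            idx = [i for i, b in enumerate(ds) if b.patient_id == pid]
            assert len({folds[i] for i in idx}) == 1

    def test_deterministic_given_seed(self):
        ds = self.balanced_dataset()
        assert np.array_equal(crossval_split(ds, seed=42), crossval_split(ds, seed=42))
        assert not np.array_equal(crossval_split(ds, seed=1), crossval_split(ds, seed=2))

    def test_small_class_warns(self):
        spec = SyntheticSpec(num_bags=12, bag_size_mean=5, bag_size_min=2, d=4,
                             signal_fraction=0.2, pool_size=50, seed=3)
        ds = generate_dataset(spec)
        with pytest.warns(UserWarning, match="best-effort"):
            crossval_split(ds, folds=10, seed=0)
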