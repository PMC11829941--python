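"""Classifier assembly: positional encodings, parameter accounting, FLOPs."""

import numpy as np
import pytest

from seqshort import (
    ConfigurationError,
    FeatureBag,
    ModelConfig,
    ShapeError,
    ValidationError,
    assemble,
    classify,
    count_parameters,
    encode_patch_locations,
    estimate_flops,
    select_trainable,
)
from seqshort.model import encoder_mac_count, load_preset


class TestPatchLocationEncoding:
    def test_origin_tile_gives_zero_sines_unit_cosines(self):
        enc = encode_patch_locations(np.array([[0, 0]]), d=8)
        assert np.allclose(enc[0, 0::2], 0.0)  # sine channels
        assert np.allclose(enc[0, 1::2], 1.0)  # cosine channels

    def test_identical_coords_identical_rows(self):
        enc = encode_patch_locations(np.array([[3, 5], [3, 5]]), d=12)
        assert np.array_equal(enc[0], enc[1])

    def test_row_and_column_blocks_are_distinct(self):
        enc = encode_patch_locations(np.array([[0, 1], [1, 0]]), d=16)
        assert not np.allclose(enc[0], enc[1])
        # the row half of (0,1) matches the row half of (0,*) etc.
        assert np.allclose(enc[0, :8], encode_patch_locations(np.array([[0, 9]]), 16)[0, :8])

    def test_odd_width_rejected(self):
        with pytest.raises(ValidationError):
            encode_patch_locations(np.array([[0, 0]]), d=7)


class TestAssembly:
    def test_presets_carry_the_published_shapes(self):
        lnm = load_preset("lnm")
        sub = load_preset("subtype")
        assert (lnm.S, lnm.h, lnm.k) == (511, 768, 4)
        assert (sub.S, sub.h, sub.k) == (256, 768, 4)

    def test_lnm_preset_encoder_sees_length_512(self):
        # 1-layer variant of the preset: the sequence entering the encoder
        # is S+1 = 512 slots ([CLS] + 511 shortened rows)
        config = load_preset("lnm")
        config.encoder_layers = 1
        model = assemble(config)
        rng = np.random.default_rng(0)
        bag = FeatureBag(rng.normal(size=(20, config.d)), slide_id="s")
        assert model.params["pos_embed"].shape == (512, 768)
        _, caches = classify(model, bag)
        assert caches["encoder"][0].shape == (512, 512)

    def test_zero_depth_output_ignores_the_bag(self, rng):
        config = ModelConfig(S=4, h=8, k=2, d=6, encoder_layers=0, encoder_heads=2,
                             encoder_ffn_width=16, num_classes=2, seed=3)
        model = assemble(config)
        p1, _ = classify(model, FeatureBag(rng.normal(size=(5, 6))))
        p2, _ = classify(model, FeatureBag(rng.normal(size=(30, 6)) * 10))
        assert np.allclose(p1, p2)

    def test_unresolvable_backbone_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError, match="not found"):
            assemble(ModelConfig(S=2, h=4, k=2, d=3, encoder_layers=1,
                                 encoder_heads=2, encoder_ffn_width=8,
                                 backbone="/no/such/archive.npz"))


class TestClassify:
    def test_probabilities_normalized(self, small_model, small_bag):
        probs, caches = classify(small_model, small_bag)
        assert probs.shape == (3,)
        assert (probs >= 0).all() and abs(probs.sum() - 1) < 1e-6
        assert caches["seqshort"].shape == (4, 9)
        assert [a.shape for a in caches["encoder"]] == [(5, 5), (5, 5)]

    def test_permutation_invariance_without_location_encoding(self, small_model, small_bag, rng):
        perm = rng.permutation(small_bag.M)
        p1, _ = classify(small_model, small_bag)
        p2, _ = classify(small_model, small_bag.permuted(perm))
        assert np.abs(p1 - p2).max() < 1e-5

    def test_location_encoding_breaks_row_only_permutation(self, small_bag, rng):
        config = ModelConfig(S=4, h=8, k=2, d=6, encoder_layers=1, encoder_heads=2,
                             encoder_ffn_width=16, num_classes=2, pos_wsi=True, seed=9)
        model = assemble(config)
        # sharpen the query/key projections so attention is far from uniform
        # (at the tiny init scale it is nearly uniform and permutation
        # effects vanish below float precision)
        model.params["seqshort.wq"].data *= 60
        model.params["seqshort.wk"].data *= 60
        perm = rng.permutation(small_bag.M)
        p0, _ = classify(model, small_bag)
        # coords permuted together with rows: unchanged
        p1, _ = classify(model, small_bag.permuted(perm))
        assert np.abs(p0 - p1).max() < 1e-5
        # rows permuted, coords left in place: generally changes
        rows_only = FeatureBag(small_bag.features[perm], coords=small_bag.coords,
                               slide_id="rows_only")
        p2, _ = classify(model, rows_only)
        # tiny init scales damp the effect strongly downstream, but the
        # mismatch is orders of magnitude above the exact-invariance case
        assert np.abs(p0 - p2).max() > 1e-12
        assert np.abs(p0 - p2).max() > 1000 * np.abs(p0 - p1).max()

    def test_pos_wsi_requires_coords(self):
        config = ModelConfig(S=2, h=4, k=2, d=4, encoder_layers=0, encoder_heads=2,
                             encoder_ffn_width=8, pos_wsi=True)
        model = assemble(config)
        with pytest.raises(ConfigurationError, match="coordinates"):
            classify(model, FeatureBag(np.zeros((3, 4)) + 1.0))

    def test_feature_width_mismatch(self, small_model, rng):
        with pytest.raises(ShapeError, match="d=9"):
            classify(small_model, FeatureBag(rng.normal(size=(4, 9))))


class TestParameterAccounting:
    def test_selection_partitions_all_parameters(self, small_model):
        sel = select_trainable(small_model, "normalization-only")
        names = [n for g in sel.groups.values() for n in g["names"]]
        assert sorted(names) == sorted(small_model.params.keys())
        assert sel.total == sum(t.size for t in small_model.params.values())

    @pytest.mark.parametrize(
        "layers,h,ffn",
        [(12, 768, 3072), (2, 64, 128), (3, 12, 20)],
    )
    def test_encoder_counts_match_closed_forms(self, layers, h, ffn):
        heads = 4 if h % 4 == 0 else 2
        config = ModelConfig(S=2, h=h, k=heads, d=5, encoder_layers=layers,
                             encoder_heads=heads, encoder_ffn_width=ffn, seed=0)
        model = assemble(config)
        sel = select_trainable(model, "normalization-only")
        attn = 4 * (h * h + h)
        ffn_count = h * ffn + ffn + ffn * h + h
        norms = 2 * 2 * h
        assert sel.groups["encoder_backbone"]["count"] == layers * (attn + ffn_count)
        assert sel.groups["encoder_norm"]["count"] == layers * norms

    def test_policies(self, small_model):
        sel_all = select_trainable(small_model, "all")
        assert sel_all.trainable == sel_all.total
        sel_head = select_trainable(small_model, "head-only")
        assert sel_head.trainable == sel_head.groups["head"]["count"]
        sel_norm = select_trainable(small_model, "normalization-only")
        assert not sel_norm.groups["encoder_backbone"]["trainable"]
        with pytest.raises(ConfigurationError):
            select_trainable(small_model, "bogus")

    def test_count_parameters_fraction(self, small_model):
        sel = select_trainable(small_model, "normalization-only")
        total, trainable, frac = count_parameters(sel)
        assert total == sel.total and trainable == sel.trainable
        assert frac == pytest.approx(trainable / total)


class TestFlops:
    CONFIG = ModelConfig(S=256, h=768, k=4, d=1280, encoder_layers=12,
                         encoder_heads=12, encoder_ffn_width=3072)

    def test_encoder_cost_constant_in_bag_size(self):
        a = estimate_flops(self.CONFIG, 1_000)
        b = estimate_flops(self.CONFIG, 10_000)
        assert a.encoder_flops == b.encoder_flops
        assert b.seqshort_flops > a.seqshort_flops

    def test_seqshort_cost_affine_in_bag_size(self):
        f = lambda M: estimate_flops(self.CONFIG, M).seqshort_flops
        assert f(2_000) - f(1_000) == f(3_000) - f(2_000)

    def test_unshortened_self_attention_is_quadratic(self):
        # hypothetical encoder running directly on the full bag
        quad = lambda M: encoder_mac_count(M, 12, 768, 3072) - 12 * (
            4 * M * 768**2 + 2 * M * 768 * 3072
        )
        assert quad(2_000) == 4 * quad(1_000)
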