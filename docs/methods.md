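# Methods

## Problem setting

A whole-slide image (WSI) in a multiple-instance-learning (MIL) setting is
an unordered bag of `M` patch feature vectors `X ∈ R^{M×d}` with a single
slide-level label; `M` varies from hundreds to many thousands of patches
per slide.  Running a deep transformer directly over the bag costs
`O(M²)` per self-attention layer and forfeits standard positional
embeddings, because the bag has no canonical order.  This package
implements a *sequence-shortening* front end that fixes both problems,
plus the classification, training and interpretability machinery around
it.

## The shortening layer

A learnable matrix of `S` query vectors `Q_l ∈ R^{S×h}` cross-attends over
the bag through a `k`-head attention layer:

    X_S    = Concat(head_1, …, head_k) W^O + Q_l                 (S×h)
    head_i = softmax(Q_l W_i^Q (X W_i^K)^T / √d_h) · X W_i^V

`W_i^Q : h→h/k`, `W_i^K, W_i^V : d→h/k`, `W^O : h→h`.  Each query row
aggregates the patches it "agrees with", so the output is a fixed-length
*ordered* sequence regardless of `M` and of the arrangement of patches —
softmax and the value-weighted sum act per query along the key/value
axis, giving exact permutation invariance.  The residual `+ Q_l` keeps
each output row anchored to its query.

Design points the layer's definition leaves open, and the choices made:

- **Scaling denominator `d_h`** — the per-head width `h/k` by default
  (the standard multi-head convention); an override is exposed so the
  full hidden width `h` can be used instead.  Both variants are covered
  by the oracle tests.
- **Per-head width** — `h/k`, concatenated back to `h`.
- **Biases** — additive biases on all four projections, toggleable
  (`bias` in the config).
- **Initialization** — all learnable tensors are zero-mean Gaussian with
  standard deviation 0.02 (biases zero), drawn from a single seeded
  generator so one config seed fixes the whole model.
- **`M = 0`** — rejected with a validation error: a slide with no tissue
  tiles is not classifiable.
- **Numerics** — softmax subtracts the row maximum before
  exponentiation; all computation is float64.

The analytic multiply–accumulate count of one pass is affine in `M`
(`2Sh²` constant, `(2dh + 2Sh)·M` slope), so the layer is `O(M)` while
the downstream encoder cost depends only on the fixed length `S+1`.

## Classifier assembly

Ordering of the forward pass: optional 2-D patch-location sinusoid added
to the raw features → shortening → prepend a learnable `[CLS]` vector →
add learnable positional embeddings over all `S+1` slots (the `[CLS]`
slot included) → `encoder_layers` post-norm transformer blocks
(BERT-class: self-attention and a GELU feed-forward, each wrapped in
residual + layer norm) → a one-hidden-layer GELU MLP head on the final
`[CLS]` representation.

The patch-location encoding devotes the first `d/2` channels to the tile
row index and the last `d/2` to the column index, each an interleaved
sine/cosine ramp with geometric wavelengths between 1 and 10000.  It is
parameter-free; with it enabled, permuting patches together with their
coordinates leaves the output unchanged while permuting patches alone
does not.

Two presets ship as YAML: `lnm` (S=511, so the encoder sees 512 slots)
and `subtype` (S=256); both use h=768, k=4, a 12-layer/12-head/FFN-3072
encoder, and `d=1280` input features (the width of the large
EfficientNetV2-class patch embedders commonly used for WSI tiles).

**Trainability policies.**  Parameters partition exhaustively into six
groups: `seqshort`, `cls`, `pos_embed`, `encoder_norm` (all layer-norm
scale/shift), `encoder_backbone` (attention + FFN weights), `head`.
Under `normalization-only` — the parameter-efficient regime this model
targets — `encoder_backbone` is frozen and everything else trains.  For
the 12×768×3072 encoder that is 36,864 trainable out of 85,054,464
encoder parameters (0.04%).  `head-only` and `all` are also provided.
Pretrained encoder weights can be injected through a named-weights
`.npz` adapter that ignores non-encoder keys (e.g. a vocabulary table);
all tests use the seeded scratch-random backbone.

## Interpretability

**Modified attention rollout.**  Standard rollout multiplies per-layer
head-mean attention matrices.  Here the `[CLS]` token did not exist in
the shortening attention, so the base case stacks a zero row on top of
the shortener's `S×M` map: `A~_0 = [0; A_0]`, then `A~_i = A_i · A~_{i-1}`
over the encoder layers; the `[CLS]` row of the final product is the
per-patch relevance.  Heads are averaged before the chain product
(max-over-heads is a one-line change in the caches).  The recursion is
implemented literally by default; an opt-in `residual_mixing` flag
averages each encoder matrix with the identity (rows renormalized)
before multiplying, the convention of the residual-aware rollout
literature — both modes are tested against their own chain-product
oracles.  Useful identity for validation: with one encoder layer, row
`r` of the final matrix sums to `1 − A_1[r, CLS]`, the mass lost to the
zero row.

**Redundancy diagnostics.**  `kl_from_uniform` is `Σ p_j ln(M p_j)` in
nats (`0·ln 0 := 0`); `query_rank_correlation` computes Spearman's rank
correlation (ties → average ranks) between every pair of query rows'
patch rankings and summarizes the off-diagonal pairs (mean, min,
fraction above 0.7).  A constant row has no ranking; its correlations
are reported as 0.  Because per-slide KL curves can be aggregated
per-query or pooled, the CLI-level diagnostic simply reports per-row
values and leaves aggregation to the caller.

**Heatmaps.**  Relevance is min–max normalized per slide and painted on
the tile grid (one `tile_size`-pixel cell per patch, inferno ramp,
unoccupied cells transparent).  All-equal relevance renders flat at the
0.5 level by convention.  The CSV score table
(`row,col,score,normalized`) round-trips exactly (`repr` precision).

## Preprocessing

Tissue is segmented on the thumbnail by Otsu-thresholding the HSV
saturation channel (stained tissue is saturated; glass, which is near
white, is not) followed by morphological closing (radius 2 by default).
A single-color thumbnail yields an empty mask, not an error.  Tiles of
256×256 pixels are laid on a fixed grid anchored at pixel (0,0) of the
working magnification; grid coordinates are 0-based `(row, col) =
(y/256, x/256)` with half-open pixel boxes; edge tiles that do not fit
entirely are dropped; a tile is kept iff its mask coverage is at least
`min_tissue` (default 0.5).  Slides are read as pyramidal TIFFs; if the
requested power (×10/×20) is absent from the pyramid the nearest
higher-resolution level is block-averaged down.  The built-in test
embedder projects 30 per-tile channel statistics (means, standard
deviations, 8-bin histograms) through a seeded random matrix — useful
for deterministic end-to-end tests, not a substitute for a real patch
encoder.  Bag rows are sorted by `(row, col)` so re-tiling is
reproducible.

## Training

Cross-entropy on the head logits, Adam (β₁=0.9, β₂=0.999, ε=1e-8).  The
schedule ramps linearly 0 → `max_lr` over the warm-up epochs, then runs
`cosine_cycles` equal-length half-cosine decays `max_lr → 0`, each cycle
restarting at `max_lr`.  Shipped presets: `lnm` — 200 epochs, 5 warm-up,
1 cycle, max 1e-4, batch 16; `subtype` — 200 epochs, 10 warm-up,
2 cycles, max 5e-5, batch 32.  Bags of unequal size are processed one
per forward pass with gradients accumulated to the configured batch
size (padding masks are unnecessary this way).  Only the parameters
flagged by the trainability selection are updated; frozen tensors are
bit-identical before and after a run (asserted in tests).  Training is
fully reproducible from the plan seed.

AUROC is the evaluation metric: rank-based with ties counted half for
binary tasks, the unweighted mean of one-vs-rest areas for multiclass.
Cross-validation assigns *patients* (all their slides together) to folds
by seeded round-robin within each class, so per-fold class counts are
within one patient of perfect stratification; a class with fewer
patients than folds triggers a warning and best-effort assignment.

The neural stack (shortener, encoder, training) runs on a small
reverse-mode autodiff engine over NumPy arrays written for this package
(`_autograd.py`); every operation's gradient is checked against central
finite differences in the test suite.

## Synthetic data generator

The generator emulates the MIL structure the method exploits — heavy
redundancy plus a small informative subset.  A fixed pool of
`pool_size` isotropic Gaussian background vectors (std `noise_std`) is
shared across classes; each bag draws its patches from the pool with
replacement (redundancy), and a Binomial(M, π) subset is shifted by
`signal_strength · noise_std` along a class-specific direction (the
class directions are mutually orthonormal, from a seeded QR rotation).
Bag sizes are Gaussian around `bag_size_mean` (coefficient of variation
`bag_size_dispersion`, floored at `bag_size_min`).  Ground-truth
per-patch indicators are stored as `signal_mask`.  Defaults: 2 classes,
200 bags, mean size 200, d=32, π=0.05, strength 4, pool 2000 — a
planted-signal regime in which a mean-pooling linear probe (the
generator's independent acceptance oracle) reaches AUROC ≳ 0.95, while
π=0 is exactly uninformative by construction.

What the generator does *not* model: real histology feature statistics,
spatial correlation between neighboring tiles, staining/scanner
variation, class-dependent bag sizes.  Passing the end-to-end tests
therefore demonstrates that the mechanism recovers planted bag-level
signal through the shortening bottleneck — not clinical performance.

## Scaled-down study sizes

The end-to-end checks train a 2-layer, h=64, k=4, S=16, d=32 model for
30 epochs (warm-up 3, one cosine cycle, max lr 1e-3, batch 16) on 200
generated bags with a 75/25 stratified split, repeated over three seeds
with the median reported, against a π=0 control under the same
protocol.  These sizes keep a full multi-seed study comfortably
reproducible on a single CPU while leaving the planted-signal recovery
(held-out AUROC ≥ 0.9 vs chance-level control) unambiguous.

## Known limitations

- The encoder is BERT-class post-norm only; pre-norm and rotary/ALiBi
  position variants are out of scope.
- No sparse/windowed attention inside the shortener: the full `S×M`
  attention is materialized (linear in `M`, but with a large constant
  for very large bags).
- The tissue segmenter is a deliberately simple saturation/Otsu rule;
  pen marks and coverslip artifacts are not detected.
- The NumPy training path is single-threaded and CPU-bound; it is meant
  for method-scale experiments and tests, not for training the
  full-width presets.
- The paper-scale figure of ~3.3M trainable parameters for a complete
  deployed model depends on head shape and embedder width conventions
  not fixed here; the package treats exact parameter accounting as
  authoritative only for the encoder groups it assembles itself.
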