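# seqshort

Weakly supervised whole-slide-image (WSI) classification built around an
attention-based **sequence-shortening layer**: a fixed set of `S`
learnable query vectors cross-attends over the unordered bag of `M`
patch feature vectors from one slide and compresses it into a short,
*ordered* `S×h` sequence

```
X_S    = Concat(head_1, …, head_k) W^O + Q_l
head_i = softmax(Q_l W_i^Q (X W_i^K)^T / √d_h) · X W_i^V
```

that any standard transformer encoder can then classify.  Because the
queries are fixed and the softmax runs along the patch axis, the layer
is exactly permutation-invariant, costs `O(M)`, and makes the deep
encoder's cost *constant* in the slide size — which in turn makes it
practical to reuse large frozen encoders while fine-tuning only their
layer-norm parameters (36,864 out of 85M for a 12-layer, width-768
encoder: 0.04%).

The package is aimed at computational-pathology researchers working on
multiple-instance learning: it provides the shortening layer, the full
classifier (2-D patch-location sinusoids, `[CLS]` token, learnable
positional embeddings, frozen-backbone policies), a modified
attention-rollout pass that traces decisions back to individual patches
through the shortening bottleneck, attention-redundancy diagnostics
(KL-from-uniform, pairwise Spearman rank agreement of queries), slide
tiling/masking/embedding, a seeded training loop with warm-up + cosine
schedules, and a synthetic bag generator with planted signal for
end-to-end validation.  The neural stack runs on a small NumPy
reverse-mode autodiff engine included in the package; no GPU is needed
for the shipped experiments.

## Worked example

Train the scaled-down classifier on synthetic bags (200 bags, ~200
patches each, 5% of patches carrying a class-specific mean shift), then
ask the rollout where the decision came from:

```python
import numpy as np
from seqshort import *
from seqshort.interpret import modified_attention_rollout

dataset = generate_dataset(SyntheticSpec(seed=1))
print(f"linear-probe AUROC: {linear_probe_oracle(dataset, seed=1):.3f}")

config = ModelConfig(S=16, h=64, k=4, d=32, encoder_layers=2, encoder_heads=4,
                     encoder_ffn_width=128, num_classes=2, seed=1)
model = assemble(config)
selection = select_trainable(model, "normalization-only")
total, trainable, frac = count_parameters(selection)
print(f"parameters: {total:,} total, {trainable:,} trainable ({100*frac:.1f}%)")

train_set, test_set = stratified_split(dataset, test_fraction=0.25, seed=1)
plan = TrainingPlan(epochs=30, warmup_epochs=3, cosine_cycles=1,
                    max_lr=1e-3, batch_size=16, seed=1)
train(model, train_set, plan)

scores = np.stack([classify(model, bag)[0] for bag in test_set])
print(f"held-out AUROC: {evaluate_auroc(scores[:, 1], test_set.labels):.3f}")

bag = test_set[0]
probs, caches = classify(model, bag)
relevance = modified_attention_rollout(caches["seqshort"], caches["encoder"])
sig = relevance.per_patch[bag.signal_mask].mean()
bg = relevance.per_patch[~bag.signal_mask].mean()
print(f"bag {bag.slide_id}: P(class 1) = {probs[1]:.3f}, "
      f"relevance signal/background = {sig/bg:.1f}x")
```

Output (about 30 s on one CPU):

```
linear-probe AUROC: 0.976
parameters: 85,954 total, 19,522 trainable (22.7%)
held-out AUROC: 1.000
bag synthetic_0003: P(class 1) = 0.999, relevance signal/background = 5.8x
```

Reading the numbers: the mean-pooling linear probe confirms the
generated dataset is separable (0.976) before any attention model is
involved; the trained shortening classifier reaches held-out AUROC 1.0
from slide-level labels only; and the rollout relevance of the planted
signal patches is ~6× that of background patches — the model is looking
at the right tiles.

The same pipeline is available from the shell:

```
seqshort simulate --seed 1 --out bags.h5
seqshort train --config subtype --data bags.h5 --seed 1 --out run/
seqshort evaluate --ckpt run/checkpoint --data bags.h5
seqshort explain --ckpt run/checkpoint --data bags.h5 --out maps/
seqshort inspect --data bags.h5 --config subtype
```

`simulate`/`preprocess` write one HDF5 group per slide (`features`
`M×d` float32, `coords` `M×2` int, attributes `slide_id`, `label`,
`magnification`); `explain` writes one PNG heatmap and one CSV score
table per bag plus a re-runnable manifest.  Model presets `lnm`
(S=511) and `subtype` (S=256) ship as YAML.

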