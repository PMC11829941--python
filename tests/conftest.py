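import numpy as np
import pytest

from seqshort import FeatureBag, ModelConfig, assemble
from seqshort.shortener import QuerySet, ShortenerWeights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bag(rng):
    coords = np.stack([np.arange(9) // 3, np.arange(9) % 3], axis=1)
    return FeatureBag(
        features=rng.normal(size=(9, 6)), coords=coords, slide_id="bag9", label=1
    )


@pytest.fixture
def small_model():
    config = ModelConfig(
        S=4,
        h=8,
        k=2,
        d=6,
        encoder_layers=2,
        encoder_heads=2,
        encoder_ffn_width=16,
        num_classes=3,
        seed=7,
    )
    return assemble(config)


def random_shortener(d, h, k, rng, bias=True, d_h=None):
    return (
        ShortenerWeights.init(d=d, h=h, k=k, rng=rng, bias=bias, d_h=d_h),
        QuerySet.init(rng.integers(1, 6), h, rng),
    )


def brute_force_shorten(X, w: ShortenerWeights, Q: np.ndarray) -> np.ndarray:
    """Independent dense recomputation of the shortening attention layer.

    Explicit per-head loop: plain softmax and matrix products, no code
    shared with the package's implementation.
    """
    heads = []
    for i in range(w.k):
        q = Q @ w.wq[i] + (w.bq[i] if w.bq is not None else 0.0)
        kk = X @ w.wk[i] + (w.bk[i] if w.bk is not None else 0.0)
        vv = X @ w.wv[i] + (w.bv[i] if w.bv is not None else 0.0)
        scores = q @ kk.T / np.sqrt(w.d_h)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        heads.append(p @ vv)
    return np.concatenate(heads, axis=1) @ w.wo + (
        w.bo if w.bo is not None else 0.0
    ) + Q


def brute_force_rollout(seqshort_attention, encoder_attentions):
    """Naive chain product oracle for the modified rollout."""
    S, M = seqshort_attention.shape
    acc = np.concatenate([np.zeros((1, M)), seqshort_attention], axis=0)
    for a in encoder_attentions:
        acc = np.asarray(a) @ acc
    return acc


def random_row_stochastic(rows, cols, rng):
    m = rng.uniform(0.05, 1.0, size=(rows, cols))
    return m / m.sum(axis=1, keepdims=True)
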