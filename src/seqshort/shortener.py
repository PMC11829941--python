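"""Sequence shortening by cross-attention from learnable queries.

A fixed set of ``S`` learnable query vectors attends over the arbitrary-
length bag of ``M`` patch features ``X`` (``M x d``) through a ``k``-head
attention layer, producing a fixed-length ordered summary

    X_S = Concat(head_1, ..., head_k) W^O + Q_l,          (S x h)
    head_i = softmax(Q_l W_i^Q (X W_i^K)^T / sqrt(d_h)) X W_i^V,

where ``Q_l`` is the ``S x h`` query matrix and the ``W`` are learnable
projections.  Because softmax and the value-weighted sum are computed
independently per query over the key/value axis, the output is invariant
to any permutation of the patches: the layer *sorts* the unordered bag
into a canonical ordered sequence, one row per query.

The scaling denominator ``d_h`` defaults to the per-head width ``h/k``
(the usual multi-head convention); it can be overridden, e.g. with the
full hidden width ``h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, softmax
from .bags import FeatureBag
from .errors import ShapeError, ValidationError

__all__ = [
    "QuerySet",
    "ShortenerWeights",
    "ShortSequence",
    "AttentionMap",
    "shorten",
    "sorted_aggregation_check",
    "seqshort_mac_count",
]

#: standard deviation used for all query / projection initializations
INIT_STD = 0.02


@dataclass
class QuerySet:
    """The learnable ``S x h`` query matrix ``Q_l``."""

    queries: np.ndarray  # (S, h)

    def __post_init__(self):
        self.queries = np.asarray(self.queries, dtype=np.float64)
        if self.queries.ndim != 2 or min(self.queries.shape) < 1:
            raise ShapeError("queries must be a non-empty S x h matrix")
        if not np.isfinite(self.queries).all():
            raise ValidationError("queries contain non-finite values")

    @property
    def S(self) -> int:
        return self.queries.shape[0]

    @property
    def h(self) -> int:
        return self.queries.shape[1]

    @classmethod
    def init(cls, S: int, h: int, rng: np.random.Generator) -> "QuerySet":
        return cls(rng.normal(0.0, INIT_STD, size=(S, h)))


@dataclass
class ShortenerWeights:
    """Per-head projections of the shortening attention layer.

    ``wq``: (k, h, h/k); ``wk``, ``wv``: (k, d, h/k); ``wo``: (h, h);
    optional biases ``bq``/``bk``/``bv``: (k, h/k) and ``bo``: (h,).
    """

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    wo: np.ndarray
    bq: np.ndarray | None = None
    bk: np.ndarray | None = None
    bv: np.ndarray | None = None
    bo: np.ndarray | None = None
    d_h: float | None = None  # scaling denominator; default h/k

    def __post_init__(self):
        for name in ("wq", "wk", "wv", "wo"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        k, h, dh = self.wq.shape
        if h != k * dh:
            raise ShapeError(f"head count k={k} must divide h={h} (per-head width {dh})")
        d = self.wk.shape[1]
        if self.wk.shape != (k, d, dh) or self.wv.shape != (k, d, dh):
            raise ShapeError(
                f"wk/wv must be (k, d, h/k)=({k}, {d}, {dh}), got {self.wk.shape}, {self.wv.shape}"
            )
        if self.wo.shape != (h, h):
            raise ShapeError(f"wo must be (h, h)=({h}, {h}), got {self.wo.shape}")
        for name in ("bq", "bk", "bv", "bo"):
            b = getattr(self, name)
            if b is not None:
                setattr(self, name, np.asarray(b, dtype=np.float64))
        for arr in (self.wq, self.wk, self.wv, self.wo):
            if not np.isfinite(arr).all():
                raise ValidationError("projection weights contain non-finite values")
        if self.d_h is None:
            self.d_h = float(dh)
        if self.d_h <= 0:
            raise ValidationError("scaling denominator d_h must be positive")

    @property
    def k(self) -> int:
        return self.wq.shape[0]

    @property
    def h(self) -> int:
        return self.wq.shape[1]

    @property
    def d(self) -> int:
        return self.wk.shape[1]

    @classmethod
    def init(
        cls,
        d: int,
        h: int,
        k: int,
        rng: np.random.Generator,
        bias: bool = True,
        d_h: float | None = None,
    ) -> "ShortenerWeights":
        if h % k:
            raise ShapeError(f"head count k={k} must divide h={h}")
        dh = h // k
        z = lambda *s: rng.normal(0.0, INIT_STD, size=s)
        return cls(
            wq=z(k, h, dh),
            wk=z(k, d, dh),
            wv=z(k, d, dh),
            wo=z(h, h),
            bq=np.zeros((k, dh)) if bias else None,
            bk=np.zeros((k, dh)) if bias else None,
            bv=np.zeros((k, dh)) if bias else None,
            bo=np.zeros(h) if bias else None,
            d_h=d_h,
        )


@dataclass
class ShortSequence:
    """The fixed-length ``S x h`` summary of one bag."""

    values: np.ndarray
    slide_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValidationError("short sequence contains non-finite values")


@dataclass
class AttentionMap:
    """Row-stochastic query-over-patch attention: per head and head-mean."""

    per_head: np.ndarray  # (k, S, M)
    head_mean: np.ndarray = field(init=False)

    def __post_init__(self):
        self.per_head = np.asarray(self.per_head, dtype=np.float64)
        if self.per_head.ndim != 3:
            raise ShapeError("per-head attention must be (k, S, M)")
        self.head_mean = self.per_head.mean(axis=0)
        if (self.per_head < -1e-12).any():
            raise ValidationError("attention weights must be non-negative")
        sums = self.per_head.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError("attention rows must sum to 1 within 1e-6")


def _shorten_graph(
    x: Tensor,
    queries: Tensor,
    wq: Tensor,
    wk: Tensor,
    wv: Tensor,
    wo: Tensor,
    bq: Tensor | None,
    bk: Tensor | None,
    bv: Tensor | None,
    bo: Tensor | None,
    d_h: float,
) -> tuple[Tensor, np.ndarray]:
    """Differentiable core shared by inference and training paths.

    Returns the ``S x h`` output tensor and the ``(k, S, M)`` attention
    probabilities as a plain array.
    """
    k, h, dh = wq.shape
    S = queries.shape[0]
    q = queries @ wq  # (k, S, dh) via broadcasting
    kk = x @ wk  # (k, M, dh)
    v = x @ wv
    if bq is not None:
        q = q + bq.reshape(k, 1, dh)
        kk = kk + bk.reshape(k, 1, dh)
        v = v + bv.reshape(k, 1, dh)
    scores = (q @ kk.transpose(0, 2, 1)) * (1.0 / np.sqrt(d_h))  # (k, S, M)
    probs = softmax(scores, axis=-1)
    heads = probs @ v  # (k, S, dh)
    concat = heads.transpose(1, 0, 2).reshape(S, h)
    out = concat @ wo
    if bo is not None:
        out = out + bo
    out = out + queries
    return out, probs.data.copy()


def shorten(
    bag: FeatureBag, weights: ShortenerWeights, queries: QuerySet
) -> tuple[ShortSequence, AttentionMap]:
    """Compress one bag into its fixed-length ordered summary.

    Deterministic given the weights; the attention map returned alongside
    holds the row-stochastic softmax factors, per head and head-averaged.
    """
    if bag.d != weights.d:
        raise ShapeError(
            f"feature axis mismatch: bag d={bag.d} but key/value projections expect d={weights.d}"
        )
    if queries.h != weights.h:
        raise ShapeError(
            f"hidden axis mismatch: queries h={queries.h} but projections produce h={weights.h}"
        )
    wrap = lambda a: None if a is None else Tensor(a)
    out, probs = _shorten_graph(
        Tensor(bag.features),
        Tensor(queries.queries),
        Tensor(weights.wq),
        Tensor(weights.wk),
        Tensor(weights.wv),
        Tensor(weights.wo),
        wrap(weights.bq),
        wrap(weights.bk),
        wrap(weights.bv),
        wrap(weights.bo),
        weights.d_h,
    )
    return ShortSequence(out.data, slide_id=bag.slide_id), AttentionMap(probs)


def sorted_aggregation_check(
    bagA: FeatureBag,
    bagB: FeatureBag,
    weights: ShortenerWeights,
    queries: QuerySet,
    tol: float = 1e-5,
) -> bool:
    """True iff the two bags shorten to the same sequence within ``tol``.

    Intended for a bag and a row permutation of it: the attention sorting
    effect makes the summary independent of patch order.
    """
    if bagA.M != bagB.M or bagA.d != bagB.d:
        raise ValidationError(
            f"bags differ in shape: ({bagA.M}, {bagA.d}) vs ({bagB.M}, {bagB.d})"
        )
    outA, _ = shorten(bagA, weights, queries)
    outB, _ = shorten(bagB, weights, queries)
    return bool(np.abs(outA.values - outB.values).max() <= tol)


def seqshort_mac_count(M: int, S: int, h: int, d: int, k: int, bias: bool = True) -> int:
    """Analytic multiply-accumulate count of one shortening pass.

    Affine in the bag size ``M``: queries and the output projection cost
    ``2 S h^2`` independent of ``M``; key/value projections and the two
    attention products contribute ``(2 d h + 2 S h) M``.
    """
    dh = h // k
    macs = k * S * h * dh  # query projections
    macs += 2 * k * M * d * dh  # key and value projections
    macs += k * S * M * dh  # score products
    macs += k * S * M * dh  # attention-weighted values
    macs += S * h * h  # output projection
    return int(macs)
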