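"""Attention interpretability: modified rollout and redundancy diagnostics.

Attention rollout traces a transformer's output back to its inputs by
multiplying the per-layer (head-mean) attention matrices.  Because the
[CLS] token is prepended *after* the shortening layer, the base case is
modified: the initial accumulated matrix stacks an all-zero row (the
[CLS] slot, which saw no patches) on top of the shortener's ``S x M``
query-over-patch attention,

    A~_0 = [0; A_0],        A~_i = A_i . A~_{i-1}  (i > 0),

and the [CLS] row of the final accumulated matrix is the per-patch
relevance of the classification decision.

Two diagnostics quantify redundancy across the learned queries: the KL
divergence of each query's attention distribution from uniform (0 =
evenly spread, ln M = one-hot) and the Spearman rank agreement between
the patch rankings induced by pairs of queries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .bags import FeatureBag
from .errors import ShapeError, ValidationError

__all__ = [
    "RolloutState",
    "RelevanceMap",
    "modified_attention_rollout",
    "kl_from_uniform",
    "query_rank_correlation",
    "render_heatmap",
    "write_score_table",
    "read_score_table",
]

_ROW_TOL = 1e-6


@dataclass
class RolloutState:
    """Accumulated attention product after ``layer_index`` encoder layers."""

    accumulated: np.ndarray  # (S+1, M)
    layer_index: int


@dataclass
class RelevanceMap:
    """Per-patch relevance (the [CLS] row of the final accumulated matrix)."""

    per_patch: np.ndarray  # (M,)
    coords: np.ndarray | None = None

    def __post_init__(self):
        self.per_patch = np.asarray(self.per_patch, dtype=np.float64)
        if self.per_patch.ndim != 1:
            raise ShapeError("relevance must be a length-M vector")
        if not np.isfinite(self.per_patch).all():
            raise ValidationError("relevance contains non-finite values")
        if (self.per_patch < -1e-12).any():
            raise ValidationError("relevance must be non-negative")


def _check_row_stochastic(mat: np.ndarray, what: str) -> None:
    if (mat < -_ROW_TOL).any():
        raise ValidationError(f"{what}: negative attention weights")
    sums = mat.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=_ROW_TOL):
        worst = float(np.abs(sums - 1.0).max())
        raise ValidationError(f"{what}: rows must sum to 1 (worst deviation {worst:.2e})")


def _mix_residual(a: np.ndarray) -> np.ndarray:
    """0.5*A + 0.5*I, rows renormalized — the residual-aware rollout variant."""
    mixed = 0.5 * a + 0.5 * np.eye(a.shape[0])
    return mixed / mixed.sum(axis=-1, keepdims=True)


def modified_attention_rollout(
    seqshort_attention: np.ndarray,
    encoder_attentions: list[np.ndarray],
    coords: np.ndarray | None = None,
    residual_mixing: bool = False,
) -> RelevanceMap:
    """Roll attention back through the encoder and the shortening layer.

    ``seqshort_attention``: head-mean ``S x M`` query-over-patch map.
    ``encoder_attentions``: head-mean ``(S+1) x (S+1)`` self-attention of
    each encoder layer, in forward order.  With an empty encoder list the
    relevance is the (all-zero) [CLS] row of the base case.

    ``residual_mixing`` averages each encoder matrix with the identity
    before multiplying (accounting for residual connections); the base
    case is used as-is in both modes.
    """
    a0 = np.asarray(seqshort_attention, dtype=np.float64)
    if a0.ndim != 2:
        raise ShapeError("shortener attention must be S x M")
    _check_row_stochastic(a0, "shortener attention")
    S, M = a0.shape
    acc = np.vstack([np.zeros((1, M)), a0])  # (S+1, M), zero [CLS] row
    for i, a in enumerate(encoder_attentions):
        a = np.asarray(a, dtype=np.float64)
        if a.shape != (S + 1, S + 1):
            raise ShapeError(
                f"encoder attention {i} must be ({S + 1}, {S + 1}), got {a.shape}"
            )
        _check_row_stochastic(a, f"encoder attention {i}")
        if residual_mixing:
            a = _mix_residual(a)
        acc = a @ acc
    return RelevanceMap(per_patch=acc[0], coords=coords)


def kl_from_uniform(attention_row: np.ndarray) -> float:
    """KL divergence (nats) of one attention distribution from uniform.

    ``sum_j p_j ln(M p_j)`` with ``0 ln 0 := 0``; ranges from 0 (uniform)
    to ``ln M`` (one-hot).
    """
    p = np.asarray(attention_row, dtype=np.float64)
    if p.ndim != 1:
        raise ShapeError("attention row must be a 1-D probability vector")
    if (p < -_ROW_TOL).any() or not np.isfinite(p).all():
        raise ValidationError("attention row must be a non-negative finite vector")
    total = p.sum()
    if abs(total - 1.0) > _ROW_TOL:
        raise ValidationError(f"attention row sums to {total:.6f}, not 1")
    M = p.size
    nz = p > 0
    return float(np.sum(p[nz] * np.log(M * p[nz])))


@dataclass
class RankAgreement:
    """Pairwise Spearman agreement between the queries' patch rankings."""

    matrix: np.ndarray  # (S, S)
    mean: float
    min: float
    fraction_above: float  # fraction of off-diagonal pairs with rho > threshold
    threshold: float = 0.7


def query_rank_correlation(
    attention: np.ndarray, threshold: float = 0.7
) -> RankAgreement:
    """Spearman rank correlation between every pair of query rows.

    Ties get average ranks.  The summary statistics (mean, min, fraction
    of pairs above ``threshold``) are computed over the ``S(S-1)/2``
    off-diagonal pairs.
    """
    a = np.asarray(attention, dtype=np.float64)
    if hasattr(attention, "head_mean"):  # accept an AttentionMap directly
        a = np.asarray(attention.head_mean, dtype=np.float64)
    if a.ndim != 2:
        raise ShapeError("attention must be S x M")
    S, M = a.shape
    if M < 2:
        raise ValidationError("patch ranking undefined for M < 2")
    ranks = np.apply_along_axis(rankdata, 1, a)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=1))
    # constant rows (all ties) have zero rank variance; correlation with
    # anything is undefined — define it as 0 off-diagonal
    safe = np.where(denom > 0, denom, 1.0)
    corr = (rc @ rc.T) / np.outer(safe, safe)
    corr[denom == 0, :] = 0.0
    corr[:, denom == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    iu = np.triu_indices(S, k=1)
    off = corr[iu]
    if off.size == 0:
        return RankAgreement(corr, 1.0, 1.0, 1.0, threshold)
    return RankAgreement(
        matrix=corr,
        mean=float(off.mean()),
        min=float(off.min()),
        fraction_above=float((off > threshold).mean()),
        threshold=threshold,
    )


# ----------------------------------------------------------------------
def _normalize(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi - lo == 0:
        # all-equal relevance: flat map at mid-level by convention
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)


def render_heatmap(relevance: RelevanceMap, tile_size: int = 16):
    """Rasterize per-patch relevance on the tile grid.

    Returns ``(image, table)``: an RGBA array of
    ``(max_row+1)*tile_size x (max_col+1)*tile_size`` pixels with each
    occupied cell colored by min-max-normalized relevance (inferno-like
    ramp) and unoccupied cells transparent, plus the score table rows
    ``(row, col, raw, normalized)``.
    """
    if relevance.coords is None:
        raise ValidationError("heatmap rendering requires tile coordinates")
    coords = np.asarray(relevance.coords)
    scores = relevance.per_patch
    norm = _normalize(scores)
    nrow = int(coords[:, 0].max()) + 1
    ncol = int(coords[:, 1].max()) + 1
    img = np.zeros((nrow * tile_size, ncol * tile_size, 4), dtype=np.uint8)
    from matplotlib import cm

    colors = (cm.inferno(norm)[:, :3] * 255).astype(np.uint8)
    table = []
    for (r, c), raw, nv, col in zip(coords.tolist(), scores, norm, colors):
        img[r * tile_size : (r + 1) * tile_size, c * tile_size : (c + 1) * tile_size, :3] = col
        img[r * tile_size : (r + 1) * tile_size, c * tile_size : (c + 1) * tile_size, 3] = 255
        table.append((int(r), int(c), float(raw), float(nv)))
    return img, table


def write_score_table(table, path) -> None:
    with open(path, "w") as f:
        f.write("row,col,score,normalized\n")
        for r, c, raw, nv in table:
            f.write(f"{r},{c},{raw!r},{nv!r}\n")


def read_score_table(path):
    rows = []
    with open(path) as f:
        next(f)
        for line in f:
            r, c, raw, nv = line.strip().split(",")
            rows.append((int(r), int(c), float(raw), float(nv)))
    return rows


def save_heatmap_png(img: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray(img, mode="RGBA").save(path)
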