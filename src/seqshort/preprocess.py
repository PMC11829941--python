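"""Slide-to-bag conversion: tissue masking, tiling and patch embedding.

Tissue is segmented on a slide thumbnail by Otsu-thresholding the HSV
saturation channel (stained tissue is saturated, glass background is
not) followed by morphological closing.  Tiles of ``tile_size`` pixels
are laid on a fixed grid anchored at pixel (0, 0) at the working
magnification; a tile is kept iff its tissue coverage reaches
``min_tissue``.  Kept tiles are embedded by a pluggable patch embedder
into one feature row each, ordered by (row, col), yielding the
``FeatureBag`` the classifier consumes.

Slides are read through :class:`Slide`, which wraps either a pyramidal
TIFF (levels resolved via ``tifffile`` series metadata) or an in-memory
array (used by tests and synthetic pipelines).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import closing as _closing
from skimage.morphology import disk

from .bags import FeatureBag
from .errors import ConfigurationError, ShapeError, ValidationError

__all__ = [
    "TileRecord",
    "Slide",
    "segment_tissue",
    "tile_slide",
    "embed_tiles",
    "ChannelStatsEmbedder",
    "tiles_to_csv",
]

TILE_SIZE = 256
#: nominal downsample of each magnification relative to a x40 base scan
_MAG_DOWNSAMPLE = {"x20": 2, "x10": 4}


@dataclass(frozen=True)
class TileRecord:
    """One kept tile: grid position, half-open pixel box, tissue coverage."""

    row: int
    col: int
    x0: int
    y0: int
    x1: int
    y1: int
    tissue_fraction: float


class Slide:
    """A pyramidal slide: full-resolution plane access plus a thumbnail."""

    def __init__(self, levels: list[np.ndarray], path: str = "<array>"):
        if not levels:
            raise ValidationError("slide has no image levels")
        self.levels = levels
        self.path = path

    @classmethod
    def from_array(cls, image: np.ndarray, n_levels: int = 3) -> "Slide":
        """Build a small pyramid from one RGB array by 2x block-averaging."""
        levels = [np.asarray(image)]
        for _ in range(n_levels - 1):
            prev = levels[-1].astype(np.float64)
            H, W = prev.shape[0] // 2 * 2, prev.shape[1] // 2 * 2
            ds = prev[:H:2, :W:2] / 4 + prev[1:H:2, :W:2] / 4 + prev[:H:2, 1:W:2] / 4 + prev[1:H:2, 1:W:2] / 4
            levels.append(ds.astype(image.dtype))
        return cls(levels)

    @classmethod
    def open(cls, path) -> "Slide":
        """Open a (tiled, possibly pyramidal) TIFF-based slide file."""
        import tifffile

        path = Path(path)
        try:
            with tifffile.TiffFile(path) as tif:
                series = tif.series[0]
                if hasattr(series, "levels") and len(series.levels) > 1:
                    levels = [lvl.asarray() for lvl in series.levels]
                else:
                    levels = [series.asarray()]
        except (OSError, ValueError) as e:
            raise OSError(f"cannot read slide '{path}': {e}") from e
        return cls(levels, path=str(path))

    @property
    def base_shape(self) -> tuple[int, int]:
        return self.levels[0].shape[:2]

    def thumbnail(self) -> np.ndarray:
        """The lowest-resolution pyramid level."""
        return self.levels[-1]

    def plane_at(self, magnification: str, base_magnification: str = "x40") -> np.ndarray:
        """Image plane at the requested power.

        The pyramid's downsample factors are taken from level shapes; if
        the exact power is missing, the nearest higher-resolution level
        is block-averaged down to it.
        """
        if magnification not in _MAG_DOWNSAMPLE:
            raise ConfigurationError(
                f"magnification must be one of {sorted(_MAG_DOWNSAMPLE)}, got '{magnification}'"
            )
        base = {"x40": 1, "x20": 2, "x10": 4}.get(base_magnification, 1)
        want = _MAG_DOWNSAMPLE[magnification] // base
        if want < 1:
            raise ConfigurationError(
                f"slide scanned at {base_magnification}; {magnification} unavailable"
            )
        h0 = self.levels[0].shape[0]
        factors = [round(h0 / lvl.shape[0]) for lvl in self.levels]
        if want in factors:
            return self.levels[factors.index(want)]
        finer = [f for f in factors if f < want and want % f == 0]
        if not finer:
            raise ConfigurationError(
                f"cannot produce downsample {want}; available levels {factors}"
            )
        src = self.levels[factors.index(max(finer))]
        step = want // max(finer)
        H, W = src.shape[0] // step * step, src.shape[1] // step * step
        src = src[:H, :W].astype(np.float64)
        ds = src.reshape(H // step, step, W // step, step, -1).mean(axis=(1, 3))
        return ds.astype(self.levels[0].dtype)


def segment_tissue(thumbnail: np.ndarray, closing_radius: int = 2) -> np.ndarray:
    """Binary tissue mask of an RGB thumbnail.

    Pixels whose HSV saturation exceeds an automatic threshold (maximum
    between-class variance of the saturation histogram) are tissue; the
    mask is then morphologically closed.  A single-color image yields an
    empty mask (no tissue) rather than an error.
    """
    thumb = np.asarray(thumbnail)
    if thumb.size == 0:
        raise ValidationError("empty thumbnail")
    if thumb.ndim != 3 or thumb.shape[2] < 3:
        raise ShapeError(f"thumbnail must be H x W x 3 RGB, got {thumb.shape}")
    if thumb.dtype != np.uint8:
        thumb = np.clip(thumb, 0, 255).astype(np.uint8)
    sat = rgb2hsv(thumb[..., :3])[..., 1]
    if np.ptp(sat) < 1e-6:
        return np.zeros(sat.shape, dtype=bool)
    mask = sat > threshold_otsu(sat)
    if closing_radius > 0:
        mask = _closing(mask, disk(closing_radius))
    return mask


def tile_slide(
    slide: Slide,
    magnification: str = "x20",
    tile_size: int = TILE_SIZE,
    mask: np.ndarray | None = None,
    min_tissue: float = 0.5,
    base_magnification: str = "x40",
) -> list[TileRecord]:
    """Non-overlapping tiles on a fixed grid, filtered by tissue coverage.

    Grid coords are ``(pixel_y / tile_size, pixel_x / tile_size)``; pixel
    boxes are half-open.  Edge tiles not fully inside the plane are
    dropped.  ``mask`` is the thumbnail-level tissue mask; when omitted
    it is computed from the slide thumbnail.
    """
    if not 0.0 <= min_tissue <= 1.0:
        raise ValidationError(f"min_tissue must be in [0, 1], got {min_tissue}")
    plane = slide.plane_at(magnification, base_magnification)
    H, W = plane.shape[:2]
    if mask is None:
        mask = segment_tissue(slide.thumbnail())
    mh, mw = mask.shape
    sy, sx = mh / H, mw / W
    records = []
    for row in range(H // tile_size):
        for col in range(W // tile_size):
            y0, x0 = row * tile_size, col * tile_size
            y1, x1 = y0 + tile_size, x0 + tile_size
            my0, my1 = int(np.floor(y0 * sy)), max(int(np.ceil(y1 * sy)), int(np.floor(y0 * sy)) + 1)
            mx0, mx1 = int(np.floor(x0 * sx)), max(int(np.ceil(x1 * sx)), int(np.floor(x0 * sx)) + 1)
            frac = float(mask[my0:my1, mx0:mx1].mean()) if mask[my0:my1, mx0:mx1].size else 0.0
            if frac >= min_tissue:
                records.append(TileRecord(row, col, x0, y0, x1, y1, frac))
    return records


class ChannelStatsEmbedder:
    """Built-in deterministic test embedder: seeded random projection of
    per-tile channel statistics (means, standard deviations and an
    8-bin intensity histogram per channel)."""

    def __init__(self, d: int = 64, seed: int = 0):
        self.d = d
        rng = np.random.default_rng(seed)
        self._proj = rng.normal(0.0, 1.0, size=(30, d)) / np.sqrt(30)

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        t = np.asarray(tile, dtype=np.float64)[..., :3] / 255.0
        stats = [t.mean(axis=(0, 1)), t.std(axis=(0, 1))]
        for c in range(3):
            hist, _ = np.histogram(t[..., c], bins=8, range=(0, 1))
            stats.append(hist / t[..., c].size)
        vec = np.concatenate(stats)  # 3 + 3 + 24 = 30
        return vec @ self._proj


def embed_tiles(
    slide: Slide,
    tiles: list[TileRecord],
    embedder,
    magnification: str = "x20",
    slide_id: str = "",
    label: int | None = None,
    base_magnification: str = "x40",
) -> FeatureBag:
    """One feature row per kept tile, rows ordered by (row, col)."""
    if not tiles:
        raise ValidationError(
            "no tissue tiles were kept — an empty slide cannot form a bag (M=0)"
        )
    plane = slide.plane_at(magnification, base_magnification)
    tiles = sorted(tiles, key=lambda t: (t.row, t.col))
    feats, coords = [], []
    for t in tiles:
        patch = plane[t.y0 : t.y1, t.x0 : t.x1]
        vec = np.asarray(embedder(patch), dtype=np.float64)
        if hasattr(embedder, "d") and vec.shape != (embedder.d,):
            raise ShapeError(
                f"embedder declared width d={embedder.d} but produced shape {vec.shape}"
            )
        feats.append(vec)
        coords.append((t.row, t.col))
    return FeatureBag(
        features=np.stack(feats),
        coords=np.array(coords),
        slide_id=slide_id or Path(slide.path).stem,
        label=label,
        magnification=magnification,
    )


def tiles_to_csv(tiles: list[TileRecord], path) -> None:
    with open(path, "w") as f:
        f.write("row,col,x0,y0,x1,y1,tissue_fraction\n")
        for t in tiles:
            f.write(f"{t.row},{t.col},{t.x0},{t.y0},{t.x1},{t.y1},{t.tissue_fraction!r}\n")
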