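"""High-power-field detection on registered CD20 saturation maps.

A high power field (HPF) is the standard microscope field pathologists grade
on: 0.159 mm^2, which at 40x / 0.23 um per pixel is a 1365 x 2165 pixel
block.  The detector separates follicle from non-follicle tissue by local
thresholding of the CD20 saturation map and keeps the HPF-sized blocks whose
positive-pixel fraction exceeds 75% — i.e. fields lying essentially inside a
follicle, the regions worth counting centroblasts in.

The threshold itself is data driven: the histogram of local-region mean
saturations is scanned for its peak; absent a unique interior peak a default
of 0.5 is used.  Because follicles are large structures, detection also works
at strongly reduced resolution (the 0.5x pathway, an 80-fold downscale from
40x, where an HPF shrinks to roughly 17 x 27 pixels); block boundaries at
reduced scale are kept aligned with the full-resolution HPF grid by using
fractional block sizes, so both pathways tile the same level-0 fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DetectionError
from .registration import RgbImage, _as_pixels, _block_mean_pool, extract_saturation

#: physical area of one high power field, mm^2 (documentation metadata)
HPF_AREA_MM2 = 0.159


@dataclass
class DetectionConfig:
    """Detection settings; defaults are the 40x operating point.

    ``hpf_rows``/``hpf_cols``: HPF block size in level-0 pixels.
    ``local_region``: side of the square local-thresholding window, pixels.
    ``min_positive_fraction``: a block is kept iff its positive-pixel
    fraction strictly exceeds this.
    ``default_threshold``: fallback when the saturation histogram has no
    unique interior peak.
    ``downscale``: integer pooling factor; 1 is native 40x, 80 is the 0.5x
    low-resolution pathway (HPF ~= 17 x 27 pixels, local window 5 x 5).
    """

    hpf_rows: int = 1365
    hpf_cols: int = 2165
    local_region: int = 400
    min_positive_fraction: float = 0.75
    default_threshold: float = 0.5
    histogram_bins: int = 100
    downscale: int = 1

    def __post_init__(self) -> None:
        if min(self.hpf_rows, self.hpf_cols, self.local_region) <= 0:
            raise ValueError("block and local-region sizes must be positive")
        if not 0 < self.min_positive_fraction <= 1:
            raise ValueError("min_positive_fraction must be in (0, 1]")
        if not 0 <= self.default_threshold <= 1:
            raise ValueError("default_threshold must be in [0, 1]")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.downscale < 1:
            raise ValueError("downscale must be >= 1")


@dataclass(frozen=True)
class HpfCandidate:
    """A detected high power field.

    ``grid_row``/``grid_col`` index the HPF block grid; ``bbox`` is the
    half-open level-0 pixel box (r0, c0, r1, c1); ``positive_fraction`` is
    the fraction of thresholded-positive pixels inside the block at the
    detection resolution.
    """

    grid_row: int
    grid_col: int
    bbox: tuple[int, int, int, int]
    positive_fraction: float


def _tile_edges(n: int, size: float, extent: float | None = None) -> np.ndarray:
    """Tile boundaries covering [0, n) with blocks of (possibly fractional) size.

    Boundaries are ``round(b * size)`` clipped to ``n``; with integer ``size``
    this is the plain anchored tiling with a partial edge block.  ``extent``
    (default ``n``) is the true content extent used to fix the block count —
    it differs from ``n`` when the array carries padding rows from mean
    pooling, where a naive count would emit a spurious sliver block.
    """
    extent = float(n if extent is None else extent)
    n_blocks = max(1, int(np.ceil(extent / size - 1e-9)))
    edges = np.round(np.arange(n_blocks + 1) * size).astype(int)
    edges = np.minimum(edges, n)
    edges[-1] = n
    return edges


def local_mean_map(sat: np.ndarray, local_region: int) -> np.ndarray:
    """Mean saturation per local_region x local_region tile, (0,0)-anchored.

    Edge tiles may be smaller and are averaged over their own pixels.
    """
    sat = np.asarray(sat, dtype=np.float64)
    if sat.size == 0:
        raise DetectionError("empty saturation map", code="empty_input")
    if local_region < 1:
        raise ValueError("local_region must be >= 1")
    redges = _tile_edges(sat.shape[0], local_region)
    cedges = _tile_edges(sat.shape[1], local_region)
    csum = np.add.reduceat(np.add.reduceat(sat, redges[:-1], axis=0), cedges[:-1], axis=1)
    counts = np.outer(np.diff(redges), np.diff(cedges))
    return csum / counts


def peak_threshold(means: np.ndarray, bins: int = 100, default: float = 0.5) -> float:
    """Threshold from the histogram peak of local-region mean saturations.

    Builds a ``bins``-bin histogram on [0, 1] and returns the center of the
    unique maximal bin.  Ties for the maximum, or all mass in a single bin at
    the domain boundary, count as "no peak" and yield ``default``.
    """
    vals = np.asarray(means, dtype=np.float64).ravel()
    if vals.size == 0:
        raise DetectionError("no mean values", code="empty_input")
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    top = counts.max()
    peaks = np.flatnonzero(counts == top)
    if len(peaks) != 1:
        return default
    b = peaks[0]
    if b in (0, bins - 1) and counts[b] == counts.sum():
        return default
    return float((edges[b] + edges[b + 1]) / 2.0)


def binarize(sat: np.ndarray, threshold: float, local_region: int) -> np.ndarray:
    """Per-local-region thresholding: a tile is positive iff mean >= threshold.

    Every pixel of a tile receives its tile's label; returns a uint8 mask of
    the saturation map's shape.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    sat = np.asarray(sat, dtype=np.float64)
    means = local_mean_map(sat, local_region)
    labels = (means >= threshold).astype(np.uint8)
    redges = _tile_edges(sat.shape[0], local_region)
    cedges = _tile_edges(sat.shape[1], local_region)
    mask = np.repeat(np.repeat(labels, np.diff(redges), axis=0), np.diff(cedges), axis=1)
    return mask


def detect_hpfs(
    mask: np.ndarray,
    config: DetectionConfig | None = None,
    *,
    block_rows: float | None = None,
    block_cols: float | None = None,
    level0_scale: int = 1,
    extent: tuple[float, float] | None = None,
) -> list[HpfCandidate]:
    """Keep HPF-sized blocks whose positive fraction strictly exceeds the cut.

    The mask is tiled (0,0)-anchored into blocks of ``block_rows`` x
    ``block_cols`` (defaults: the config's HPF size; may be fractional when
    the mask is a downscaled rendering of the slide).  Partial edge blocks
    are judged against their own pixel count.  Candidates are returned
    row-major with bounding boxes in level-0 pixels (``level0_scale`` times
    the mask coordinates).
    """
    config = config or DetectionConfig()
    mask = np.asarray(mask)
    if mask.size == 0:
        return []
    br = block_rows if block_rows is not None else config.hpf_rows
    bc = block_cols if block_cols is not None else config.hpf_cols
    er, ec = extent if extent is not None else (None, None)
    redges = _tile_edges(mask.shape[0], br, er)
    cedges = _tile_edges(mask.shape[1], bc, ec)
    m = mask.astype(np.float64)
    sums = np.add.reduceat(np.add.reduceat(m, redges[:-1], axis=0), cedges[:-1], axis=1)
    counts = np.outer(np.diff(redges), np.diff(cedges))
    frac = sums / counts
    out: list[HpfCandidate] = []
    for i in range(frac.shape[0]):
        for j in range(frac.shape[1]):
            if frac[i, j] > config.min_positive_fraction:
                bbox = (int(redges[i] * level0_scale), int(cedges[j] * level0_scale),
                        int(redges[i + 1] * level0_scale), int(cedges[j + 1] * level0_scale))
                out.append(HpfCandidate(grid_row=i, grid_col=j, bbox=bbox,
                                        positive_fraction=float(frac[i, j])))
    return out


def detect_hpfs_multires(
    cd20_registered: "RgbImage | np.ndarray",
    config: DetectionConfig | None = None,
) -> list[HpfCandidate]:
    """Full detection pipeline on a registered CD20 image.

    Pools the image by ``config.downscale`` (block-mean per channel), then
    runs saturation extraction, local-region mean, histogram-peak threshold,
    binarization and block selection with sizes scaled by the same factor.
    Candidate boxes come back in level-0 coordinates, so the candidate grid
    is identical across resolutions for follicles that fill whole blocks.
    """
    config = config or DetectionConfig()
    px = _as_pixels(cd20_registered)
    f = config.downscale
    if f > 1:
        pooled = np.stack([_block_mean_pool(px[..., ch].astype(np.float32), f)
                           for ch in range(3)], axis=-1)
        px = np.clip(np.rint(pooled), 0, 255).astype(np.uint8)
    sat = extract_saturation(px)
    local = max(1, int(round(config.local_region / f)))
    means = local_mean_map(sat, local)
    thr = peak_threshold(means, config.histogram_bins, config.default_threshold)
    mask = binarize(sat, thr, local)
    rows0, cols0 = _as_pixels(cd20_registered).shape[:2]
    cands = detect_hpfs(mask, config, block_rows=config.hpf_rows / f,
                        block_cols=config.hpf_cols / f, level0_scale=f,
                        extent=(rows0 / f, cols0 / f))
    if f > 1:  # recompute level-0 boxes exactly from the block grid
        cands = [HpfCandidate(c.grid_row, c.grid_col,
                              (c.grid_row * config.hpf_rows,
                               c.grid_col * config.hpf_cols,
                               min((c.grid_row + 1) * config.hpf_rows, rows0),
                               min((c.grid_col + 1) * config.hpf_cols, cols0)),
                              c.positive_fraction) for c in cands]
    return cands
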