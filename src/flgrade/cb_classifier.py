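"""Centroblast-density classification of high power fields and tissues.

Rather than segmenting individual centroblasts, each detected HPF is broken
into 64 x 64 pixel sub-blocks and every sub-block is labelled centroblast /
non-centroblast by k-nearest-neighbor matching of its 64-bin color histogram
against a labelled training set.  Rule-based aggregation then grades each
level of the hierarchy:

* sub-block: centroblast iff at least half of its k = 49 nearest training
  neighbors are centroblast blocks;
* HPF: high-centroblast field iff more than p = 115 of its sub-blocks (693
  for a 1365 x 2165 field) are centroblast blocks;
* tissue: high risk (grade III) iff at least 50% of its detected HPFs are
  high-centroblast fields.

The WHO manual-count grade (mean centroblasts over ten HPFs: I <= 5,
II 6-15, III > 15) is also provided for the conventional-reading arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .errors import ClassificationError
from .hpf_detection import HpfCandidate
from .registration import RgbImage, _as_pixels

logger = logging.getLogger(__name__)

CB = "CB"
NONCB = "NONCB"
HIGH = "HIGH"
LOW = "LOW"


@dataclass
class ClassifierConfig:
    """Sub-block / HPF / tissue classification settings.

    ``k``: neighbor count of the sub-block kNN (odd).  ``p``: HPF is HIGH iff
    its centroblast sub-block count strictly exceeds ``p``.  ``subblock``:
    sub-block side in pixels.  ``tissue_high_fraction``: tissue is HIGH iff
    the fraction of HIGH HPFs reaches this.  ``noncb_per_image`` /
    ``noncb_min_distance``: non-centroblast sampling density and exclusion
    radius (center-to-center pixels) around marked centroblasts.
    """

    k: int = 49
    p: int = 115
    subblock: int = 64
    tissue_high_fraction: float = 0.5
    noncb_per_image: int = 20
    noncb_min_distance: float = 128.0
    max_sampling_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1")
        if self.p < 0 or self.subblock < 1:
            raise ValueError("p must be >= 0 and subblock >= 1")
        if not 0 < self.tissue_high_fraction < 1:
            raise ValueError("tissue_high_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CentroblastAnnotation:
    """A pathologist-marked centroblast center (row, col) in one image."""

    image_id: str
    row: int
    col: int


@dataclass
class TrainingSet:
    """Labelled 64-bin color histograms backing the kNN classifier."""

    features: np.ndarray  # (n, 64) rows summing to 1
    labels: np.ndarray  # (n,) strings in {CB, NONCB}
    n_cb: int = 0
    n_noncb: int = 0
    # sampling provenance (image_id, row, col), populated by build_training_set
    noncb_centers: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[1] != 64:
            raise ValueError("features must be (n, 64)")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels differ in length")
        if not np.allclose(self.features.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("histogram weights must sum to 1")
        if np.any(self.features < 0):
            raise ValueError("histogram weights must be non-negative")
        self.n_cb = int(np.sum(self.labels == CB))
        self.n_noncb = int(np.sum(self.labels == NONCB))
        if self.n_cb == 0 or self.n_noncb == 0:
            raise ValueError("both classes must be present")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class HpfClassification:
    """Per-HPF outcome: sub-block tally and the HIGH/LOW rule result."""

    n_subblocks: int
    n_cb_blocks: int
    label: str
    tile_labels: np.ndarray | None = None  # (grid_r, grid_c) bool, CB = True


@dataclass(frozen=True)
class TissueResult:
    """Per-slide aggregate of the HPF labels."""

    n_detected: int
    n_high: int
    percent_high: float
    grade: str


def color_histogram(block: "RgbImage | np.ndarray", subblock: int = 64) -> np.ndarray:
    """64-bin color histogram of one sub-block.

    The RGB cube is split into 4 x 4 x 4 uniform bins; bin index is
    ``16*(R//64) + 4*(G//64) + B//64``; counts are normalized to sum to 1.
    """
    px = _as_pixels(block)
    if px.shape[:2] != (subblock, subblock):
        raise ClassificationError(
            f"expected {subblock}x{subblock} block, got {px.shape[:2]}",
            code="bad_block_shape")
    idx = (16 * (px[..., 0] // 64) + 4 * (px[..., 1] // 64) + px[..., 2] // 64)
    counts = np.bincount(idx.ravel().astype(np.int64), minlength=64)
    return counts / counts.sum()


def _tile_histograms(px: np.ndarray, subblock: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Histograms of all full subblock tiles of an image, row-major."""
    rows, cols = px.shape[:2]
    gr, gc = rows // subblock, cols // subblock
    crop = px[: gr * subblock, : gc * subblock]
    idx = (16 * (crop[..., 0] // 64) + 4 * (crop[..., 1] // 64) + crop[..., 2] // 64)
    idx = idx.astype(np.int64)
    tiles = idx.reshape(gr, subblock, gc, subblock).transpose(0, 2, 1, 3)
    tiles = tiles.reshape(gr * gc, subblock * subblock)
    offset = np.arange(gr * gc)[:, None] * 64
    counts = np.bincount((tiles + offset).ravel(), minlength=gr * gc * 64)
    hists = counts.reshape(gr * gc, 64) / (subblock * subblock)
    return hists, (gr, gc)


def build_training_set(
    images: "Mapping[str, RgbImage | np.ndarray] | Sequence[RgbImage | np.ndarray]",
    annotations: Iterable[CentroblastAnnotation],
    config: ClassifierConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> TrainingSet:
    """Extract labelled histograms from annotated training images.

    One centroblast feature per annotation whose centered sub-block fits in
    its image (others are skipped with a warning); per image,
    ``noncb_per_image`` non-centroblast blocks are sampled uniformly among
    positions at least ``noncb_min_distance`` (center to center) from every
    marked centroblast of that image.
    """
    config = config or ClassifierConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not isinstance(images, Mapping):
        images = {str(i): im for i, im in enumerate(images)}
    by_image: dict[str, list[CentroblastAnnotation]] = {k: [] for k in images}
    for ann in annotations:
        if ann.image_id not in images:
            raise ClassificationError(f"annotation references unknown image {ann.image_id!r}")
        by_image[ann.image_id].append(ann)

    half = config.subblock // 2
    feats: list[np.ndarray] = []
    labels: list[str] = []
    noncb_centers: list[tuple[str, int, int]] = []
    for image_id, image in images.items():
        px = _as_pixels(image)
        rows, cols = px.shape[:2]
        centers = np.array([[a.row, a.col] for a in by_image[image_id]], dtype=float)
        for a in by_image[image_id]:
            r0, c0 = a.row - half, a.col - half
            if r0 < 0 or c0 < 0 or r0 + config.subblock > rows or c0 + config.subblock > cols:
                logger.warning("skipping centroblast at (%d, %d) in %s: block does not fit",
                               a.row, a.col, image_id)
                continue
            feats.append(color_histogram(px[r0:r0 + config.subblock, c0:c0 + config.subblock],
                                         config.subblock))
            labels.append(CB)
        if rows < config.subblock or cols < config.subblock:
            raise ClassificationError(f"image {image_id!r} smaller than one sub-block")
        n_drawn = 0
        for _ in range(config.max_sampling_attempts):
            if n_drawn >= config.noncb_per_image:
                break
            r = int(rng.integers(half, rows - config.subblock + half + 1))
            c = int(rng.integers(half, cols - config.subblock + half + 1))
            if len(centers) and np.min(np.hypot(centers[:, 0] - r, centers[:, 1] - c)) \
                    < config.noncb_min_distance:
                continue
            r0, c0 = r - half, c - half
            feats.append(color_histogram(px[r0:r0 + config.subblock, c0:c0 + config.subblock],
                                         config.subblock))
            labels.append(NONCB)
            noncb_centers.append((image_id, r, c))
            n_drawn += 1
        if n_drawn < config.noncb_per_image:
            raise ClassificationError(
                f"could not sample non-centroblast blocks from image {image_id!r}",
                code="noncb_sampling_exhausted")
    return TrainingSet(features=np.array(feats), labels=np.array(labels),
                       noncb_centers=noncb_centers)


def _knn_votes(dist2: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """CB-vote counts among the k nearest training points per query row.

    Ties at the k-th distance are broken by ascending training index, which a
    stable sort on the distance array realizes directly.
    """
    order = np.argsort(dist2, axis=1, kind="stable")[:, :k]
    return (labels[order] == CB).sum(axis=1)


def knn_label(query: np.ndarray, ts: TrainingSet, k: int = 49) -> str:
    """Majority label of the k nearest training histograms (Euclidean).

    A query is CB iff at least ceil(k/2) of its k nearest neighbors are CB.
    """
    if k > len(ts):
        raise ClassificationError("k exceeds training-set size", code="k_exceeds_training")
    q = np.asarray(query, dtype=np.float64).reshape(1, 64)
    diff = ts.features - q
    dist2 = (diff * diff).sum(axis=1)[None, :]
    votes = _knn_votes(dist2, ts.labels, k)[0]
    return CB if votes >= -(-k // 2) else NONCB


def knn_labels(queries: np.ndarray, ts: TrainingSet, k: int = 49) -> np.ndarray:
    """Vectorized :func:`knn_label` over an (m, 64) query array."""
    if k > len(ts):
        raise ClassificationError("k exceeds training-set size", code="k_exceeds_training")
    q = np.asarray(queries, dtype=np.float64)
    # squared Euclidean via the expansion; BLAS-backed for large batches
    dist2 = ((q * q).sum(axis=1)[:, None] + (ts.features * ts.features).sum(axis=1)[None, :]
             - 2.0 * q @ ts.features.T)
    votes = _knn_votes(dist2, ts.labels, k)
    return np.where(votes >= -(-k // 2), CB, NONCB)


def classify_hpf(hpf: "RgbImage | np.ndarray", ts: TrainingSet,
                 config: ClassifierConfig | None = None) -> HpfClassification:
    """Grade one HPF by tallying centroblast sub-blocks against threshold p.

    The field is tiled into non-overlapping subblock-sized tiles anchored at
    (0, 0); partial edge tiles are discarded (a 1365 x 2165 field yields
    21 * 33 = 693 tiles).
    """
    config = config or ClassifierConfig()
    px = _as_pixels(hpf)
    if px.shape[0] < config.subblock or px.shape[1] < config.subblock:
        raise ClassificationError("HPF smaller than one sub-block", code="hpf_too_small")
    hists, (gr, gc) = _tile_histograms(px, config.subblock)
    labels = knn_labels(hists, ts, config.k)
    n_cb = int(np.sum(labels == CB))
    return HpfClassification(
        n_subblocks=gr * gc, n_cb_blocks=n_cb,
        label=HIGH if n_cb > config.p else LOW,
        tile_labels=(labels == CB).reshape(gr, gc))


def classify_tissue(hpf_labels: Sequence[str] | None = None, *,
                    n_detected: int | None = None, n_high: int | None = None,
                    high_fraction: float = 0.5) -> TissueResult:
    """Aggregate HPF labels into the tissue grade.

    Accepts either the label list or the (n_detected, n_high) counts.  The
    tissue is HIGH iff the percentage of HIGH fields reaches
    ``100 * high_fraction`` (default 50%).
    """
    if hpf_labels is not None:
        n_detected = len(hpf_labels)
        n_high = sum(1 for x in hpf_labels if x == HIGH)
    if not n_detected:
        raise ClassificationError("no detected HPFs", code="no_detected_hpfs")
    if n_high is None or not 0 <= n_high <= n_detected:
        raise ClassificationError("invalid HPF counts")
    percent = 100.0 * n_high / n_detected
    return TissueResult(n_detected=n_detected, n_high=n_high, percent_high=percent,
                        grade=HIGH if percent >= 100.0 * high_fraction else LOW)


def who_grade(cb_counts: Sequence[float], n_fields: int = 10) -> str:
    """WHO histological grade from manual centroblast counts per HPF.

    Grade III iff the mean count exceeds 15; grade II iff it exceeds 5 (up to
    15); grade I otherwise.  ``n_fields`` fields are expected (ten in
    standard practice).
    """
    counts = np.asarray(cb_counts, dtype=float)
    if len(counts) != n_fields:
        raise ClassificationError(f"expected {n_fields} counts, got {len(counts)}")
    if np.any(counts < 0):
        raise ClassificationError("counts must be non-negative", code="bad_count")
    m = counts.mean()
    if m > 15:
        return "III"
    if m > 5:
        return "II"
    return "I"


def overlay_classification(
    he: "RgbImage | np.ndarray",
    candidates: Sequence[HpfCandidate],
    labels: Sequence[str],
    width: int = 12,
) -> np.ndarray:
    """Draw the HPF classification map: green boxes for HIGH, red for LOW."""
    img = Image.fromarray(_as_pixels(he).copy())
    draw = ImageDraw.Draw(img)
    for cand, label in zip(candidates, labels):
        r0, c0, r1, c1 = cand.bbox
        color = (0, 200, 0) if label == HIGH else (220, 0, 0)
        draw.rectangle([c0, r0, c1 - 1, r1 - 1], outline=color, width=width)
    return np.asarray(img)
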