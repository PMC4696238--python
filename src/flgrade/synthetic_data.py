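"""Synthetic inputs for every stage of the grading pipeline.

No slide archive ships with this package, so validation runs on simulated
material that reproduces the image properties the pipeline relies on:

* CD20 renderings whose follicle regions carry elevated HSV saturation over
  the non-follicle background (the single property the detector uses);
* H&E-like renderings tiled from two distinct 64 x 64 color palettes, one
  standing in for centroblast-rich texture and one for everything else;
* reader confidence scores from a binormal latent model with crossed reader
  and case random effects (Roe-Metz style), with closed-form true AUCs.

Palettes, saturation levels and noise are stand-ins chosen for clear class
structure, not estimates of real stain statistics.  All generators are pure
functions of their seed.

The one piece of real data is the packaged 20-case detection/classification
summary table (per-case detected-HPF and high-HPF counts with consensus and
computer grades), exposed by :func:`table2_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cb_classifier import HIGH, LOW
from .errors import SimulationError
from .registration import RgbImage, RigidTransform, warp_rgb
from .reader_stats import AIDED, UNAIDED


@dataclass
class SlideSimConfig:
    """Paired pseudo-H&E / CD20 slide generator settings.

    The default slide is a 3 x 3 grid of HPF blocks (4095 x 6495 pixels)
    holding ``n_follicles`` block-aligned follicles.  CD20 saturation is
    ``cd20_pos_saturation`` inside follicles and ``cd20_neg_saturation``
    outside (plus Gaussian noise of sd ``noise_sd``); the H&E rendering
    tiles follicle blocks with ``cb_palette`` 64 x 64 tiles at fraction
    ``cb_block_fraction_high`` (high-grade follicles) or
    ``cb_block_fraction_low``, the rest drawn from ``noncb_palette``.
    """

    rows: int = 3 * 1365
    cols: int = 3 * 2165
    n_follicles: int = 3
    n_high_follicles: int | None = None  # None: all follicles high grade
    follicle_block_span: int = 1
    cd20_pos_saturation: float = 0.7
    cd20_neg_saturation: float = 0.3
    cb_palette: tuple[int, int, int] = (100, 60, 140)
    noncb_palette: tuple[int, int, int] = (210, 160, 200)
    cb_block_fraction_high: float = 0.30
    cb_block_fraction_low: float = 0.05
    noise_sd: float = 0.05
    misregistration: RigidTransform = field(default_factory=RigidTransform)
    hpf_rows: int = 1365
    hpf_cols: int = 2165
    subblock: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cb_palette == self.noncb_palette:
            raise ValueError("palettes must be distinct")
        for frac in (self.cb_block_fraction_high, self.cb_block_fraction_low):
            if not 0 <= frac <= 1:
                raise ValueError("tile fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SimulatedSlide:
    """A generated slide pair with full ground truth."""

    he: RgbImage
    cd20: RgbImage
    follicle_mask: np.ndarray  # uint8, 1 inside planted follicles
    cb_centers: list[tuple[int, int]]
    follicle_blocks: list[tuple[int, int]]  # planted (grid_row, grid_col)
    true_hpf_labels: list[str]  # aligned with follicle_blocks
    true_grade: str
    applied_transform: RigidTransform


@dataclass
class ReaderSimConfig:
    """Crossed random-effects score generator for reader-study validation.

    Latent score for reader i, case k, modality m:

        ``sep_m * 1[case k high] + reader_i + case_k + eps_ikm``

    with independent normal effects (sds ``reader_sd``, ``case_sd``,
    ``error_sd``), squashed to [0, 100] by a fixed logistic map.  The
    implied within-reader true AUC of modality m is
    ``Phi(sep_m / sqrt(2 * (case_sd^2 + error_sd^2)))``.  Defaults emulate
    the source study's arm sizes (11 readers, 20 balanced cases) with
    separations implying true AUCs of about 0.65 unaided and 0.75 aided.
    """

    n_readers: int = 11
    n_cases: int = 20
    mu_sep_unaided: float = 0.77064
    mu_sep_aided: float = 1.34898
    reader_sd: float = 0.3
    case_sd: float = 1.0
    error_sd: float = 1.0
    squash_scale: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.reader_sd, self.case_sd, self.error_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_cases % 2:
            raise ValueError("n_cases must be even (balanced classes)")


def implied_auc(separation: float, case_sd: float = 1.0, error_sd: float = 1.0) -> float:
    """Closed-form binormal AUC implied by a latent class separation."""
    sd = np.sqrt(2.0 * (case_sd**2 + error_sd**2))
    if sd == 0:  # noise-free limit: any positive separation is perfect
        return 1.0 if separation > 0 else (0.0 if separation < 0 else 0.5)
    return float(norm.cdf(separation / sd))


def separation_for_auc(auc: float, case_sd: float = 1.0, error_sd: float = 1.0) -> float:
    """Latent separation producing a given true within-reader AUC."""
    return float(norm.ppf(auc) * np.sqrt(2.0 * (case_sd**2 + error_sd**2)))


def _render_cd20(sat: np.ndarray) -> np.ndarray:
    """Map a saturation field to RGB at fixed hue/value (brown-ish DAB tone).

    With value V and hue in the first sector, R = V, B = V(1-S), so the HSV
    saturation of the rendered pixel equals S up to uint8 quantization.
    """
    v = 0.9
    out = np.empty(sat.shape + (3,), dtype=np.uint8)
    out[..., 0] = round(255 * v)
    buf = np.multiply(sat, -0.52 * 255 * v, dtype=np.float32)
    buf += 255 * v
    np.rint(buf, out=buf)
    out[..., 1] = buf.astype(np.uint8)
    buf = np.multiply(sat, -255 * v, dtype=np.float32)
    buf += 255 * v
    np.rint(buf, out=buf)
    out[..., 2] = buf.astype(np.uint8)
    return out


def _palette_image(tile_is_cb: np.ndarray, config: SlideSimConfig,
                   rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Expand a boolean tile grid into a noisy RGB image of the two palettes."""
    sb = config.subblock
    cb = np.array(config.cb_palette, dtype=np.float32)
    ncb = np.array(config.noncb_palette, dtype=np.float32)
    tiles = np.where(tile_is_cb[..., None], cb, ncb)  # (gr, gc, 3)
    img = np.repeat(np.repeat(tiles, sb, axis=0), sb, axis=1)[:rows, :cols]
    if config.noise_sd > 0:
        noise = rng.standard_normal(img.shape, dtype=np.float32)
        noise *= 255.0 * config.noise_sd
        noise += img
        img = noise
    np.clip(img, 0, 255, out=img)
    np.rint(img, out=img)
    return img.astype(np.uint8)


def simulate_slide(config: SlideSimConfig | None = None) -> SimulatedSlide:
    """Generate one paired pseudo-H&E / CD20 slide with planted ground truth.

    Follicles occupy whole HPF blocks chosen without replacement from the
    slide's block grid; ``n_high_follicles`` of them are rendered
    centroblast-rich.  The CD20 image is optionally mis-registered by
    ``config.misregistration`` (the transform the registration stage should
    recover maps the rendered CD20 back onto the H&E grid).
    """
    config = config or SlideSimConfig()
    rng = np.random.default_rng(config.seed)
    grid_r = config.rows // config.hpf_rows
    grid_c = config.cols // config.hpf_cols
    span = config.follicle_block_span
    sites_r = grid_r // span
    sites_c = grid_c // span
    if config.n_follicles > sites_r * sites_c:
        raise SimulationError("follicles do not fit in the slide", code="placement_failed")
    chosen = rng.choice(sites_r * sites_c, size=config.n_follicles, replace=False)
    blocks: list[tuple[int, int]] = []
    for site in np.sort(chosen):
        base_r, base_c = int(site // sites_c) * span, int(site % sites_c) * span
        blocks.extend((base_r + i, base_c + j) for i in range(span) for j in range(span))

    n_high = config.n_follicles if config.n_high_follicles is None \
        else config.n_high_follicles
    n_high = min(n_high, len(blocks))
    labels = [HIGH] * n_high + [LOW] * (len(blocks) - n_high)

    mask = np.zeros((config.rows, config.cols), dtype=np.uint8)
    for gr, gc in blocks:
        mask[gr * config.hpf_rows:(gr + 1) * config.hpf_rows,
             gc * config.hpf_cols:(gc + 1) * config.hpf_cols] = 1

    # CD20: saturation field + noise, rendered at fixed hue
    sat = np.where(mask.astype(bool), config.cd20_pos_saturation,
                   config.cd20_neg_saturation).astype(np.float32)
    if config.noise_sd > 0:
        sat = sat + config.noise_sd * rng.standard_normal(sat.shape, dtype=np.float32)
    cd20_aligned = _render_cd20(np.clip(sat, 0.0, 1.0))
    del sat

    # H&E: non-CB palette background; follicle blocks re-tiled with their own
    # (block-origin-anchored) 64-px grids so planted CB counts live on the
    # same sub-block grid a downstream classifier of that block will use
    sb = config.subblock
    he = _palette_image(np.zeros((-(-config.rows // sb), -(-config.cols // sb)), bool),
                        config, rng, config.rows, config.cols)
    cb_centers: list[tuple[int, int]] = []
    for (gr, gc), label in zip(blocks, labels):
        full_r, full_c = config.hpf_rows // sb, config.hpf_cols // sb
        frac = config.cb_block_fraction_high if label == HIGH \
            else config.cb_block_fraction_low
        n_cb = int(round(frac * full_r * full_c))  # among full tiles only
        tile_is_cb = np.zeros((-(-config.hpf_rows // sb), -(-config.hpf_cols // sb)),
                              dtype=bool)
        pick = rng.choice(full_r * full_c, size=n_cb, replace=False)
        tile_is_cb[pick // full_c, pick % full_c] = True
        block = _palette_image(tile_is_cb, config, rng,
                               config.hpf_rows, config.hpf_cols)
        r0, c0 = gr * config.hpf_rows, gc * config.hpf_cols
        he[r0:r0 + config.hpf_rows, c0:c0 + config.hpf_cols] = block
        for tr, tc in zip(pick // full_c, pick % full_c):
            cb_centers.append((int(r0 + tr * sb + sb // 2),
                               int(c0 + tc * sb + sb // 2)))

    tf = config.misregistration
    if tf != RigidTransform():
        cd20 = warp_rgb(cd20_aligned, tf.inverse((config.rows, config.cols)),
                        (config.rows, config.cols))
    else:
        cd20 = cd20_aligned

    frac_high = sum(1 for x in labels if x == HIGH) / len(labels) if labels else 0.0
    return SimulatedSlide(
        he=RgbImage(he), cd20=RgbImage(cd20), follicle_mask=mask,
        cb_centers=cb_centers, follicle_blocks=blocks, true_hpf_labels=labels,
        true_grade=HIGH if labels and frac_high >= 0.5 else LOW,
        applied_transform=tf)


def simulate_hpf(n_cb_tiles: int, config: SlideSimConfig | None = None,
                 seed: int = 0) -> np.ndarray:
    """One HPF-sized image with exactly ``n_cb_tiles`` CB-palette sub-blocks.

    Tiles are anchored at (0, 0) like the classifier's grid, so the planted
    count is exactly recoverable; partial margins use the non-CB palette.
    """
    config = config or SlideSimConfig()
    rng = np.random.default_rng(seed)
    sb = config.subblock
    gr, gc = config.hpf_rows // sb, config.hpf_cols // sb
    if n_cb_tiles > gr * gc:
        raise SimulationError(f"at most {gr * gc} full tiles available")
    tile_is_cb = np.zeros((-(-config.hpf_rows // sb), -(-config.hpf_cols // sb)),
                          dtype=bool)
    pick = rng.choice(gr * gc, size=n_cb_tiles, replace=False)
    tile_is_cb[pick // gc, pick % gc] = True  # only among full tiles
    return _palette_image(tile_is_cb, config, rng, config.hpf_rows, config.hpf_cols)


def simulate_training_data(
    n_images: int = 20,
    tiles: tuple[int, int] = (16, 16),
    cb_per_image: int = 6,
    config: SlideSimConfig | None = None,
    seed: int = 0,
):
    """Annotated pseudo-H&E training images for the sub-block classifier.

    Each image is a ``tiles`` grid of 64-px palette tiles with
    ``cb_per_image`` CB tiles planted at random positions; annotations mark
    the planted tile centers.  Returns ``(images, annotations)`` with
    ``images`` a dict keyed by image id.
    """
    from .cb_classifier import CentroblastAnnotation

    config = config or SlideSimConfig()
    rng = np.random.default_rng(seed)
    sb = config.subblock
    images: dict[str, np.ndarray] = {}
    annotations: list[CentroblastAnnotation] = []
    for i in range(n_images):
        image_id = f"train{i:03d}"
        tile_is_cb = np.zeros(tiles, dtype=bool)
        pick = rng.choice(tiles[0] * tiles[1], size=cb_per_image, replace=False)
        tile_is_cb[pick // tiles[1], pick % tiles[1]] = True
        images[image_id] = _palette_image(tile_is_cb, config, rng,
                                          tiles[0] * sb, tiles[1] * sb)
        for tr, tc in zip(*np.nonzero(tile_is_cb)):
            annotations.append(CentroblastAnnotation(
                image_id=image_id, row=int(tr) * sb + sb // 2, col=int(tc) * sb + sb // 2))
    return images, annotations


def simulate_reader_scores(config: ReaderSimConfig | None = None):
    """Fully crossed reader x case x modality confidence scores.

    Returns ``(scores, truth, info)``: tidy score and truth DataFrames in
    the package's CSV dialects plus a dict with the analytically implied
    true AUC per modality and their difference.
    """
    config = config or ReaderSimConfig()
    rng = np.random.default_rng(config.seed)
    n_r, n_c = config.n_readers, config.n_cases
    is_pos = np.zeros(n_c, dtype=bool)
    is_pos[: n_c // 2] = True

    reader_eff = config.reader_sd * rng.standard_normal(n_r)
    case_eff = config.case_sd * rng.standard_normal(n_c)
    seps = {UNAIDED: config.mu_sep_unaided, AIDED: config.mu_sep_aided}
    rows = []
    for m, sep in seps.items():
        eps = config.error_sd * rng.standard_normal((n_r, n_c))
        latent = (sep * is_pos[None, :] + reader_eff[:, None]
                  + case_eff[None, :] + eps)
        score = 100.0 * expit(config.squash_scale * (latent - sep / 2.0))
        for i in range(n_r):
            for k in range(n_c):
                rows.append({"reader_id": f"r{i:02d}", "case_id": f"c{k:02d}",
                             "modality": m, "score": float(score[i, k])})
    scores = pd.DataFrame(rows)
    truth = pd.DataFrame({"case_id": [f"c{k:02d}" for k in range(n_c)],
                          "grade": np.where(is_pos, HIGH, LOW)})
    info = {
        "true_auc_unaided": implied_auc(config.mu_sep_unaided, config.case_sd,
                                        config.error_sd),
        "true_auc_aided": implied_auc(config.mu_sep_aided, config.case_sd,
                                      config.error_sd),
    }
    info["true_auc_difference"] = info["true_auc_aided"] - info["true_auc_unaided"]
    return scores, truth, info


def table2_fixture() -> pd.DataFrame:
    """The packaged 20-case detection/classification summary.

    Columns: case, consensus_grade, n_detected, n_high, n_low, percent_high
    (printed to one decimal), computer_grade.
    """
    with resources.files("flgrade.data").joinpath("table2.csv").open() as fh:
        return pd.read_csv(fh)
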