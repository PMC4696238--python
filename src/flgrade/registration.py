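"""Saturation extraction and rigid CD20-to-H&E registration.

Follicle detection runs on the CD20 immunostain, but grading happens on the
H&E section of the same tissue, so the CD20 image must first be mapped onto
the H&E pixel grid.  Both steps work on the HSV saturation channel: follicles,
surrounding tissue and the white slide background separate well in saturation,
which makes it a good single-channel similarity target for intensity-based
registration.

The transform model is rigid (translation + rotation about the reference
image center, optional uniform scale).  Estimation is coarse-to-fine: at each
pyramid level a small rotation sweep is combined with FFT phase correlation
for the translation, candidates are scored by zero-mean normalized
cross-correlation (NCC) at full resolution, and a candidate is accepted only
if it does not decrease the full-resolution score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import RegistrationError

#: scanner resolution of the source material, micrometers per pixel at 40x
PIXEL_SIZE_UM = 0.23


@dataclass
class RgbImage:
    """An RGB raster with slide metadata.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols, 3), uint8
        Intensities in [0, 255].
    pixel_size_um : float
        Physical resolution in micrometers per pixel.
    magnification_label : str
        Free-text magnification tag, e.g. ``"40x"`` or ``"0.5x"``.
    """

    pixels: np.ndarray
    pixel_size_um: float = PIXEL_SIZE_UM
    magnification_label: str = "40x"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("RgbImage requires a rows x cols x 3 array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _as_pixels(image: "RgbImage | np.ndarray") -> np.ndarray:
    if isinstance(image, RgbImage):
        return image.pixels
    return np.asarray(image)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map from moving (CD20) coordinates into the reference (H&E) frame.

    A point ``p`` (row, col) in the moving image maps to

        ``p' = scale * R(theta) @ (p - c) + c + (dy, dx)``

    where ``c`` is the center of the reference grid and ``R(theta)`` rotates
    by ``theta`` radians (positive = counter-clockwise in (row, col) axes).
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not (-np.pi < self.theta <= np.pi):
            raise ValueError("theta must lie in (-pi, pi]")

    def matrix(self) -> np.ndarray:
        """Rotation+scale matrix acting on (row, col) vectors."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Map (row, col) points given the reference grid ``shape``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        center = (np.asarray(shape, dtype=float) - 1) / 2.0
        out = (self.matrix() @ (pts - center).T).T + center
        out += np.array([self.dy, self.dx])
        return out

    def inverse(self, shape: tuple[int, int]) -> "RigidTransform":
        """Inverse transform about the same grid center."""
        c, s = np.cos(-self.theta), np.sin(-self.theta)
        rinv = np.array([[c, -s], [s, c]]) / self.scale
        t = -rinv @ np.array([self.dy, self.dx])
        # rinv is a pure rotation/scale about the center, so the inverse is
        # again of the stored (theta, scale, translation) form.
        return RigidTransform(dx=float(t[1]), dy=float(t[0]),
                              theta=float(-self.theta), scale=1.0 / self.scale)

    def to_dict(self) -> dict:
        return {"dx": self.dx, "dy": self.dy, "theta": self.theta, "scale": self.scale}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(dx=d["dx"], dy=d["dy"], theta=d["theta"], scale=d.get("scale", 1.0))


@dataclass
class SearchConfig:
    """Transform-search settings for :func:`register_cd20_to_he`.

    ``max_rotation_deg`` bounds the rotation sweep; ``coarsest_size`` sets the
    pyramid apex (largest image dimension after maximal downsampling);
    ``min_overlap`` is the required fraction of reference pixels whose
    preimage lands inside the moving image.
    """

    max_rotation_deg: float = 5.0
    coarsest_size: int = 96
    min_overlap: float = 0.25
    rotation_steps: tuple[float, ...] = (1.0, 0.5, 0.25, 0.1)
    scales: tuple[float, ...] = field(default=(1.0,))


def extract_saturation(image: "RgbImage | np.ndarray") -> np.ndarray:
    """HSV saturation channel, S = (max - min) / max with S = 0 at black.

    Returns a float array in [0, 1] with the input's spatial dimensions.
    """
    px = _as_pixels(image)
    if px.dtype == np.uint8:  # reduce before converting: ~3x less float traffic
        mx = px.max(axis=-1)
        mn = px.min(axis=-1)
        return (mx - mn).astype(np.float32) / np.maximum(mx, 1).astype(np.float32)
    px = np.asarray(px, dtype=np.float64)
    mx = px.max(axis=-1)
    mn = px.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return sat


def _block_mean_pool(arr: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool a 2-D array by an integer factor, padding edges by replication."""
    if factor == 1:
        return arr
    rows, cols = arr.shape
    pr = (-rows) % factor
    pc = (-cols) % factor
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), mode="edge")
    r, c = arr.shape
    return arr.reshape(r // factor, factor, c // factor, factor).mean(axis=(1, 3))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two equal-shape arrays."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _warp_sat(mov: np.ndarray, tf: RigidTransform, shape: tuple[int, int]) -> np.ndarray:
    """Resample a saturation map onto the reference grid under ``tf``."""
    inv = tf.inverse(shape)
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    offset = center + np.array([inv.dy, inv.dx]) - inv.matrix() @ center
    return ndimage.affine_transform(mov, inv.matrix(), offset=offset,
                                    output_shape=shape, order=1, cval=0.0)


def warp_rgb(image: "RgbImage | np.ndarray", tf: RigidTransform,
             shape: tuple[int, int]) -> np.ndarray:
    """Warp an RGB image onto a reference grid, bilinear, white background."""
    px = _as_pixels(image).astype(np.float64)
    inv = tf.inverse(shape)
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    offset = center + np.array([inv.dy, inv.dx]) - inv.matrix() @ center
    out = np.empty(shape + (3,), dtype=np.float64)
    for ch in range(3):
        out[..., ch] = ndimage.affine_transform(
            px[..., ch], inv.matrix(), offset=offset,
            output_shape=shape, order=1, cval=255.0)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _overlap_fraction(tf: RigidTransform, mov_shape: tuple[int, int],
                      ref_shape: tuple[int, int]) -> float:
    """Fraction of reference pixels whose preimage lies inside the moving image."""
    inv = tf.inverse(ref_shape)
    rr = np.linspace(0, ref_shape[0] - 1, min(ref_shape[0], 64))
    cc = np.linspace(0, ref_shape[1] - 1, min(ref_shape[1], 64))
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1).reshape(-1, 2)
    pre = inv.apply(grid, ref_shape)
    inside = ((pre[:, 0] >= 0) & (pre[:, 0] <= mov_shape[0] - 1)
              & (pre[:, 1] >= 0) & (pre[:, 1] <= mov_shape[1] - 1))
    return float(inside.mean())


def register_cd20_to_he(
    cd20: "RgbImage | np.ndarray",
    he: "RgbImage | np.ndarray",
    search: SearchConfig | None = None,
) -> tuple[RigidTransform, np.ndarray]:
    """Estimate the rigid transform aligning a CD20 image to its H&E partner.

    Works on the two saturation maps.  Returns the transform together with
    the CD20 image resampled onto the H&E grid (white fill outside the
    source footprint).

    Raises
    ------
    RegistrationError
        ``registration_uninformative`` if either saturation map is constant;
        ``no_valid_transform`` if no candidate achieves the minimum overlap.
    """
    search = search or SearchConfig()
    he_px = _as_pixels(he)
    cd_px = _as_pixels(cd20)
    ref = extract_saturation(he_px)
    mov_raw = extract_saturation(cd_px)

    if np.ptp(ref) < 1e-9 or np.ptp(mov_raw) < 1e-9:
        raise RegistrationError("constant saturation map", code="registration_uninformative")

    # embed the moving map in the reference grid, top-left anchored, so all
    # pyramid levels share a shape (phase correlation needs equal shapes)
    mov = np.zeros_like(ref)
    r = min(ref.shape[0], mov_raw.shape[0])
    c = min(ref.shape[1], mov_raw.shape[1])
    mov[:r, :c] = mov_raw[:r, :c]

    # pyramid factors, coarse to fine
    factors = [1]
    while max(ref.shape) // (factors[-1] * 2) >= search.coarsest_size:
        factors.append(factors[-1] * 2)
    factors = factors[::-1]

    best = RigidTransform()
    best_score = _ncc(_warp_sat(mov, best, ref.shape), ref)
    self_score = best_score
    level_scores: list[float] = []

    for li, f in enumerate(factors):
        ref_l = _block_mean_pool(ref, f)
        mov_l = _block_mean_pool(mov, f)
        step = search.rotation_steps[min(li, len(search.rotation_steps) - 1)]
        if li == 0:
            angles = np.arange(-search.max_rotation_deg,
                               search.max_rotation_deg + step / 2, step)
        else:
            prev = np.degrees(best.theta)
            angles = prev + np.arange(-2 * step, 2 * step + step / 2, step)
        for scale in search.scales:
            for ang in angles:
                theta = np.radians(ang)
                mat = RigidTransform(theta=float(theta), scale=scale).matrix()
                center_l = (np.asarray(ref_l.shape, dtype=float) - 1) / 2.0
                inv_mat = np.linalg.inv(mat)
                offset = center_l - inv_mat @ center_l
                mov_rot = ndimage.affine_transform(mov_l, inv_mat, offset=offset,
                                                   order=1, cval=0.0)
                shift, _, _ = phase_cross_correlation(
                    ref_l, mov_rot, upsample_factor=1 if f > 1 else 10,
                    normalization=None)
                cand = RigidTransform(dx=float(shift[1] * f), dy=float(shift[0] * f),
                                      theta=float(theta), scale=scale)
                score = _ncc(_warp_sat(mov, cand, ref.shape), ref)
                if score > best_score:
                    best, best_score = cand, score
        level_scores.append(best_score)

    if _overlap_fraction(best, mov_raw.shape, ref.shape) < search.min_overlap:
        raise RegistrationError("insufficient overlap after registration",
                                code="no_valid_transform")
    if best_score < self_score:  # never return worse than the identity
        best, best_score = RigidTransform(), self_score

    warped = warp_rgb(cd_px, best, ref.shape)
    register_cd20_to_he.last_level_scores = level_scores  # introspection for diagnostics
    return best, warped
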