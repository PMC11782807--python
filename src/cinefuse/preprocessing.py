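"""Standardise raw cine series into the fixed model input layout.

The pipeline is: percentile intensity normalisation (clip at the 3rd/97th
percentile of the whole series, then map affinely onto [0, 1]), bilinear
resampling to 0.94 mm/pixel, and a centred crop or symmetric zero-pad to a
256 x 256 matrix (240 x 240 mm field of view).  During training, one random
affine augmentation (flip / shift / scale / rotate) is drawn per cine series
and applied identically to all 20 frames so that temporal coherence within
a series is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exam import (
    FRAME_SIZE,
    N_PHASES,
    TARGET_SPACING,
    VIEWS,
    CineExam,
    PreprocessedCineSeries,
    RawCineSeries,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentationParams",
    "normalize_intensity",
    "resample_to_spacing",
    "crop_or_pad",
    "preprocess_series",
    "preprocess_exam",
    "augment",
]


@dataclass
class AugmentationParams:
    """Ranges for the per-series random affine augmentation.

    Magnitudes are deliberately mild so augmented hearts stay anatomically
    plausible; all are configurable.
    """

    flip_prob: float = 0.5
    max_shift_px: float = 16.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    max_rotation_deg: float = 15.0
    shared_across_views: bool = False

    def __post_init__(self):
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")
        if self.max_shift_px < 0 or self.max_rotation_deg < 0:
            raise ValueError("augmentation magnitudes must be nonnegative")
        if not (0 < self.scale_range[0] <= self.scale_range[1]):
            raise ValueError("scale_range must be positive and ordered")

    @classmethod
    def identity(cls) -> "AugmentationParams":
        return cls(flip_prob=0.0, max_shift_px=0.0, scale_range=(1.0, 1.0),
                   max_rotation_deg=0.0)


def normalize_intensity(frames: np.ndarray) -> np.ndarray:
    """Clip a frame stack at its series-wide 3rd/97th percentile and map to [0, 1].

    Percentiles are taken over all pixels of the whole series (linear
    interpolation), not per frame, so relative brightness between frames is
    preserved.  A degenerate series (3rd percentile equal to the 97th) maps
    to all zeros with a warning.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.size == 0:
        raise ValueError("empty series")
    p3, p97 = np.percentile(frames, [3.0, 97.0])
    if p97 <= p3:
        logger.warning("degenerate series (p3 == p97 == %g); returning zeros", p3)
        return np.zeros_like(frames)
    clipped = np.clip(frames, p3, p97)  # float64 via scalar promotion
    clipped -= p3
    clipped /= p97 - p3
    return clipped.astype(np.float32)


def resample_to_spacing(series: RawCineSeries,
                        target_spacing: float = TARGET_SPACING) -> RawCineSeries:
    """Bilinearly resample every frame so one pixel covers `target_spacing` mm."""
    if not target_spacing > 0:
        raise ValueError("target spacing must be positive")
    factor = series.pixel_spacing / target_spacing
    if abs(factor - 1.0) < 1e-9:
        return RawCineSeries(series.frames.copy(), target_spacing, series.view_id)
    p, h, w = series.frames.shape
    out_h, out_w = round(h * factor), round(w * factor)
    out = np.empty((p, out_h, out_w), dtype=np.float32)
    for i in range(p):
        out[i] = _resize_bilinear(series.frames[i], (out_h, out_w))
    return RawCineSeries(out, target_spacing, series.view_id)


def _resize_bilinear(frame: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    zoom = (shape[0] / frame.shape[0], shape[1] / frame.shape[1])
    return ndimage.zoom(frame, zoom, order=1, grid_mode=True, mode="grid-constant")


def crop_or_pad(frames: np.ndarray, size: int = FRAME_SIZE,
                center_offset: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Centre-crop (or symmetrically zero-pad) every frame to ``size x size``.

    The same offsets apply to all frames of the stack.  ``center_offset``
    shifts the crop window from the geometric centre (rows, cols).
    """
    frames = np.asarray(frames)
    p, h, w = frames.shape
    out = np.zeros((p, size, size), dtype=frames.dtype)

    def window(src: int, off: int):
        if src >= size:
            lo = (src - size) // 2 + off
            lo = min(max(lo, 0), src - size)
            return slice(lo, lo + size), slice(0, size)
        lo = (size - src) // 2
        return slice(0, src), slice(lo, lo + src)

    rs, rd = window(h, center_offset[0])
    cs, cd = window(w, center_offset[1])
    out[:, rd, cd] = frames[:, rs, cs]
    return out


def preprocess_series(series: RawCineSeries,
                      target_spacing: float = TARGET_SPACING,
                      size: int = FRAME_SIZE) -> PreprocessedCineSeries:
    """Full pipeline: normalise, resample, crop/pad.  Requires 20 phases."""
    if series.n_phases != N_PHASES:
        raise ValueError(f"expected {N_PHASES} phases, got {series.n_phases}")
    frames = normalize_intensity(series.frames)
    resampled = resample_to_spacing(
        RawCineSeries(frames, series.pixel_spacing, series.view_id), target_spacing
    )
    fixed = np.clip(crop_or_pad(resampled.frames, size), 0.0, 1.0)
    return PreprocessedCineSeries(fixed, series.view_id, target_spacing)


def preprocess_mask_set(masks, pixel_spacing: float,
                        target_spacing: float = TARGET_SPACING,
                        size: int = FRAME_SIZE):
    """Bring chamber masks into the preprocessed frame geometry.

    Nearest-neighbour resampling keeps masks binary; the crop/pad offsets
    are the same as for the frames, so masks stay aligned.
    """
    from .exam import ChamberMaskSet

    factor = pixel_spacing / target_spacing
    out: dict[str, dict[str, np.ndarray]] = {}
    for view, chambers in masks.masks.items():
        out[view] = {}
        for ch, m in chambers.items():
            stack = m if m.ndim == 3 else m[None]
            if abs(factor - 1.0) > 1e-9:
                h, w = stack.shape[1:]
                zoom = (round(h * factor) / h, round(w * factor) / w)
                stack = np.stack([
                    ndimage.zoom(f, zoom, order=0, grid_mode=True,
                                 mode="grid-constant") for f in stack])
            stack = crop_or_pad(stack, size)
            out[view][ch] = stack if m.ndim == 3 else stack[0]
    return ChamberMaskSet(out, per_frame=masks.per_frame)


def preprocess_exam(exam: CineExam, **kwargs) -> CineExam:
    """Preprocess all four views of an exam; masks are resampled alongside."""
    series = {v: preprocess_series(exam.series[v], **kwargs) for v in VIEWS}
    masks = exam.masks
    if masks is not None:
        spacing = exam.series[VIEWS[0]].pixel_spacing
        masks = preprocess_mask_set(
            masks, spacing,
            kwargs.get("target_spacing", TARGET_SPACING),
            kwargs.get("size", FRAME_SIZE))
    return CineExam(series=series, labels=exam.labels, masks=masks,
                    exam_id=exam.exam_id, meta=dict(exam.meta))


def _sample_affine(params: AugmentationParams, rng: np.random.Generator):
    flip = rng.random() < params.flip_prob
    shift = rng.uniform(-params.max_shift_px, params.max_shift_px, size=2)
    scale = rng.uniform(*params.scale_range)
    theta = np.deg2rad(rng.uniform(-params.max_rotation_deg, params.max_rotation_deg))
    return flip, shift, scale, theta


def _apply_affine(frames: np.ndarray, flip: bool, shift: np.ndarray,
                  scale: float, theta: float) -> np.ndarray:
    if not flip and not np.any(shift) and scale == 1.0 and theta == 0.0:
        return frames.copy()
    h, w = frames.shape[1:]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    if flip:  # horizontal mirror: negate the column axis
        rot = rot @ np.diag([1.0, -1.0])
    # affine_transform maps output coords -> input coords, so invert the
    # forward (scale then rotate then shift) transform
    matrix = rot.T / scale
    offset = center - matrix @ (center + shift)
    return _warp_bilinear(frames, matrix, offset)


def _warp_bilinear(frames: np.ndarray, matrix: np.ndarray,
                   offset: np.ndarray) -> np.ndarray:
    """Inverse-map bilinear warp of a (P, H, W) stack, zero outside.

    The source coordinates are computed once and all phases are sampled
    together, which is what makes on-the-fly augmentation cheap enough to
    run every epoch.
    """
    p, h, w = frames.shape
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    sy = matrix[0, 0] * yy + matrix[0, 1] * xx + offset[0]
    sx = matrix[1, 0] * yy + matrix[1, 1] * xx + offset[1]
    valid = (sy >= 0) & (sy <= h - 1) & (sx >= 0) & (sx <= w - 1)
    y0 = np.clip(np.floor(sy).astype(np.intp), 0, h - 2)
    x0 = np.clip(np.floor(sx).astype(np.intp), 0, w - 2)
    wy = (sy - y0).astype(frames.dtype)
    wx = (sx - x0).astype(frames.dtype)
    f00 = frames[:, y0, x0]
    f01 = frames[:, y0, x0 + 1]
    f10 = frames[:, y0 + 1, x0]
    f11 = frames[:, y0 + 1, x0 + 1]
    out = ((1 - wy) * ((1 - wx) * f00 + wx * f01)
           + wy * ((1 - wx) * f10 + wx * f11))
    out *= valid
    return np.clip(out, 0.0, 1.0).astype(frames.dtype)


def augment(exam: CineExam, params: AugmentationParams,
            rng: np.random.Generator | int | None = None) -> CineExam:
    """Randomly flip/shift/scale/rotate each cine series of an exam.

    One transform is drawn per series (or one for the whole exam when
    ``params.shared_across_views``) and applied to all 20 frames, keeping
    the cardiac cycle coherent.  Deterministic given the generator state.
    """
    rng = np.random.default_rng(rng)
    series: dict[str, PreprocessedCineSeries] = {}
    draw = _sample_affine(params, rng) if params.shared_across_views else None
    for v in VIEWS:
        src = exam.series[v]
        sample = draw if draw is not None else _sample_affine(params, rng)
        series[v] = PreprocessedCineSeries(
            _apply_affine(src.frames, *sample), v, src.pixel_spacing
        )
    return CineExam(series=series, labels=exam.labels, masks=exam.masks,
                    exam_id=exam.exam_id, meta=dict(exam.meta))


def augment_array(frames: np.ndarray, params: AugmentationParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Array fast path: augment a (V, P, H, W) stack, one transform per view."""
    out = np.empty_like(frames)
    if params.shared_across_views:
        sample = _sample_affine(params, rng)
        for v in range(frames.shape[0]):
            out[v] = _apply_affine(frames[v], *sample)
        return out
    for v in range(frames.shape[0]):
        out[v] = _apply_affine(frames[v], *_sample_affine(params, rng))
    return out


def _affine_matrix(flip: bool, shift: np.ndarray, scale: float, theta: float,
                   h: int, w: int):
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    if flip:
        rot = rot @ np.diag([1.0, -1.0])
    matrix = rot.T / scale
    return matrix, center - matrix @ (center + shift)


def augment_batch(xb: np.ndarray, params: AugmentationParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Augment a whole (B, V, P, H, W) batch in one vectorized warp.

    Draws exactly the same per-series transforms, in the same generator
    order, as mapping :func:`augment_array` over the batch, and performs
    elementwise-identical bilinear interpolation — only the gather is
    vectorized across all series.
    """
    if params.shared_across_views:
        return np.stack([augment_array(exam, params, rng) for exam in xb])
    b, v, p, h, w = xb.shape
    n = b * v
    mats = np.empty((n, 2, 2))
    offs = np.empty((n, 2))
    for i in range(n):
        mats[i], offs[i] = _affine_matrix(*_sample_affine(params, rng), h, w)

    yy, xx = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    yy, xx = yy.ravel(), xx.ravel()
    sy = mats[:, 0, 0, None] * yy + mats[:, 0, 1, None] * xx + offs[:, 0, None]
    sx = mats[:, 1, 0, None] * yy + mats[:, 1, 1, None] * xx + offs[:, 1, None]
    valid = (sy >= 0) & (sy <= h - 1) & (sx >= 0) & (sx <= w - 1)
    y0 = np.clip(np.floor(sy).astype(np.intp), 0, h - 2)
    x0 = np.clip(np.floor(sx).astype(np.intp), 0, w - 2)
    wy = (sy - y0).astype(xb.dtype)[:, None, :]
    wx = (sx - x0).astype(xb.dtype)[:, None, :]

    flat = np.ascontiguousarray(xb).reshape(n, p, h * w)
    lin = y0 * w + x0

    def gather(offset):
        return np.take_along_axis(flat, (lin + offset)[:, None, :], axis=2)

    f00, f01 = gather(0), gather(1)
    f10, f11 = gather(w), gather(w + 1)
    out = ((1 - wy) * ((1 - wx) * f00 + wx * f01)
           + wy * ((1 - wx) * f10 + wx * f11))
    out *= valid[:, None, :]
    np.clip(out, 0.0, 1.0, out=out)
    return out.reshape(b, v, p, h, w).astype(xb.dtype)
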