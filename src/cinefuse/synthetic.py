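"""Synthetic multi-view cardiac cine phantoms with plantable target signal.

Each exam renders the four standard planes (2CH, 4CH, RVLA, SAX) as noisy
grayscale images containing elliptical chambers — exactly the chambers
anatomically visible in each plane — over a 20-phase cardiac cycle whose
contraction extremum (end-systole) falls at a configurable phase (default
9).  A *signal map* links the regression target to chamber geometry: for
every (view, chamber) pair with a nonzero coefficient, the chamber's linear
size scales with the z-scored target, so ground truth about where the
predictive information lives is known by construction.  By default the
signal lives only in the right ventricle on the short-axis view, mirroring
the chamber/view the clinical model is known to rely on.

Labels emulate a pulmonary-hypertension referral cohort: mPAP is truncated
normal 39.7 +/- 14.5 mmHg (> 0), PVR is linearly linked to mPAP
(0.25 * mPAP - 3 plus noise, floored at 0.1 Wood units), and PAWP is an
independent normal 12.9 +/- 5.4 mmHg clipped to [2, 35].  These conventions
give both precapillary-positive and negative cases in a default draw.

Exams are rendered lazily from per-exam seeds, so cohorts of hundreds of
exams never hold all frames in memory at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .evaluation import HemodynamicTriple
from .exam import (
    N_PHASES,
    TARGET_SPACING,
    VIEW_CHAMBERS,
    VIEWS,
    ChamberMaskSet,
    CineExam,
    RawCineSeries,
)
from .preprocessing import preprocess_exam
from .training import assert_disjoint_splits

__all__ = ["PhantomConfig", "generate_exam", "generate_labels",
           "generate_cohort", "SyntheticCohort", "ExamRecord",
           "downsample_frames", "contraction_profile"]

# (row, col, semi-axis a, semi-axis b, angle deg, role) at 256 px / 0.94 mm
_BASE_GEOMETRY: dict[str, dict[str, tuple]] = {
    "2CH": {"LV": (105, 120, 46, 28, 25, "ventricle"),
            "LA": (172, 152, 27, 22, 0, "atrium")},
    "4CH": {"RV": (105, 95, 40, 24, 10, "ventricle"),
            "RA": (170, 92, 26, 21, 0, "atrium"),
            "LV": (105, 168, 42, 26, -10, "ventricle"),
            "LA": (170, 170, 25, 21, 0, "atrium")},
    "RVLA": {"RV": (105, 115, 45, 27, 15, "ventricle"),
             "RA": (174, 147, 27, 22, 0, "atrium")},
    # SAX chambers are spaced so that even a Gaussian-dilated LV mask can
    # never clip the RV at its largest (signal-enlarged) size: perturbing
    # one chamber must not touch the other's pixels
    "SAX": {"LV": (184, 180, 35, 33, 0, "ventricle"),
            "RV": (88, 84, 32, 21, 30, "ventricle")},
}

_BLOOD_INTENSITY = {"LV": 0.92, "RV": 0.85, "LA": 0.80, "RA": 0.78}
_MYO_INTENSITY = 0.45
_BACKGROUND = 0.15
_RING_SCALE = 1.18


@dataclass
class PhantomConfig:
    """Study conditions for the phantom cohort."""

    image_size: int = 256
    pixel_spacing: float = TARGET_SPACING
    n_phases: int = N_PHASES
    # target distribution (referral-cohort mPAP)
    mpap_mean: float = 39.7
    mpap_sd: float = 14.5
    # label links
    pvr_slope: float = 0.25
    pvr_intercept: float = -3.0
    pvr_noise_sd: float = 1.0
    pawp_mean: float = 12.9
    pawp_sd: float = 5.4
    # image model
    signal_map: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("SAX", "RV"): 0.20})
    contraction: float = 0.20       # end-systolic shrink of ventricle semi-axes
    end_systole_phase: int = 9      # 1-based phase of maximal contraction
    noise_sd: float = 0.04          # background Gaussian noise (pre-scaling)
    edge_blur_sigma: float = 1.0    # soft chamber borders; 0 = hard edges
    jitter_shift_px: float = 6.0    # per-exam pose jitter
    jitter_angle_deg: float = 8.0
    jitter_scale: float = 0.05
    gain_range: tuple[float, float] = (300.0, 500.0)  # arbitrary raw units
    z_clip: tuple[float, float] = (-2.5, 2.8)

    def __post_init__(self):
        for view, chamber in self.signal_map:
            if chamber not in VIEW_CHAMBERS.get(view, ()):
                raise ValueError(f"signal map pair ({view}, {chamber}) is not a "
                                 "valid view/chamber combination")
        if self.noise_sd < 0 or self.contraction < 0 or self.mpap_sd < 0:
            raise ValueError("noise, contraction, and SDs must be nonnegative")


def contraction_profile(phase: np.ndarray | int, n_phases: int = N_PHASES,
                        es_phase: int = 9) -> np.ndarray:
    """Cyclic contraction fraction in [0, 1]; 0 at phase 1, 1 at end-systole."""
    p = np.asarray(phase, dtype=np.float64)
    rising = np.sin(0.5 * np.pi * (p - 1) / (es_phase - 1)) ** 2
    falling = np.sin(0.5 * np.pi * (n_phases - p + 1) / (n_phases - es_phase + 1)) ** 2
    return np.where(p <= es_phase, rising, falling)


def _ellipse(yy, xx, cy, cx, a, b, angle_deg) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(t) + dx * np.sin(t)
    v = -dy * np.sin(t) + dx * np.cos(t)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _ellipse_sparse(size, cy, cx, a, b, angle_deg):
    """Ellipse interior evaluated only on its bounding box.

    Returns (row slice, col slice, boolean patch); a rotated ellipse fits
    inside the circle of radius max(a, b), so evaluating the quadratic on
    that box alone gives the identical pixel set at a fraction of the cost.
    """
    r = max(a, b) + 1.0
    y0 = max(int(np.floor(cy - r)), 0)
    y1 = min(int(np.ceil(cy + r)) + 1, size)
    x0 = max(int(np.floor(cx - r)), 0)
    x1 = min(int(np.ceil(cx + r)) + 1, size)
    if y0 >= y1 or x0 >= x1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0), dtype=bool)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    return slice(y0, y1), slice(x0, x1), _ellipse(yy, xx, cy, cx, a, b, angle_deg)


def generate_exam(config: PhantomConfig, labels: HemodynamicTriple,
                  seed: int, exam_id: str = "") -> CineExam:
    """Render one four-view exam for the given labels; deterministic in seed.

    The returned masks are per-frame and equal, pixel for pixel, to the
    rendered chamber interiors (blurring softens intensities, never the
    mask definition).
    """
    rng = np.random.default_rng(seed)
    size, n_p = config.image_size, config.n_phases
    scale_px = TARGET_SPACING / config.pixel_spacing  # geometry defined at 0.94 mm

    z = (labels.mPAP - config.mpap_mean) / config.mpap_sd
    z = float(np.clip(z, *config.z_clip))

    series: dict[str, RawCineSeries] = {}
    masks: dict[str, dict[str, np.ndarray]] = {}
    phases = np.arange(1, n_p + 1)
    contraction = config.contraction * contraction_profile(
        phases, n_p, config.end_systole_phase)

    for view in VIEWS:
        # one pose per exam and view, shared by all 20 frames
        shift = rng.uniform(-config.jitter_shift_px, config.jitter_shift_px, size=2)
        angle_jit = rng.uniform(-config.jitter_angle_deg, config.jitter_angle_deg)
        size_jit = 1.0 + rng.uniform(-config.jitter_scale, config.jitter_scale)
        gain = rng.uniform(*config.gain_range)
        noise = rng.normal(0.0, config.noise_sd, size=(n_p, size, size))

        chambers = VIEW_CHAMBERS[view]
        # paint signal-carrying chambers last so their geometry is never clipped
        order = sorted(chambers, key=lambda c: (view, c) in config.signal_map)
        frames = np.empty((n_p, size, size), dtype=np.float32)
        view_masks = {c: np.zeros((n_p, size, size), dtype=np.uint8) for c in chambers}

        for k in range(n_p):
            img = _BACKGROUND + noise[k]
            interiors = {}
            for ch in order:
                cy, cx, a, b, ang, role = _BASE_GEOMETRY[view][ch]
                coef = config.signal_map.get((view, ch), 0.0)
                s = size_jit * (1.0 + coef * z)
                s *= (1.0 - contraction[k]) if role == "ventricle" \
                    else (1.0 + 0.5 * contraction[k])
                cy = (cy + shift[0]) * scale_px
                cx = (cx + shift[1]) * scale_px
                a_k, b_k = a * s * scale_px, b * s * scale_px
                interiors[ch] = (cy, cx, a_k, b_k, ang + angle_jit, role)
            # myocardial rings first, interiors second (interiors override)
            for ch in order:
                cy, cx, a_k, b_k, ang, role = interiors[ch]
                if role == "ventricle":
                    sy, sx, patch = _ellipse_sparse(
                        size, cy, cx, a_k * _RING_SCALE, b_k * _RING_SCALE, ang)
                    img[sy, sx][patch] = _MYO_INTENSITY
            claimed = np.zeros((size, size), dtype=bool)
            for ch in order:
                cy, cx, a_k, b_k, ang, _ = interiors[ch]
                sy, sx, patch = _ellipse_sparse(size, cy, cx, a_k, b_k, ang)
                patch &= ~claimed[sy, sx]
                img[sy, sx][patch] = _BLOOD_INTENSITY[ch]
                claimed[sy, sx] |= patch
                view_masks[ch][k, sy, sx][patch] = 1
            frames[k] = img

        if config.edge_blur_sigma > 0:  # one separable filter per view
            frames = ndimage.gaussian_filter(
                frames, sigma=(0, config.edge_blur_sigma, config.edge_blur_sigma))
        frames = np.maximum(frames, 0.0) * gain
        series[view] = RawCineSeries(frames, config.pixel_spacing, view)
        masks[view] = view_masks

    return CineExam(
        series=series,
        labels={"mPAP": labels.mPAP, "PAWP": labels.PAWP, "PVR": labels.PVR},
        masks=ChamberMaskSet(masks, per_frame=True),
        exam_id=exam_id,
        meta={"seed": seed},
    )


def generate_labels(config: PhantomConfig, n: int,
                    rng: np.random.Generator) -> list[HemodynamicTriple]:
    """Draw a cohort of hemodynamic triples from the configured distributions."""
    a = (0.0 - config.mpap_mean) / config.mpap_sd
    mpap = stats.truncnorm.rvs(a, np.inf, loc=config.mpap_mean,
                               scale=config.mpap_sd, size=n, random_state=rng)
    pvr = np.maximum(
        config.pvr_slope * mpap + config.pvr_intercept
        + rng.normal(0.0, config.pvr_noise_sd, size=n),
        0.1,
    )
    pawp = np.clip(rng.normal(config.pawp_mean, config.pawp_sd, size=n), 2.0, 35.0)
    return [HemodynamicTriple(float(m), float(w), float(v))
            for m, w, v in zip(mpap, pawp, pvr)]


@dataclass(frozen=True)
class ExamRecord:
    exam_id: str
    seed: int
    labels: HemodynamicTriple


@dataclass
class SyntheticCohort:
    """A split cohort of lazily rendered exams."""

    config: PhantomConfig
    splits: dict[str, list[ExamRecord]]

    def render(self, record: ExamRecord) -> CineExam:
        return generate_exam(self.config, record.labels, record.seed, record.exam_id)

    def iter_exams(self, split: str):
        for rec in self.splits[split]:
            yield self.render(rec)

    def labels(self, split: str, target: str = "mPAP") -> np.ndarray:
        return np.array([getattr(r.labels, target) for r in self.splits[split]])

    def triples(self, split: str) -> list[HemodynamicTriple]:
        return [r.labels for r in self.splits[split]]

    def load_arrays(self, split: str, target: str = "mPAP", pool: int = 1,
                    preprocess: bool = True, with_chamber_regions: bool = False):
        """Materialise a split as (X, y): X (n, 4, 20, s, s) float32.

        Exams are rendered, preprocessed, and optionally block-averaged by
        `pool` one at a time, so peak memory stays at one full-resolution
        exam plus the pooled output.

        With ``with_chamber_regions`` a third element is returned: per
        exam, a dict ``view -> (n_chambers, s, s)`` of binary regions —
        each chamber's mask united over the cardiac cycle, Gaussian-dilated,
        and pooled — usable as anatomy-shaped occlusion regions in training.
        """
        from .explainability import dilate_mask

        records = self.splits[split]
        xs, all_regions = [], []
        for rec in records:
            exam = self.render(rec)
            if preprocess:
                exam = preprocess_exam(exam)
            arr = exam.to_array()
            xs.append(downsample_frames(arr, pool))
            if with_chamber_regions:
                regions: dict[str, np.ndarray] = {}
                for view in VIEWS:
                    stacks = []
                    for ch in VIEW_CHAMBERS[view]:
                        union = exam.masks.get_stack(view, ch).max(axis=0)
                        pooled = downsample_frames(
                            dilate_mask(union).astype(np.float32), pool)
                        stacks.append((pooled > 0).astype(np.uint8))
                    regions[view] = np.stack(stacks)
                all_regions.append(regions)
        x = np.stack(xs)
        y = self.labels(split, target)
        if with_chamber_regions:
            return x, y, all_regions
        return x, y


def downsample_frames(frames: np.ndarray, pool: int) -> np.ndarray:
    """Block-average the trailing two axes by an integer factor."""
    if pool <= 1:
        return frames.astype(np.float32)
    *lead, h, w = frames.shape
    if h % pool or w % pool:
        raise ValueError(f"frame size {(h, w)} not divisible by pool={pool}")
    out = frames.reshape(*lead, h // pool, pool, w // pool, pool)
    return out.mean(axis=(-3, -1), dtype=np.float32)


def generate_cohort(config: PhantomConfig, n_train: int, n_val: int, n_test: int,
                    seed: int = 0) -> SyntheticCohort:
    """Draw labels and per-exam seeds for disjoint train/val/test splits.

    Default split sizing convention is the 65/15/20 ratio used by the
    reference cohort; any explicit sizes are accepted.
    """
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("all split sizes must be positive")
    rng = np.random.default_rng(seed)
    n = n_train + n_val + n_test
    labels = generate_labels(config, n, rng)
    exam_seeds = rng.integers(0, 2**31 - 1, size=n)
    records = [ExamRecord(f"exam_{i:05d}", int(exam_seeds[i]), labels[i])
               for i in range(n)]
    splits = {"train": records[:n_train],
              "val": records[n_train:n_train + n_val],
              "test": records[n_train + n_val:]}
    assert_disjoint_splits(*[[r.exam_id for r in recs] for recs in splits.values()])
    return SyntheticCohort(config=config, splits=splits)
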