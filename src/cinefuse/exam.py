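"""Core containers for multi-view cardiac cine examinations.

An examination is four 2-D cine series — two-chamber (2CH), four-chamber
(4CH), right-ventricular long-axis (RVLA), and a representative mid-slice
short-axis (SAX) — each covering one cardiac cycle in 20 phases, together
with right-heart-catheter labels (mPAP, PAWP, PVR) and optional per-chamber
binary masks for the chambers anatomically visible in each view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VIEWS: tuple[str, ...] = ("2CH", "4CH", "RVLA", "SAX")
N_PHASES: int = 20
TARGET_SPACING: float = 0.94  # mm per pixel after resampling
FRAME_SIZE: int = 256  # matrix size after crop/pad (240 mm field of view)

#: Chambers visible in each imaging plane.
VIEW_CHAMBERS: dict[str, tuple[str, ...]] = {
    "2CH": ("LV", "LA"),
    "4CH": ("LV", "LA", "RV", "RA"),
    "RVLA": ("RV", "RA"),
    "SAX": ("LV", "RV"),
}
CHAMBERS: tuple[str, ...] = ("LV", "LA", "RV", "RA")
TARGETS: tuple[str, ...] = ("mPAP", "PAWP", "PVR")


@dataclass
class RawCineSeries:
    """One cine series as acquired: frames (P, H, W), isotropic spacing in mm."""

    frames: np.ndarray
    pixel_spacing: float
    view_id: str

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (P, H, W) stack with at least one frame")
        if not self.pixel_spacing > 0:
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        if self.view_id not in VIEWS:
            raise ValueError(f"unknown view {self.view_id!r}; expected one of {VIEWS}")

    @property
    def n_phases(self) -> int:
        return self.frames.shape[0]


@dataclass
class PreprocessedCineSeries:
    """Model-ready series: 20 x 256 x 256, values in [0, 1], 0.94 mm/px."""

    frames: np.ndarray
    view_id: str
    pixel_spacing: float = TARGET_SPACING

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.shape != (N_PHASES, FRAME_SIZE, FRAME_SIZE):
            raise ValueError(
                f"preprocessed series must be {(N_PHASES, FRAME_SIZE, FRAME_SIZE)}, "
                f"got {self.frames.shape}"
            )
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"intensities must lie in [0, 1], got [{lo}, {hi}]")


@dataclass
class ChamberMaskSet:
    """Binary chamber masks per view.

    ``masks[view][chamber]`` is either one (H, W) mask applied to all phases
    (``per_frame=False``) or a (P, H, W) stack (``per_frame=True``).  Only the
    (view, chamber) pairs in :data:`VIEW_CHAMBERS` may appear.
    """

    masks: dict[str, dict[str, np.ndarray]]
    per_frame: bool = False

    def __post_init__(self):
        for view, chambers in self.masks.items():
            for chamber, m in chambers.items():
                if chamber not in VIEW_CHAMBERS.get(view, ()):
                    raise ValueError(f"chamber {chamber} is not visible in view {view}")
                m = np.asarray(m)
                if not ((m == 0) | (m == 1)).all():
                    raise ValueError(f"mask for {view}/{chamber} is not binary")
                expected_ndim = 3 if self.per_frame else 2
                if m.ndim != expected_ndim:
                    raise ValueError(
                        f"mask for {view}/{chamber} has ndim {m.ndim}, "
                        f"expected {expected_ndim}"
                    )
                chambers[chamber] = m.astype(np.uint8)

    def get_stack(self, view: str, chamber: str, n_phases: int = N_PHASES) -> np.ndarray:
        """Mask as a (P, H, W) stack regardless of storage convention."""
        m = self.masks[view][chamber]
        if self.per_frame:
            return m
        return np.broadcast_to(m, (n_phases,) + m.shape)


@dataclass
class CineExam:
    """A complete examination: one series per view plus labels and masks."""

    series: dict[str, RawCineSeries | PreprocessedCineSeries]
    labels: dict[str, float] | None = None
    masks: ChamberMaskSet | None = None
    exam_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [v for v in VIEWS if v not in self.series]
        if missing:
            raise ValueError(f"exam {self.exam_id!r} is missing views {missing}")

    def to_array(self) -> np.ndarray:
        """Stack the four views into a (4, P, H, W) array in VIEWS order."""
        return np.stack([self.series[v].frames for v in VIEWS])
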