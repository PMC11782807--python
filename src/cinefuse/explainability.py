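"""The three built-in importance analyses.

1. *Per-feature performance*: because fusion preserves the feature
   dimension, the shared regression layer can score every one of the 80
   frame features, 24 summaries, and the final feature; each feature's
   prediction is evaluated (MAE/PCC/R^2) over a dataset.
2. *Attention weights*: the normalised softmax weights of every fusion
   group, averaged over exams.  Groups are reported separately and never
   renormalised against each other.
3. *Chamber perturbation*: complementary mask/paste occlusion.  Chamber
   masks are first dilated by thresholding a truncated Gaussian filter
   (sigma 4 px, radius 16 px) at zero, hiding exact area and boundary-shape
   information.  *Masking* zeroes the chamber region in the selected
   view(s) and leaves everything else intact; *pasting* keeps only the
   chamber region of the selected view(s) on an otherwise black input.
   For any mask the two perturbed inputs sum back to the original exam
   pixel-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .evaluation import mae as _mae
from .evaluation import pearson_corr, r_squared
from .exam import VIEW_CHAMBERS, VIEWS, CHAMBERS, ChamberMaskSet
from .network import MultiViewCineNet
from .synthetic import downsample_frames

logger = logging.getLogger(__name__)

__all__ = ["per_feature_performance", "mean_attention_weights", "dilate_mask",
           "apply_mask", "apply_paste", "chamber_importance", "PerturbationGrid"]

ALL_VIEWS_ROW = "All views"


def _safe_pcc(truth, pred):
    try:
        return pearson_corr(truth, pred)
    except ValueError:
        logger.warning("PCC undefined (constant input); reporting NaN")
        return float("nan")


def _safe_r2(truth, pred):
    try:
        return r_squared(truth, pred)
    except ValueError:
        return float("nan")


def _collect_traces(net: MultiViewCineNet, x: np.ndarray, batch_size: int = 16):
    """Run forward_trace over batches and concatenate the batched traces."""
    from .network import BatchTrace

    parts = []
    for i in range(0, len(x), batch_size):
        _, tr = net.forward_trace(x[i:i + batch_size])
        parts.append(tr)
    fields = {
        name: np.concatenate([getattr(p, name) for p in parts])
        for name in BatchTrace.__dataclass_fields__
    }
    return BatchTrace(**fields)


def per_feature_performance(net: MultiViewCineNet, x: np.ndarray, y: np.ndarray,
                            batch_size: int = 16) -> pd.DataFrame:
    """Score every component and fused feature by its own regression metrics.

    Returns one row per feature — V*P frame features, P spatial summaries,
    V temporal summaries, and the final feature (105 rows for the 4 x 20
    model) — with columns for identity (level/view/phase), MAE, PCC, R^2,
    and the mean normalised attention weight(s) of the fusion group(s) the
    feature takes part in.
    """
    y = np.asarray(y, dtype=np.float64)
    trace = _collect_traces(net, x, batch_size)
    views = list(net.config.views)
    n_p = net.config.n_phases
    mean_view_alpha = trace.view_alpha.mean(axis=0)    # (V, P)
    mean_phase_alpha = trace.phase_alpha.mean(axis=0)  # (V, P)
    mean_s2_alpha = trace.stage2_alpha.mean(axis=0)    # (P+V,)

    rows = []
    for vi, view in enumerate(views):
        for p in range(n_p):
            pred = trace.frame_predictions[:, vi, p]
            rows.append({
                "level": "frame", "view": view, "phase": p + 1,
                "mae": _mae(y, pred), "pcc": _safe_pcc(y, pred),
                "r2": _safe_r2(y, pred),
                "mean_view_weight": mean_view_alpha[vi, p],
                "mean_phase_weight": mean_phase_alpha[vi, p],
                "mean_stage2_weight": np.nan,
            })
    for p in range(n_p):
        pred = trace.spatial_predictions[:, p]
        rows.append({
            "level": "spatial", "view": None, "phase": p + 1,
            "mae": _mae(y, pred), "pcc": _safe_pcc(y, pred),
            "r2": _safe_r2(y, pred),
            "mean_view_weight": np.nan, "mean_phase_weight": np.nan,
            "mean_stage2_weight": mean_s2_alpha[p],
        })
    for vi, view in enumerate(views):
        pred = trace.temporal_predictions[:, vi]
        rows.append({
            "level": "temporal", "view": view, "phase": None,
            "mae": _mae(y, pred), "pcc": _safe_pcc(y, pred),
            "r2": _safe_r2(y, pred),
            "mean_view_weight": np.nan, "mean_phase_weight": np.nan,
            "mean_stage2_weight": mean_s2_alpha[n_p + vi],
        })
    pred = trace.final_prediction
    rows.append({
        "level": "final", "view": None, "phase": None,
        "mae": _mae(y, pred), "pcc": _safe_pcc(y, pred), "r2": _safe_r2(y, pred),
        "mean_view_weight": np.nan, "mean_phase_weight": np.nan,
        "mean_stage2_weight": np.nan,
    })
    return pd.DataFrame(rows)


def mean_attention_weights(net: MultiViewCineNet, x: np.ndarray,
                           batch_size: int = 16) -> dict[str, np.ndarray]:
    """Normalised attention weights averaged over exams, per fusion group.

    Returns ``view_wise`` (P, V) — one row per phase summing to 1 over
    views; ``phase_wise`` (V, P) — one row per view summing to 1 over
    phases; ``stage2`` (P+V,) summing to 1; and the convenience
    ``view_mean`` (V,), the per-view average of the view-wise rows (still
    summing to 1).  Groups are never renormalised across each other.
    """
    trace = _collect_traces(net, x, batch_size)
    view_wise = trace.view_alpha.mean(axis=0).T       # (P, V)
    phase_wise = trace.phase_alpha.mean(axis=0)       # (V, P)
    stage2 = trace.stage2_alpha.mean(axis=0)          # (P+V,)
    return {
        "view_wise": view_wise,
        "phase_wise": phase_wise,
        "stage2": stage2,
        "view_mean": view_wise.mean(axis=0),
    }


def dilate_mask(mask: np.ndarray, sigma: float = 4.0, radius: int = 16) -> np.ndarray:
    """Dilate a binary mask: truncated Gaussian filter, thresholded at zero.

    The kernel is truncated at `radius` pixels, so a single pixel dilates to
    a (2*radius+1)-square footprint.  Values exactly zero after filtering
    stay background, so an empty mask stays empty and the output always
    contains the input support.
    """
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary (0/1)")
    filtered = ndimage.gaussian_filter(mask.astype(np.float64), sigma=sigma,
                                       truncate=radius / sigma)
    return (filtered > 0).astype(np.uint8)


def _check_alignment(frames: np.ndarray, mask: np.ndarray):
    if mask.shape != frames.shape[-mask.ndim:]:
        raise ValueError(f"mask shape {mask.shape} does not align with "
                         f"frames {frames.shape}")


def apply_mask(frames: np.ndarray, masks: dict[str, np.ndarray]) -> np.ndarray:
    """Zero out the masked region in the selected views of a (V, P, H, W) exam.

    ``masks`` maps view_id -> (P, H, W) or (H, W) binary mask; views without
    an entry are untouched.
    """
    out = np.array(frames, copy=True)
    for view, m in masks.items():
        vi = VIEWS.index(view)
        _check_alignment(out[vi], m)
        out[vi] = out[vi] * (1 - m)
    return out


def apply_paste(frames: np.ndarray, masks: dict[str, np.ndarray]) -> np.ndarray:
    """Keep only the masked region of the selected views on a black canvas."""
    out = np.zeros_like(np.asarray(frames))
    src = np.asarray(frames)
    for view, m in masks.items():
        vi = VIEWS.index(view)
        _check_alignment(src[vi], m)
        out[vi] = src[vi] * m
    return out


@dataclass
class PerturbationGrid:
    """Perturbed test-set PCC per mode x view x chamber, plus the intact PCC."""

    table: pd.DataFrame  # columns: mode, view, chamber, pcc, n
    intact_pcc: float

    def pivot(self, mode: str) -> pd.DataFrame:
        sub = self.table[self.table["mode"] == mode]
        grid = sub.pivot(index="view", columns="chamber", values="pcc")
        order = [v for v in (*VIEWS, ALL_VIEWS_ROW) if v in grid.index]
        cols = [c for c in CHAMBERS if c in grid.columns]
        return grid.loc[order, cols]


def _chamber_cells() -> list[tuple[str, str]]:
    cells = [(view, ch) for view in VIEWS for ch in VIEW_CHAMBERS[view]]
    cells += [(ALL_VIEWS_ROW, ch) for ch in CHAMBERS]
    return cells


def chamber_importance(net: MultiViewCineNet, exams, truth,
                       pool: int = 1, sigma: float = 4.0, radius: int = 16,
                       ) -> PerturbationGrid:
    """Mask/paste every chamber in every view and re-measure test-set PCC.

    ``exams`` is an iterable of ``(frames, mask_set)`` pairs — frames of
    shape (V, P, H, W) at full preprocessed resolution, masks a
    :class:`ChamberMaskSet` aligned to them.  ``pool`` block-averages the
    perturbed frames before they enter the network (for reduced-resolution
    profiles).  Exams are processed one at a time, so memory stays flat.

    The grid has a row per view plus an "All views" row; cells exist only
    where the chamber is visible in the view.  A cell whose perturbed
    predictions are degenerate (e.g. constant) reports NaN.
    """
    truth = np.asarray(truth, dtype=np.float64)
    cells = _chamber_cells()
    preds: dict[tuple[str, str, str], list[float]] = {
        (mode, view, ch): [] for mode in ("mask", "paste") for view, ch in cells
    }
    intact: list[float] = []

    for frames, mask_set in exams:
        frames = np.asarray(frames, dtype=np.float32)
        n_phases = frames.shape[1]
        dilated: dict[tuple[str, str], np.ndarray] = {}
        for view in VIEWS:
            for ch in VIEW_CHAMBERS[view]:
                stack = mask_set.get_stack(view, ch, n_phases)
                dilated[(view, ch)] = np.stack(
                    [dilate_mask(m, sigma, radius) for m in stack])

        # all perturbed variants of one exam go through a single forward
        variants = [downsample_frames(frames, pool)]
        keys: list[tuple[str, str, str]] = []
        for view, ch in cells:
            if view == ALL_VIEWS_ROW:
                sel = {v: dilated[(v, ch)] for v in VIEWS
                       if ch in VIEW_CHAMBERS[v]}
            else:
                sel = {view: dilated[(view, ch)]}
            for mode, op in (("mask", apply_mask), ("paste", apply_paste)):
                variants.append(downsample_frames(op(frames, sel), pool))
                keys.append((mode, view, ch))
        batch_preds = net.predict(np.stack(variants))
        intact.append(float(batch_preds[0]))
        for key, value in zip(keys, batch_preds[1:]):
            preds[key].append(float(value))

    rows = []
    for (mode, view, ch), p in preds.items():
        p = np.asarray(p)
        rows.append({"mode": mode, "view": view, "chamber": ch,
                     "pcc": _safe_pcc(truth, p), "n": len(p)})
    return PerturbationGrid(table=pd.DataFrame(rows),
                            intact_pcc=_safe_pcc(truth, np.asarray(intact)))
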