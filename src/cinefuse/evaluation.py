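"""Regression metrics and the precapillary-PH diagnostic rule.

Regression performance is summarised by the mean absolute error (MAE, in
target units), the Pearson correlation coefficient (PCC), and the
coefficient of determination

    R^2 = 1 - SS_residual / SS_total,

with SS_total taken about the ground-truth mean, so a predictor worse than
the mean gives a negative R^2.  Bland-Altman agreement uses the sample
(n-1) standard deviation for the 1.96-SD limits.  The diagnostic rule flags
precapillary pulmonary hypertension in the absence of left-heart disease:
mPAP > 20 mmHg, PVR > 2 Wood units, and PAWP <= 15 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RegressionReport",
    "HemodynamicTriple",
    "DiagnosticReport",
    "mae",
    "pearson_corr",
    "r_squared",
    "regression_report",
    "bland_altman",
    "classify_precapillary",
    "diagnostic_report",
]

# precapillary-PH thresholds (mmHg, Wood units, mmHg)
MPAP_THRESHOLD = 20.0
PVR_THRESHOLD = 2.0
PAWP_THRESHOLD = 15.0


@dataclass(frozen=True)
class HemodynamicTriple:
    """mPAP (mmHg), PAWP (mmHg), PVR (Wood units)."""

    mPAP: float
    PAWP: float
    PVR: float

    def __post_init__(self):
        for name in ("mPAP", "PAWP", "PVR"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"{name} must be a finite number, got {v!r}")


@dataclass(frozen=True)
class RegressionReport:
    mae: float
    pcc: float
    r2: float
    n: int

    def __str__(self):
        return (f"n={self.n}  MAE={self.mae:.3f}  PCC={self.pcc:.3f}  "
                f"R2={self.r2:.3f}")


@dataclass(frozen=True)
class DiagnosticReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def _check_pair(truth, pred, min_n: int = 1):
    truth = np.asarray(truth, dtype=np.float64).ravel()
    pred = np.asarray(pred, dtype=np.float64).ravel()
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {truth.size}")
    return truth, pred


def mae(truth, pred) -> float:
    truth, pred = _check_pair(truth, pred, min_n=1)
    return float(np.mean(np.abs(truth - pred)))


def pearson_corr(truth, pred) -> float:
    truth, pred = _check_pair(truth, pred, min_n=2)
    if np.std(truth) == 0 or np.std(pred) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(truth, pred).statistic)


def r_squared(truth, pred) -> float:
    truth, pred = _check_pair(truth, pred, min_n=2)
    ss_total = float(np.sum((truth - truth.mean()) ** 2))
    if ss_total == 0:
        raise ValueError("R^2 undefined: ground truth is constant")
    ss_residual = float(np.sum((truth - pred) ** 2))
    return 1.0 - ss_residual / ss_total


def regression_report(truth, pred) -> RegressionReport:
    truth, pred = _check_pair(truth, pred, min_n=2)
    return RegressionReport(mae=mae(truth, pred), pcc=pearson_corr(truth, pred),
                            r2=r_squared(truth, pred), n=truth.size)


def bland_altman(truth, pred) -> tuple[float, tuple[float, float]]:
    """Mean difference (pred - truth) and its 1.96-sample-SD limits of agreement."""
    truth, pred = _check_pair(truth, pred, min_n=2)
    diff = pred - truth
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def classify_precapillary(triple: HemodynamicTriple) -> bool:
    """Precapillary PH without left-heart disease, exactly as printed:
    mPAP > 20 mmHg AND PVR > 2 Wood units AND PAWP <= 15 mmHg."""
    return (triple.mPAP > MPAP_THRESHOLD
            and triple.PVR > PVR_THRESHOLD
            and triple.PAWP <= PAWP_THRESHOLD)


def diagnostic_report(pred_triples, truth_triples) -> DiagnosticReport:
    """Apply the rule to predictions and ground truth; tabulate the confusion."""
    pred_triples = list(pred_triples)
    truth_triples = list(truth_triples)
    if len(pred_triples) != len(truth_triples):
        raise ValueError("prediction and truth lists differ in length")
    tp = fp = tn = fn = 0
    for p, t in zip(pred_triples, truth_triples):
        ph, th = classify_precapillary(p), classify_precapillary(t)
        if ph and th:
            tp += 1
        elif ph and not th:
            fp += 1
        elif not ph and th:
            fn += 1
        else:
            tn += 1
    return DiagnosticReport(tp=tp, fp=fp, tn=tn, fn=fn)
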