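"""Discrimination, calibration and meta-analysis machinery.

ROC/AUC uses the rank (Mann–Whitney) statistic with ties counted one half and
the Hanley–McNeil standard error; the ROC-derived cut-off maximises Youden's
J; the classification table reports sensitivity, specificity, the diagnostic
odds ratio and percent correctly classified; calibration compares mean
predicted probability with the observed event rate within quintiles; AUCs
from several studies are pooled with a DerSimonian–Laird random-effects
meta-analysis.
"""

from __future__ import annotations

import json
import math
import warnings as _warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DegenerateInputError

__all__ = [
    "ROCResult",
    "ClassificationTable",
    "CalibrationBin",
    "CalibrationBins",
    "MetaAnalysisResult",
    "roc_auc",
    "roc_cutoff",
    "classification_table",
    "calibration_quintiles",
    "meta_auc",
]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    points: tuple[tuple[float, float], ...]  # (fpr, tpr), from (0,0) to (1,1)
    thresholds: tuple[float, ...]            # score value per point; +inf at (0,0)
    n_pos: int
    n_neg: int


def roc_auc(probs: Sequence[float], outcomes: Sequence[int]) -> ROCResult:
    """Rank-based AUC with tie correction, Hanley–McNeil SE and curve points.

    AUC equals the concordance P(score_event > score_nonevent) + ½ P(tie).
    Curve points are generated from every distinct threshold with the
    positive rule ``score ≥ threshold``.
    """
    scores = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("probs and outcomes must be 1-D sequences of equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("need at least one event and one non-event")

    ranks = rankdata(scores)  # average ranks handle ties as ½
    auc = (float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # Hanley–McNeil standard error
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_y = y[order]
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    thresholds: list[float] = [math.inf]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            tp += int(sorted_y[j] == 1)
            fp += int(sorted_y[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        thresholds.append(float(sorted_scores[i]))
        i = j

    return ROCResult(
        auc=auc,
        se=se,
        points=tuple(points),
        thresholds=tuple(thresholds),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def roc_cutoff(roc: ROCResult) -> float:
    """Threshold maximising Youden's J = sensitivity + specificity − 1.

    Ties are broken toward higher specificity (fewer predicted positives).
    The returned cut-off is the midpoint between the selected distinct score
    and the next lower one (scores are probabilities, so the virtual bounds
    are 0 and 1), which keeps the ``≥`` prediction rule unambiguous.
    """
    best_index = 0
    best_j = -math.inf
    for i, (fpr, tpr) in enumerate(roc.points):
        j = tpr - fpr
        # strictly-better J wins; on a tie prefer lower fpr (higher cut-off)
        if j > best_j or (j == best_j and fpr < roc.points[best_index][0]):
            best_j = j
            best_index = i

    distinct = list(roc.thresholds[1:])  # descending distinct scores
    if best_index == 0:  # predict nobody positive: cut above the top score
        return (distinct[0] + 1.0) / 2.0
    upper = distinct[best_index - 1]
    lower = distinct[best_index] if best_index < len(distinct) else 0.0
    return (upper + lower) / 2.0


@dataclass(frozen=True)
class ClassificationTable:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    dor: float          # diagnostic odds ratio; inf when a cell is empty
    pct_correct: float  # percent

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "dor": self.dor if math.isfinite(self.dor) else "inf",
            "pct_correct": self.pct_correct,
        }


def classification_table(
    probs: Sequence[float],
    outcomes: Sequence[int],
    cutoff: float,
    continuity_correction: bool = False,
) -> ClassificationTable:
    """2×2 table at a cut-off; caesarean predicted iff probability ≥ cutoff.

    With an empty cell the DOR is reported as ``inf`` with a warning unless
    ``continuity_correction`` adds 0.5 to every cell.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    scores = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))

    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    if continuity_correction:
        dor = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
    elif min(tp, fp, tn, fn) == 0:
        _warnings.warn(
            "empty cell in classification table; diagnostic odds ratio reported as inf",
            stacklevel=2,
        )
        dor = math.inf
    else:
        dor = (tp * tn) / (fp * fn)
    n = tp + fp + tn + fn
    return ClassificationTable(
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        dor=dor,
        pct_correct=100.0 * (tp + tn) / n,
    )


@dataclass(frozen=True)
class CalibrationBin:
    n: int
    mean_predicted: float
    observed_rate: float


@dataclass(frozen=True)
class CalibrationBins:
    bins: tuple[CalibrationBin, ...]

    def to_dict(self) -> dict:
        return {
            "bins": [
                {
                    "n": b.n,
                    "mean_predicted": b.mean_predicted,
                    "observed_rate": b.observed_rate,
                }
                for b in self.bins
            ]
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def calibration_quintiles(
    probs: Sequence[float], outcomes: Sequence[int], n_bins: int = 5
) -> CalibrationBins:
    """Mean predicted vs observed event rate within quantile bins.

    Records are ranked by predicted probability and split into ``n_bins``
    near-equal bins; when n is not divisible, the remainder goes to the
    lowest-probability bins.
    """
    scores = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n = len(scores)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} records for {n_bins} bins")
    order = np.argsort(scores, kind="stable")
    base, remainder = divmod(n, n_bins)
    bins: list[CalibrationBin] = []
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < remainder else 0)
        idx = order[start : start + size]
        bins.append(
            CalibrationBin(
                n=size,
                mean_predicted=float(np.mean(scores[idx])),
                observed_rate=float(np.mean(y[idx])),
            )
        )
        start += size
    return CalibrationBins(bins=tuple(bins))


@dataclass(frozen=True)
class MetaAnalysisResult:
    pooled_auc: float
    ci_low: float
    ci_high: float
    se: float
    tau2: float
    i2: float  # percent
    q: float
    weights: tuple[float, ...]  # normalised random-effects weights

    def to_dict(self) -> dict:
        return {
            "pooled_auc": self.pooled_auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "se": self.se,
            "tau2": self.tau2,
            "i2": self.i2,
            "q": self.q,
            "weights": list(self.weights),
        }


def meta_auc(studies: Sequence[tuple[float, float]]) -> MetaAnalysisResult:
    """DerSimonian–Laird random-effects pooling of per-study (AUC, SE) pairs.

    Fixed-effect weights 1/SE² feed Cochran's Q; τ² = max(0, (Q − df)/C) with
    C = Σw − Σw²/Σw; random-effects weights are 1/(SE² + τ²); the 95% CI uses
    the normal quantile.  I² = max(0, (Q − df)/Q), reported as a percent.
    """
    if len(studies) == 0:
        raise ValueError("at least one study is required")
    aucs = np.array([a for a, _ in studies], dtype=float)
    ses = np.array([s for _, s in studies], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("every study must have a positive standard error")

    w = 1.0 / ses**2
    mu_fixed = float(np.sum(w * aucs) / np.sum(w))
    q = float(np.sum(w * (aucs - mu_fixed) ** 2))
    df = len(studies) - 1
    if df > 0:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        i2 = 100.0 * max(0.0, (q - df) / q) if q > 0 else 0.0
    else:
        tau2 = 0.0
        i2 = 0.0

    w_re = 1.0 / (ses**2 + tau2)
    pooled = float(np.sum(w_re * aucs) / np.sum(w_re))
    se_pooled = float(1.0 / math.sqrt(np.sum(w_re)))
    z = float(norm.ppf(0.975))
    return MetaAnalysisResult(
        pooled_auc=pooled,
        ci_low=pooled - z * se_pooled,
        ci_high=pooled + z * se_pooled,
        se=se_pooled,
        tau2=tau2,
        i2=i2,
        q=q,
        weights=tuple(float(x) for x in (w_re / np.sum(w_re))),
    )
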