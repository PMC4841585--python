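"""Prediction-quality metrics: SN, SP, ACC, MCC, ROC and AUC.

    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

AUC is the area under the ROC curve obtained by sweeping a threshold over
the predicted probabilities (trapezoidal rule, tied scores grouped into one
step); it equals the probability that a random positive outscores a random
negative.  Repeated cross-validation results are aggregated as mean +/-
sample standard deviation per metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

SCALAR_METRICS = ("AUC", "SN", "SP", "ACC", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_calls(cls, labels: Sequence[int], calls: Sequence[int]) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        c = np.asarray(calls, dtype=int)
        if y.shape != c.shape:
            raise ValueError("labels and calls must have equal length")
        return cls(
            TP=int(((y == 1) & (c == 1)).sum()),
            TN=int(((y == 0) & (c == 0)).sum()),
            FP=int(((y == 0) & (c == 1)).sum()),
            FN=int(((y == 1) & (c == 0)).sum()),
        )


@dataclass
class MetricsReport:
    """Scalar metrics plus (optionally) the ROC curve they came from."""

    SN: float
    SP: float
    ACC: float
    MCC: float
    AUC: float = math.nan
    roc: pd.DataFrame | None = None  # columns FPR, TPR
    counts: ConfusionCounts | None = None

    def scalars(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in SCALAR_METRICS}

    def to_text(self, percent: bool = True) -> str:
        """Render a one-row table (SN/SP/ACC as percent, AUC/MCC as values)."""
        row = self.scalars()
        parts = []
        for m in SCALAR_METRICS:
            v = row[m]
            if percent and m in ("SN", "SP", "ACC"):
                parts.append(f"{m}={100 * v:.2f}%")
            else:
                parts.append(f"{m}={v:.4f}")
        return "  ".join(parts)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Exact SN/SP/ACC/MCC arithmetic from a confusion matrix.

    When a class is absent from the truth, the corresponding rate (SN or SP)
    is undefined and reported as NaN.  When any factor of the MCC
    denominator is zero, MCC is 0 by convention (logged).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero evaluated examples")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = tp / (tp + fn) if tp + fn else math.nan
    sp = tn / (tn + fp) if tn + fp else math.nan
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.warning("MCC denominator has a zero factor; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(SN=sn, SP=sp, ACC=acc, MCC=mcc, counts=counts)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[pd.DataFrame, float]:
    """ROC points and trapezoidal AUC from probabilities and binary labels.

    Tied scores collapse into a single threshold step, so the AUC equals the
    pairwise concordance probability (Mann-Whitney U / (n_pos * n_neg), ties
    counted half).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    roc = pd.DataFrame({"FPR": fpr, "TPR": tpr})
    return roc, float(_trapezoid_auc(fpr, tpr))


def evaluate_predictions(
    labels: Sequence[int], probabilities: Sequence[float], cutoff: float = 0.5
) -> MetricsReport:
    """Full report (Eq.-style scalars + ROC/AUC) for one prediction set."""
    calls = (np.asarray(probabilities, dtype=float) > cutoff).astype(int)
    report = compute_metrics(ConfusionCounts.from_calls(labels, calls))
    report.roc, report.AUC = roc_auc(probabilities, labels)
    return report


@dataclass
class MetricsSummary:
    """Mean +/- sample SD of scalar metrics across cross-validation repeats."""

    mean: dict[str, float]
    sd: dict[str, float]
    per_repeat: list[MetricsReport] = field(default_factory=list)

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        """One row per metric in the conventional report layout."""
        rows = []
        for m in SCALAR_METRICS:
            mu, sd = self.mean[m], self.sd[m]
            if percent and m in ("SN", "SP", "ACC"):
                mu, sd = 100 * mu, 100 * sd
            rows.append({"metric": m, "mean": round(mu, 4), "sd": round(sd, 4)})
        return pd.DataFrame(rows)

    def to_text(self, percent: bool = True) -> str:
        parts = []
        for m in SCALAR_METRICS:
            mu, sd = self.mean[m], self.sd[m]
            if percent and m in ("SN", "SP", "ACC"):
                parts.append(f"{m}={100 * mu:.2f}±{100 * sd:.2f}%")
            else:
                parts.append(f"{m}={mu:.4f}±{sd:.4f}")
        return "  ".join(parts)


def summarize(reports: Sequence[MetricsReport]) -> MetricsSummary:
    """Arithmetic mean and sample standard deviation per scalar metric."""
    if not reports:
        raise ValueError("need at least one report to summarize")
    mean, sd = {}, {}
    for m in SCALAR_METRICS:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        mean[m] = float(vals.mean())
        sd[m] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return MetricsSummary(mean=mean, sd=sd, per_repeat=list(reports))


def write_report(summary: MetricsSummary, path: str | Path) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False)


def write_roc(roc: pd.DataFrame, path: str | Path) -> None:
    roc.to_csv(path, sep="\t", index=False)
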