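"""Binary-classification metric battery for interface prediction.

Covers the thresholded confusion-matrix rates (TPR, TNR, PPV, NPV, ACC and
their complements), the derived summary scores (balanced accuracy, Matthews
correlation coefficient, F1 and the Dice coefficient, which coincide for
binary label sets), and the rank-based areas (ROC-AUC, PR-AUC), plus
per-structure aggregation by median (the convention for the AUCs) or by
pooling confusion counts.

MCC is computable from counts or, when only the four predictive rates are
known (e.g. transcribing a published table), from the rate-product identity

    MCC = sqrt(TPR * TNR * PPV * NPV) - sqrt(FNR * FPR * FDR * FOR)

which agrees exactly with the count formula whenever all denominators are
positive.  Undefined rates (zero denominator) are carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionRates",
    "MetricsReport",
    "confusion_rates",
    "summary_metrics",
    "rank_metrics",
    "evaluate_predictions",
    "aggregate",
]

DEFAULT_THRESHOLD = 0.5  # predicted positive iff probability >= threshold


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


@dataclass
class ConfusionRates:
    """Confusion counts and the full set of derived rates.

    Counts are ``None`` when the rates were supplied directly (e.g. from a
    published table) rather than computed from predictions.
    """

    TPR: float
    TNR: float
    PPV: float
    NPV: float
    ACC: float = float("nan")
    TP: int | None = None
    FP: int | None = None
    TN: int | None = None
    FN: int | None = None

    @property
    def FNR(self) -> float:
        return 1.0 - self.TPR

    @property
    def FPR(self) -> float:
        return 1.0 - self.TNR

    @property
    def FDR(self) -> float:
        return 1.0 - self.PPV

    @property
    def FOR(self) -> float:
        return 1.0 - self.NPV

    @property
    def has_counts(self) -> bool:
        return self.TP is not None

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "ConfusionRates":
        return cls(
            TPR=_ratio(tp, tp + fn),
            TNR=_ratio(tn, tn + fp),
            PPV=_ratio(tp, tp + fp),
            NPV=_ratio(tn, tn + fn),
            ACC=_ratio(tp + tn, tp + fp + tn + fn),
            TP=tp, FP=fp, TN=tn, FN=fn,
        )


def confusion_rates(
    probs: np.ndarray, labels: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> ConfusionRates:
    """Threshold probabilities (positive iff >= threshold) and count."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.size == 0:
        raise ValueError("empty input")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels have different lengths")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionRates.from_counts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


@dataclass
class MetricsReport:
    BACC: float = float("nan")
    MCC: float = float("nan")
    F1: float = float("nan")
    DICE: float = float("nan")
    ROC_AUC: float = float("nan")
    PR_AUC: float = float("nan")
    rates: ConfusionRates | None = None

    def as_dict(self) -> dict[str, float]:
        out = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "rates"}
        if self.rates is not None:
            out.update(
                {
                    name: getattr(self.rates, name)
                    for name in ("TPR", "TNR", "PPV", "NPV", "ACC", "FNR", "FPR", "FDR", "FOR")
                }
            )
        return out


def _mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return float("nan")
    return (tp * tn - fp * fn) / np.sqrt(den)


def summary_metrics(rates: ConfusionRates) -> MetricsReport:
    """Derive BACC, MCC, F1 and Dice from a confusion table (or bare rates)."""
    bacc = (rates.TPR + rates.TNR) / 2.0
    if rates.has_counts:
        mcc = _mcc_from_counts(rates.TP, rates.FP, rates.TN, rates.FN)
        dice = _ratio(2 * rates.TP, 2 * rates.TP + rates.FP + rates.FN)
    else:
        mcc = float(
            np.sqrt(rates.TPR * rates.TNR * rates.PPV * rates.NPV)
            - np.sqrt(rates.FNR * rates.FPR * rates.FDR * rates.FOR)
        )
        dice = _ratio(2 * rates.PPV * rates.TPR, rates.PPV + rates.TPR)
    f1 = _ratio(2 * rates.PPV * rates.TPR, rates.PPV + rates.TPR)
    return MetricsReport(BACC=bacc, MCC=mcc, F1=f1, DICE=dice, rates=rates)


def rank_metrics(probs: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """ROC-AUC (Mann-Whitney, ties count 1/2) and PR-AUC (step interpolation
    over recall).  NaN when only one class is present."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        return float("nan"), float("nan")
    return float(roc_auc_score(labels, probs)), float(average_precision_score(labels, probs))


def evaluate_predictions(
    probs: np.ndarray, labels: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> MetricsReport:
    """Full battery for one structure (or one pooled set) of residues."""
    rates = confusion_rates(probs, labels, threshold)
    report = summary_metrics(rates)
    report.ROC_AUC, report.PR_AUC = rank_metrics(probs, labels)
    return report


def aggregate(per_structure: list[MetricsReport], method: str = "median") -> MetricsReport:
    """Aggregate per-structure reports.

    ``median``: NaN-aware median of every metric across structures (the
    convention used for the AUCs).  ``pooled``: recompute the threshold
    metrics from summed confusion counts (equivalent to concatenating all
    residues); the AUCs are still aggregated by median, since pooling rank
    metrics requires the raw scores.
    """
    if not per_structure:
        raise ValueError("nothing to aggregate")
    if method not in ("median", "pooled"):
        raise ValueError(f"unknown aggregation method {method!r}")

    def med(name: str) -> float:
        vals = np.array([getattr(r, name) for r in per_structure], dtype=float)
        return float(np.nanmedian(vals)) if not np.isnan(vals).all() else float("nan")

    roc, pr = med("ROC_AUC"), med("PR_AUC")
    if method == "median":
        return MetricsReport(
            BACC=med("BACC"), MCC=med("MCC"), F1=med("F1"), DICE=med("DICE"),
            ROC_AUC=roc, PR_AUC=pr,
        )
    if any(r.rates is None or not r.rates.has_counts for r in per_structure):
        raise ValueError("pooled aggregation needs confusion counts on every report")
    totals = ConfusionRates.from_counts(
        tp=sum(r.rates.TP for r in per_structure),
        fp=sum(r.rates.FP for r in per_structure),
        tn=sum(r.rates.TN for r in per_structure),
        fn=sum(r.rates.FN for r in per_structure),
    )
    pooled = summary_metrics(totals)
    pooled.ROC_AUC, pooled.PR_AUC = roc, pr
    return pooled
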