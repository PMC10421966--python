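"""Classification metrics, globally and stratified per allele.

ROC AUC, PR curves and threshold metrics delegate to scikit-learn's metrics
API; the Matthews correlation under a zero confusion-matrix marginal returns
0 with an explicit flag instead of dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .io import Dataset


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann–Whitney: P(random positive outscores
    random negative), ties counted ½)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


@dataclass(frozen=True)
class MetricReport:
    """Threshold-free and thresholded metrics for one score/label set."""

    auc: float
    f1: float
    mcc: float
    precision: float
    recall: float
    threshold: float
    n_pos: int
    n_neg: int
    tp: int
    fp: int
    fn: int
    tn: int
    mcc_degenerate: bool = False  # a confusion marginal was zero; mcc set to 0
    per_allele: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "auc", "f1", "mcc", "precision", "recall", "threshold",
                "n_pos", "n_neg", "tp", "fp", "fn", "tn", "mcc_degenerate",
            )
        }
        if self.per_allele:
            d["per_allele"] = {
                a: (r.to_dict() if r is not None else None)
                for a, r in self.per_allele.items()
            }
        return d


def threshold_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """F1, MCC, precision, recall and confusion counts at a score threshold.

    MCC is reported as 0 with ``mcc_degenerate=True`` when any confusion
    marginal is zero (the usual 0/0 convention, made explicit).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / np.sqrt(denom)
    return MetricReport(
        auc=roc_auc(scores, labels),
        f1=float(f1),
        mcc=float(mcc),
        precision=float(precision),
        recall=float(recall),
        threshold=float(threshold),
        n_pos=int(pos.sum()),
        n_neg=int((~pos).sum()),
        tp=tp, fp=fp, fn=fn, tn=tn,
        mcc_degenerate=bool(degenerate),
    )


def pr_curve(scores, labels) -> list[tuple[float, float]]:
    """(recall, precision) points at every distinct score threshold,
    recall nondecreasing along the sweep."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    precision, recall, _ = precision_recall_curve(labels, scores)
    pts = sorted(zip(recall.tolist(), precision.tolist()))
    return [(float(r), float(p)) for r, p in pts]


def evaluate_dataset(
    dataset: Dataset, scores, threshold: float = 0.5, per_allele: bool = True
) -> MetricReport:
    """Global metric report over a dataset's EL records, with an optional
    per-allele breakdown (alleles lacking both classes map to None)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(dataset.records):
        raise ValueError("one score per record required")
    is_el = np.array([r.assay_type == "EL" for r in dataset.records])
    labels = np.array([int(r.target) for r in dataset.records])
    report = threshold_metrics(scores[is_el], labels[is_el], threshold)
    if per_allele:
        breakdown = per_allele_report(dataset, scores, threshold)
        report = MetricReport(**{**report.to_dict(), "per_allele": breakdown})
    return report


def per_allele_report(
    dataset: Dataset, scores, threshold: float = 0.5
) -> dict[str, MetricReport | None]:
    """Metrics within each allele stratum (EL records only).

    Alleles whose stratum lacks one of the classes are listed with value
    ``None`` (unevaluable) rather than dropped.
    """
    scores = np.asarray(scores, dtype=float)
    out: dict[str, MetricReport | None] = {}
    alleles = sorted(
        {r.allele_name for r in dataset.records if r.allele_name is not None}
    )
    for allele in alleles:
        sel = np.array(
            [r.allele_name == allele and r.assay_type == "EL" for r in dataset.records]
        )
        labels = np.array([int(r.target) for r in dataset.records])[sel]
        if len(np.unique(labels)) < 2:
            out[allele] = None
            continue
        out[allele] = threshold_metrics(scores[sel], labels, threshold)
    return out


def curve_frames(scores, labels) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROC and PR curve points as tables, for external plotting."""
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fpr, tpr, thr = roc_curve(labels, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    pr = pd.DataFrame(pr_curve(scores, labels), columns=["recall", "precision"])
    return roc, pr


def report_frame(report: MetricReport) -> pd.DataFrame:
    """Flatten a report (plus any per-allele breakdown) into a table."""
    rows = [{"stratum": "all", **{k: v for k, v in report.to_dict().items() if k != "per_allele"}}]
    for allele, sub in report.per_allele.items():
        if sub is None:
            rows.append({"stratum": allele, "auc": np.nan})
        else:
            rows.append(
                {"stratum": allele, **{k: v for k, v in sub.to_dict().items() if k != "per_allele"}}
            )
    return pd.DataFrame(rows)
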