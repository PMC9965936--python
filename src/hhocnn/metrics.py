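"""Binary-classification evaluation: confusion counts, rates, ROC/AUC.

Conventions: the tumor class (label 1) is positive.  Rates with a zero
denominator are reported as 0 and the affected metric name is recorded in
``flags`` (portable JSON instead of NaN).  The ROC curve is the standard
threshold sweep over the unique predicted probabilities and the AUC is its
trapezoidal area.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve, auc as _sk_auc

__all__ = ["MetricsReport", "compute_metrics", "report", "read_report"]


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    specificity: float
    precision: float
    recall: float
    f1: float
    roc_fpr: list[float] = field(default_factory=list)
    roc_tpr: list[float] = field(default_factory=list)
    roc_thresholds: list[float] = field(default_factory=list)
    auc: float = 0.0
    flags: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        lines = [
            f"n = {self.n}  (TP={self.tp}  TN={self.tn}  FP={self.fp}  FN={self.fn})",
            f"accuracy    {self.accuracy:.4f}",
            f"specificity {self.specificity:.4f}",
            f"precision   {self.precision:.4f}",
            f"recall      {self.recall:.4f}",
            f"F1          {self.f1:.4f}",
            f"AUC         {self.auc:.4f}",
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def _safe_ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(
    y_true, y_pred, probabilities=None
) -> MetricsReport:
    """Confusion counts and the five standard rates, plus ROC/AUC.

    ``accuracy=(TP+TN)/N``, ``specificity=TN/(TN+FP)``,
    ``precision=TP/(TP+FP)``, ``recall=TP/(TP+FN)`` and F1 as the harmonic
    mean of precision and recall.  *probabilities* (optional) drives the
    ROC sweep; AUC is flagged and reported 0 when only one class is
    present.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    flags: list[str] = []
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    accuracy = _safe_ratio(tp + tn, len(y_true), "accuracy", flags)
    specificity = _safe_ratio(tn, tn + fp, "specificity", flags)
    precision = _safe_ratio(tp, tp + fp, "precision", flags)
    recall = _safe_ratio(tp, tp + fn, "recall", flags)
    f1 = _safe_ratio(2.0 * precision * recall, precision + recall, "f1", flags)

    roc_fpr: list[float] = []
    roc_tpr: list[float] = []
    roc_thr: list[float] = []
    auc_val = 0.0
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=np.float64)
        if probabilities.shape != y_true.shape:
            raise ValueError("probability sequence differs in length")
        if len(np.unique(y_true)) == 2:
            fpr, tpr, thr = _sk_roc_curve(y_true, probabilities)
            auc_val = float(_sk_auc(fpr, tpr))
            roc_fpr, roc_tpr = fpr.tolist(), tpr.tolist()
            roc_thr = np.clip(thr, -1e12, 1e12).tolist()
        else:
            flags.append("auc")
    return MetricsReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=accuracy,
        specificity=specificity,
        precision=precision,
        recall=recall,
        f1=f1,
        roc_fpr=roc_fpr,
        roc_tpr=roc_tpr,
        roc_thresholds=roc_thr,
        auc=auc_val,
        flags=flags,
    )


def report(metrics: MetricsReport, out_dir: str | os.PathLike, extra: dict | None = None) -> dict:
    """Write metrics JSON, a ROC CSV and a plain-text summary; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = metrics.to_dict()
    if extra:
        payload = {"classification": payload, **extra}
    json_path = out_dir / "metrics.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    roc_path = out_dir / "roc.csv"
    pd.DataFrame(
        {
            "threshold": metrics.roc_thresholds,
            "fpr": metrics.roc_fpr,
            "tpr": metrics.roc_tpr,
        }
    ).to_csv(roc_path, index=False)
    txt_path = out_dir / "summary.txt"
    txt_path.write_text(metrics.summary() + "\n")
    return {"metrics": json_path, "roc": roc_path, "summary": txt_path}


def read_report(json_path: str | os.PathLike) -> dict:
    with open(json_path) as fh:
        return json.load(fh)
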