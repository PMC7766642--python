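"""Classification accuracy scoring from confusion matrices.

Matrix orientation is fixed as prediction-in-rows, reference-in-columns:
user accuracy (UA) is therefore a row property (of the map the user holds)
and producer accuracy (PA) a column property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = ["AccuracyReport", "accuracy_metrics", "split_samples", "confusion_from_labels"]


@dataclass(frozen=True)
class AccuracyReport:
    """Overall accuracy, Kappa, and per-class user/producer accuracy."""

    overall_accuracy: float
    kappa: float
    user_accuracy: pd.Series
    producer_accuracy: pd.Series

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"UA": self.user_accuracy, "PA": self.producer_accuracy}
        )
        frame.loc["overall"] = [self.overall_accuracy, np.nan]
        frame.loc["kappa"] = [self.kappa, np.nan]
        return frame


def accuracy_metrics(matrix) -> AccuracyReport:
    """OA, Kappa, UA and PA from a confusion-count matrix.

    OA = trace/total; UA_c = diagonal/row total; PA_c = diagonal/column
    total; Kappa = (p_o − p_e)/(1 − p_e) with chance agreement
    p_e = Σ (row marginal × column marginal)/total².  A class with a zero
    marginal gets NaN for the affected accuracy; other classes are
    unaffected.
    """
    if isinstance(matrix, pd.DataFrame):
        counts = matrix.to_numpy(dtype=float)
        labels = list(matrix.index)
    else:
        counts = np.asarray(matrix, dtype=float)
        labels = list(range(counts.shape[0]))
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be positive")
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    oa = diag.sum() / total
    p_e = float((row * col).sum()) / total**2
    kappa = 1.0 if p_e == 1.0 and oa == 1.0 else (oa - p_e) / (1.0 - p_e)
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(row > 0, diag / np.where(row > 0, row, 1), np.nan)
        pa = np.where(col > 0, diag / np.where(col > 0, col, 1), np.nan)
    idx = pd.Index(labels, name="class")
    return AccuracyReport(
        overall_accuracy=float(oa),
        kappa=float(kappa),
        user_accuracy=pd.Series(ua, index=idx, name="UA"),
        producer_accuracy=pd.Series(pa, index=idx, name="PA"),
    )


def confusion_from_labels(reference, predicted, codes=None) -> pd.DataFrame:
    """Cross-tabulate reference/predicted label pairs (prediction in rows)."""
    ref = np.asarray(reference)
    pred = np.asarray(predicted)
    if ref.shape != pred.shape:
        raise ValueError("label arrays must have equal length")
    if codes is None:
        codes = sorted(set(ref.tolist()) | set(pred.tolist()))
    frame = pd.crosstab(
        pd.Series(pred, name="predicted"), pd.Series(ref, name="reference")
    ).reindex(index=codes, columns=codes, fill_value=0)
    return frame


def split_samples(labels, train_fraction: float = 0.7, seed: int = 0):
    """Stratified, reproducible train/test split of labeled sample points.

    Returns ``(train_idx, test_idx)`` index arrays forming an exclusive,
    exhaustive partition with per-class proportions preserved.  A class
    with fewer than 2 points cannot be stratified and raises.
    """
    labels = np.asarray(labels)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    _, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 points for a stratified split")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=int(seed)
    )
    return np.sort(train_idx), np.sort(test_idx)
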