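"""The max-coverage bridge and shared metric protocols.

A nucleotide-level model emits one value per base; a sequence-level model
emits one scalar per window.  Taking the *maximum* predicted coverage of a
window as its score puts both on one metric surface: PR-AUC/ROC-AUC against
binding labels, and Pearson correlation of per-window maxima (or of all
nucleotides) against the true track.  Binding strength of a peak is defined
as the log-scaled number of reads overlapping it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .windows import IntervalSet

__all__ = [
    "EvalReport",
    "window_max",
    "classification_metrics",
    "fit_metrics",
    "binding_strength_correlation",
    "evaluate_model",
]


@dataclass
class EvalReport:
    prauc: float
    rocauc: float
    pearson_max: float
    pearson_nt: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {k: (float(v) if not isinstance(v, int) else v)
                for k, v in self.__dict__.items()}


def window_max(per_base: np.ndarray) -> np.ndarray:
    """Window score(s): the maximum per-base value.  Accepts (L,) or (N, L)."""
    arr = np.asarray(per_base)
    if arr.size == 0:
        raise ValueError("empty prediction vector")
    return arr.max(axis=-1)


def classification_metrics(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(PR-AUC, ROC-AUC) for binary labels.

    PR-AUC uses step interpolation (sum of precision times recall increments
    over the threshold-grouped curve); ROC-AUC is the normalized Mann-Whitney
    U statistic.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("classification metrics need both classes present")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # curve is returned from high threshold to low; integrate step-wise
    prauc = float(-np.sum(np.diff(recall) * precision[:-1]))
    rocauc = float(roc_auc_score(labels, scores))
    return prauc, rocauc


def fit_metrics(
    pred: np.ndarray,
    true: np.ndarray,
    scope: str = "positives_max",
    with_spearman: bool = False,
):
    """Pearson correlation of predictions against truth on positive windows.

    scope="positives_max": correlate per-window maxima (pred and true are
    (N, L) arrays over positive windows).  scope="all_nucleotides": correlate
    the concatenated per-base values.
    """
    pred, true = np.asarray(pred), np.asarray(true)
    if scope == "positives_max":
        a, b = window_max(pred), window_max(true)
    elif scope == "all_nucleotides":
        a, b = pred.ravel(), true.ravel()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if a.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    if with_spearman:
        return r, float(stats.spearmanr(a, b).statistic)
    return r


def binding_strength_correlation(
    reads: IntervalSet, peaks: IntervalSet, peak_max_coverage: np.ndarray
) -> float:
    """Pearson between log-scaled per-peak read counts and peak coverage maxima.

    A read counts toward a peak if it overlaps it by at least one base;
    strength = log10(1 + count).
    """
    if len(peaks) == 0:
        raise ValueError("no peaks")
    # duplicate reads are distinct events: count from records, not the tree
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r[0] for r in reads.records}:
        recs = [(s, e) for c, s, e, *_ in reads.records if c == chrom]
        starts = np.sort(np.array([s for s, _ in recs]))
        ends = np.sort(np.array([e for _, e in recs]))
        by_chrom[chrom] = (starts, ends)
    counts = []
    for chrom, start, end, *_ in peaks:
        if chrom not in by_chrom:
            counts.append(0)
            continue
        starts, ends = by_chrom[chrom]
        # overlap iff read.start < peak.end and read.end > peak.start
        n = np.searchsorted(starts, end, side="left") - np.searchsorted(
            ends, start, side="right"
        )
        counts.append(int(n))
    counts = np.asarray(counts, dtype=float)
    if counts.max() == 0:
        raise ValueError("no reads overlap any peak; strength undefined")
    strength = np.log10(1.0 + counts)
    return float(stats.pearsonr(strength, np.asarray(peak_max_coverage)).statistic)


def evaluate_model(
    model,
    x_pos: np.ndarray,
    y_pos: np.ndarray,
    x_neg: np.ndarray,
    y_neg: np.ndarray,
) -> EvalReport:
    """Bridge evaluation of a nucleotide-level model on encoded windows."""
    pred_pos = model.predict(x_pos)
    pred_neg = model.predict(x_neg)
    scores = np.concatenate([window_max(pred_pos), window_max(pred_neg)])
    labels = np.concatenate([np.ones(len(x_pos)), np.zeros(len(x_neg))])
    prauc, rocauc = classification_metrics(scores, labels)
    pearson_max = fit_metrics(pred_pos, y_pos, scope="positives_max")
    pearson_nt = fit_metrics(pred_pos, y_pos, scope="all_nucleotides")
    return EvalReport(prauc, rocauc, pearson_max, pearson_nt, len(x_pos), len(x_neg))
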