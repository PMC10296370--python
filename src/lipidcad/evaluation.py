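"""Model evaluation: ROC curves, tie-aware AUC, the DeLong paired-AUC test,
per-stratum validation AUC tables, and per-individual model-overlap counts.

AUC is the Mann-Whitney concordance (#concordant + half #tied) / (n+ * n-),
computed via midranks. The DeLong test estimates the variance of the paired
AUC difference from the empirical covariance of per-sample placement values
(midrank form for ties) and refers z = dAUC / SE to the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "RocResult",
    "DelongResult",
    "OverlapTable",
    "roc_auc",
    "delong_test",
    "evaluate_subcohorts",
    "compare_model_targets",
]


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class DelongResult:
    auc1: float
    auc2: float
    z: float
    p: float


@dataclass
class OverlapTable:
    """Cross-tabulated correctness of two models among true-positive samples."""

    both: int
    lrs_only: int
    frs_only: int
    neither: int

    @property
    def n_positive(self) -> int:
        return self.both + self.lrs_only + self.frs_only + self.neither

    def percentages(self) -> dict[str, str]:
        n = self.n_positive
        out = {}
        for name in ("both", "lrs_only", "frs_only", "neither"):
            pct = 100.0 * getattr(self, name) / n if n else 0.0
            text = f"{pct:.0f}" if pct >= 99.5 else f"{pct:.2g}"
            out[name] = f"{text}%"
        return out


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        known = np.isin(arr, ["sCAD_minus", "sCAD_plus"])
        if not known.all():
            raise DataError("labels must be sCAD_minus/sCAD_plus (or 0/1)")
        arr = (arr == "sCAD_plus").astype(int)
    arr = arr.astype(int)
    if set(np.unique(arr)) - {0, 1}:
        raise DataError("binary labels required")
    return arr


def _auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    """Tie-aware AUC via midranks."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes required to compute AUC")
    ranks = stats.rankdata(scores)  # midranks
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc(scores, labels) -> RocResult:
    """ROC curve over all unique score thresholds plus the tie-aware AUC."""
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise DataError("scores and labels differ in length")
    auc = _auc_mann_whitney(s, y)

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    block_end = np.flatnonzero(np.diff(s_sorted, append=-np.inf) != 0)
    thresholds = np.concatenate([[np.inf], s_sorted[block_end]])
    sens = np.concatenate([[0.0], tps[block_end] / n_pos])
    spec = np.concatenate([[1.0], 1.0 - fps[block_end] / n_neg])
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def _placement_values(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (midrank form).

    V10[i] for positive i: fraction of negatives scored below (+ half ties);
    V01[j] for negative j: fraction of positives scored above (+ half ties).
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """DeLong's paired test for the difference of two correlated AUCs
    measured on the same samples."""
    y = _binary_labels(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise DataError("paired scores and labels must have equal length")
    v10a, v01a = _placement_values(a, y)
    v10b, v01b = _placement_values(b, y)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())

    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            return DelongResult(auc1=auc_a, auc2=auc_b, z=0.0, p=1.0)
        raise DataError("zero variance estimate with unequal AUCs")
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(auc1=auc_a, auc2=auc_b, z=float(z), p=float(p))


def evaluate_subcohorts(
    scores: dict[str, pd.Series],
    labels: pd.Series,
    strata: dict[str, list],
) -> pd.DataFrame:
    """AUC per (model, stratum).

    ``scores`` maps model name to a per-sample risk Series computed once on
    the full validation set; each stratum is a list of sample ids. Strata
    containing a single class yield NaN with a flag.
    """
    rows = []
    for model_name, s in scores.items():
        for stratum_name, ids in strata.items():
            ids = [i for i in ids if i in s.index]
            y = _binary_labels(labels.reindex(ids))
            if len(np.unique(y)) < 2:
                rows.append(
                    {"model": model_name, "stratum": stratum_name, "n": len(ids),
                     "auc": np.nan, "flag": "single_class"}
                )
                continue
            rows.append(
                {"model": model_name, "stratum": stratum_name, "n": len(ids),
                 "auc": _auc_mann_whitney(s.reindex(ids).to_numpy(), y), "flag": ""}
            )
    return pd.DataFrame(rows)


def compare_model_targets(calls_lrs, calls_frs, labels) -> OverlapTable:
    """Among true sCAD+ samples, cross-tabulate which model called them
    correctly: both, LRS only, FRS only, or neither."""
    y = _binary_labels(labels)
    a = np.asarray(calls_lrs, dtype=bool)
    b = np.asarray(calls_frs, dtype=bool)
    if not (len(a) == len(b) == len(y)):
        raise DataError("call vectors and labels must have equal length")
    pos = y == 1
    lrs_correct = a[pos]
    frs_correct = b[pos]
    return OverlapTable(
        both=int((lrs_correct & frs_correct).sum()),
        lrs_only=int((lrs_correct & ~frs_correct).sum()),
        frs_only=int((~lrs_correct & frs_correct).sum()),
        neither=int((~lrs_correct & ~frs_correct).sum()),
    )
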