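"""Classification metrics and clinical-utility curves.

ACC/SEN/SPEC from confusion counts (score >= threshold counts as a positive
prediction), ROC/AUC (trapezoidal, equal to tie-corrected pairwise
concordance), decision-curve analysis net benefit, the Mann-Whitney U test,
and cohort positive-fraction summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu as _scipy_mwu
from sklearn.metrics import auc as _trapezoid_auc, roc_curve as _sk_roc_curve

from .preprocess import CohortSplit


# ----------------------------------------------------------- confusion/ROC
@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion(scores: np.ndarray, labels: np.ndarray,
              threshold: float = 0.5) -> ConfusionCounts:
    """Counts with the >= tie rule: score == threshold predicts positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length, non-empty")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()), fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()), fn=int((~pred & pos).sum()))


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """ACC = (TP+TN)/N, SEN = TP/(TP+FN), SPEC = TN/(TN+FP); an undefined
    ratio (empty class) is reported as NaN with a warning."""
    if counts.n == 0:
        raise ValueError("no samples evaluated")
    acc = (counts.tp + counts.tn) / counts.n
    if counts.tp + counts.fn == 0:
        warnings.warn("no positive labels: sensitivity undefined", stacklevel=2)
        sen = np.nan
    else:
        sen = counts.tp / (counts.tp + counts.fn)
    if counts.tn + counts.fp == 0:
        warnings.warn("no negative labels: specificity undefined", stacklevel=2)
        spec = np.nan
    else:
        spec = counts.tn / (counts.tn + counts.fp)
    return {"acc": acc, "sen": sen, "spec": spec}


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr,
                    auc=float(_trapezoid_auc(fpr, tpr)))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal ROC area (= concordance probability with ties at 1/2)."""
    return roc_curve(scores, labels).auc


# ------------------------------------------------------------------- DCA
@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray    # threshold probabilities p_t in (0, 1)
    model: np.ndarray         # net benefit of the classifier at each p_t
    treat_all: np.ndarray
    treat_none: np.ndarray    # identically zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "model": self.model,
                             "treat_all": self.treat_all,
                             "treat_none": self.treat_none})


def decision_curve(scores: np.ndarray, labels: np.ndarray,
                   thresholds: np.ndarray | None = None) -> NetBenefitCurve:
    """Decision-curve analysis: net benefit TP/N - FP/N * p_t/(1-p_t) over a
    grid of treatment threshold probabilities (default 0.01..0.99)."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.0, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("threshold probabilities must lie strictly in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    odds = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, (pt, od) in enumerate(zip(thresholds, odds)):
        c = confusion(scores, labels, threshold=pt)
        nb_model[i] = c.tp / n - c.fp / n * od
    prevalence = labels.mean()
    nb_all = prevalence - (1.0 - prevalence) * odds
    return NetBenefitCurve(thresholds=thresholds, model=nb_model,
                           treat_all=nb_all,
                           treat_none=np.zeros_like(thresholds))


# --------------------------------------------------------------- rank tests
def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration when both samples are
    small (min n <= 8) and tie-free, tie-corrected normal approximation
    otherwise.  Returns (U of the first sample, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = _scipy_mwu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ----------------------------------------------------------- cohort summary
def cohort_proportions(split: CohortSplit | pd.DataFrame) -> dict[str, float]:
    """Positive-patient percentage per cohort, rounded to one decimal.

    Accepts a CohortSplit of labelled samples or a patient-level DataFrame
    with 'cohort' (train/test), 'patient_id', and 'label' columns.
    """
    if isinstance(split, pd.DataFrame):
        frame = split[["cohort", "patient_id", "label"]]
    else:
        rows = [{"cohort": c, "patient_id": s.patient_id, "label": s.label}
                for c, samples in (("train", split.train), ("test", split.test))
                for s in samples]
        frame = pd.DataFrame(rows)
    out = {}
    for cohort, grp in frame.groupby("cohort"):
        per_patient = grp.groupby("patient_id")["label"].max()
        out[cohort] = round(100.0 * per_patient.mean(), 1)
    return out


def patient_level_scores(scores: np.ndarray, labels: np.ndarray,
                         patient_ids: np.ndarray) -> pd.DataFrame:
    """Aggregate per-image scores to per-patient mean score (labels are
    constant within a patient)."""
    df = pd.DataFrame({"patient_id": patient_ids, "score": scores, "label": labels})
    return df.groupby("patient_id").agg(score=("score", "mean"),
                                        label=("label", "max")).reset_index()
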