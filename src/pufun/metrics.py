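"""CAFA-style evaluation: protein-centric Fmax, Smin and AUPR, plus
class-centric average ROC AUC.

All protein-centric measures scan a fixed threshold grid t in [0, 1] with
step 0.01; a class counts as predicted for a protein when its score is
greater than or equal to t.  Per threshold,

    pr_i(t) = |P_i(t) & T_i| / |P_i(t)|        (proteins with a prediction)
    rc_i(t) = |P_i(t) & T_i| / |T_i|           (proteins with true terms)
    AvgPr(t) = mean pr_i over the m(t) proteins with >= 1 prediction
    AvgRc(t) = mean rc_i over the n proteins with >= 1 true annotation

Fmax is the maximum harmonic mean of (AvgPr, AvgRc) over thresholds where
AvgPr is defined.  Smin weights misclassified terms by information content:
ru(t) averages the IC of missed true terms, mi(t) the IC of wrongly
predicted terms, and Smin = min_t sqrt(ru^2 + mi^2).  AUPR integrates the
(AvgRc, AvgPr) curve by the trapezoid rule over its defined points.  The
class-centric AUC averages a rank-based (Mann-Whitney, ties at 0.5) ROC AUC
over classes that have both positives and negatives.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import LabelMatrix
from .nn import ScoreMatrix
from .ontology import ClassIndex, ICVector

THRESHOLDS = np.round(np.arange(0, 101) * 0.01, 2)


@dataclass
class EvaluationInput:
    """Matched predictions and truth plus the IC weights Smin needs."""

    predictions: ScoreMatrix
    truth: LabelMatrix
    ic: ICVector | None = None
    thresholds: np.ndarray = field(default_factory=lambda: THRESHOLDS.copy())

    def __post_init__(self) -> None:
        if self.predictions.proteins != self.truth.proteins:
            raise ValueError("prediction and truth protein orders differ")
        if self.predictions.index.terms != self.truth.index.terms:
            raise ValueError("prediction and truth class indices differ")
        if self.predictions.kind != "probability":
            raise ValueError("evaluation expects probability scores")
        if self.ic is not None and len(self.ic.values) != len(self.truth.index):
            raise ValueError("IC vector does not cover the class index")
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be sorted ascending")


@dataclass
class CurvePoint:
    threshold: float
    avg_pr: float | None  # None when m(t) = 0
    avg_rc: float
    m: int


@dataclass
class MetricsReport:
    fmax: float
    fmax_threshold: float | None
    smin: float | None
    smin_threshold: float | None
    aupr: float
    auc: float | None
    n_auc_classes: int
    curve: list[CurvePoint]

    def to_dict(self) -> dict:
        return {
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "smin": self.smin,
            "smin_threshold": self.smin_threshold,
            "aupr": self.aupr,
            "auc": self.auc,
            "n_auc_classes": self.n_auc_classes,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def precision_recall_curve_points(ev: EvaluationInput) -> list[CurvePoint]:
    """Averaged precision/recall at each grid threshold.

    Proteins with an empty truth set are excluded from the recall average
    (their recall is undefined); thresholds where no protein has a
    prediction yield an undefined AvgPr (``None``).  A zero score is never a
    prediction (prediction files only list scored terms), so the t=0 grid
    point covers exactly the positively-scored cells.
    """
    scores = ev.predictions.values
    truth = ev.truth.values.astype(bool)
    has_truth = truth.any(axis=1)
    n_truth = int(has_truth.sum())
    truth_sizes = truth.sum(axis=1)
    points: list[CurvePoint] = []
    for t in ev.thresholds:
        pred = (scores >= t) & (scores > 0)
        tp = (pred & truth).sum(axis=1)
        pred_sizes = pred.sum(axis=1)
        has_pred = pred_sizes > 0
        m = int(has_pred.sum())
        if m > 0:
            avg_pr = float((tp[has_pred] / pred_sizes[has_pred]).mean())
        else:
            avg_pr = None
        if n_truth > 0:
            avg_rc = float((tp[has_truth] / truth_sizes[has_truth]).mean())
        else:
            avg_rc = 0.0
        points.append(CurvePoint(float(t), avg_pr, avg_rc, m))
    return points


def fmax(ev: EvaluationInput) -> tuple[float, float | None]:
    """Maximum harmonic mean of averaged precision and recall.

    Ties break toward the smallest threshold.  When no threshold has a
    defined precision the result is 0 with a warning.
    """
    best, best_t = 0.0, None
    defined = False
    for pt in precision_recall_curve_points(ev):
        if pt.avg_pr is None:
            continue
        defined = True
        denom = pt.avg_pr + pt.avg_rc
        f = 0.0 if denom == 0 else 2 * pt.avg_pr * pt.avg_rc / denom
        if f > best or best_t is None:
            best, best_t = f, pt.threshold
    if not defined:
        warnings.warn("no threshold produced a prediction; Fmax = 0", stacklevel=2)
        return 0.0, None
    return best, best_t


def smin(ev: EvaluationInput) -> tuple[float, float | None]:
    """Minimum semantic distance sqrt(ru(t)^2 + mi(t)^2) over thresholds.

    ru(t): mean (over all evaluated proteins) total IC of true terms missed
    at t; mi(t): mean total IC of predicted-but-false terms.
    """
    if ev.ic is None:
        raise ValueError("Smin requires an ICVector")
    ic = ev.ic.values
    scores = ev.predictions.values
    truth = ev.truth.values.astype(bool)
    n = scores.shape[0]
    best, best_t = np.inf, None
    for t in ev.thresholds:
        pred = (scores >= t) & (scores > 0)
        missed = truth & ~pred
        wrong = pred & ~truth
        ru = float((missed @ ic).sum()) / n
        mi = float((wrong @ ic).sum()) / n
        s = float(np.hypot(ru, mi))
        if s < best - 1e-15:
            best, best_t = s, float(t)
    return best, best_t


def aupr(ev: EvaluationInput) -> float:
    """Trapezoidal area under the (AvgRc, AvgPr) curve's defined points.

    The curve is anchored at recall 0 with the precision of the most
    stringent defined threshold (the usual convention; without it a
    perfect one-point curve would integrate to zero); no extrapolation
    toward recall 1 beyond observed points.  Fewer than two defined points
    after anchoring yield 0 with a warning.
    """
    defined = [p for p in precision_recall_curve_points(ev) if p.avg_pr is not None]
    pts = sorted(((p.avg_rc, p.avg_pr) for p in defined))
    if pts and pts[0][0] > 0:
        stringent = max(defined, key=lambda p: p.threshold)
        pts.insert(0, (0.0, stringent.avg_pr))
    if len(pts) < 2:
        warnings.warn("fewer than 2 defined curve points; AUPR = 0", stacklevel=2)
        return 0.0
    rc = np.array([p[0] for p in pts])
    pr = np.array([p[1] for p in pts])
    return float(np.trapezoid(pr, rc))


def class_centric_auc(ev: EvaluationInput) -> tuple[float, int]:
    """Mean rank-based ROC AUC over classes with both positives and negatives.

    Ties count one half (Mann-Whitney convention).  Raises when no class is
    evaluable.
    """
    scores = ev.predictions.values
    truth = ev.truth.values.astype(bool)
    aucs = []
    for j in range(scores.shape[1]):
        col_truth = truth[:, j]
        n_pos = int(col_truth.sum())
        n_neg = col_truth.size - n_pos
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(scores[:, j])
        u = ranks[col_truth].sum() - n_pos * (n_pos + 1) / 2.0
        aucs.append(u / (n_pos * n_neg))
    if not aucs:
        raise ValueError("no class has both positives and negatives")
    return float(np.mean(aucs)), len(aucs)


def evaluate(ev: EvaluationInput) -> MetricsReport:
    """All four measures in one report."""
    f, ft = fmax(ev)
    if ev.ic is not None:
        s, st = smin(ev)
    else:
        s, st = None, None
    a = aupr(ev)
    try:
        auc, n_classes = class_centric_auc(ev)
    except ValueError:
        auc, n_classes = None, 0
    return MetricsReport(
        fmax=f, fmax_threshold=ft, smin=s, smin_threshold=st,
        aupr=a, auc=auc, n_auc_classes=n_classes,
        curve=precision_recall_curve_points(ev),
    )


# ---------------------------------------------------------------------------
# CAFA-style prediction TSV


def write_cafa_tsv(scores: ScoreMatrix, path, min_score: float = 0.0) -> None:
    """Write (protein, term, score) rows with 3-decimal scores."""
    with open(path, "w") as fh:
        for i, prot in enumerate(scores.proteins):
            row = scores.values[i]
            for j in np.flatnonzero(row > min_score):
                fh.write(f"{prot}\t{scores.index.terms[j]}\t{row[j]:.3f}\n")


def read_cafa_tsv(
    path, index: ClassIndex, proteins: list[str]
) -> ScoreMatrix:
    """Read a prediction TSV into a score matrix over a known universe.

    Rows naming unknown proteins or terms are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["protein", "term", "score"],
                     dtype={"protein": str, "term": str, "score": float})
    pos = {p: i for i, p in enumerate(proteins)}
    values = np.zeros((len(proteins), len(index)))
    skipped_prot = skipped_term = 0
    for prot, term, score in df.itertuples(index=False):
        i = pos.get(prot)
        j = index.position.get(term)
        if i is None:
            skipped_prot += 1
            continue
        if j is None:
            skipped_term += 1
            continue
        values[i, j] = score
    if skipped_prot or skipped_term:
        warnings.warn(
            f"skipped {skipped_prot} rows with unknown proteins and "
            f"{skipped_term} with unknown terms",
            stacklevel=2,
        )
    return ScoreMatrix(list(proteins), index, np.clip(values, 0.0, 1.0),
                       kind="probability")
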