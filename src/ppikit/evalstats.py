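"""Evaluation calculus for docking-model ranking and interactor calls.

Models above a score threshold are called positive; crossing that with
the ground truth (acceptable vs incorrect model, or interacting vs
non-interacting pair) gives a confusion matrix and the standard rates

    TPR = TP/(TP+FN),  FPR = FP/(FP+TN),  PPV = TP/(TP+FP),  FDR = 1-PPV.

Sweeping the threshold over all observed scores yields an ROC curve and
its area (AUC).  The success rate (SR) is the fraction of models with
DockQ >= 0.23.  Coevolution signal in a paired alignment is assessed as
the precision of the top-N inter-chain coupling scores, with N the
number of true interface contacts.  Interface secondary structure is
collapsed from 8-state DSSP annotation to helix/sheet/loop, and
continuous covariates (contact counts, Neff) are binned into tertiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "Rates",
    "ROCCurve",
    "DCAAssessment",
    "TertileSplit",
    "confusion_at",
    "rates",
    "roc_curve",
    "tpr_at_fpr",
    "success_rate",
    "dca_interface_ppv",
    "interface_ss_class",
    "tertile_split",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion matrix must contain at least one item")


class Rates(NamedTuple):
    """Confusion-matrix rates; undefined rates are NaN."""

    tpr: float
    fpr: float
    ppv: float
    fdr: float


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve: descending thresholds, (0,0) → (1,1)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class DCAAssessment:
    """Precision of the top-N inter-chain coupling signals."""

    n_true_contacts: int
    n_correct_in_top_n: int
    ppv: float


@dataclass(frozen=True)
class TertileSplit:
    """Indices of values in each tertile bin, lowest first."""

    bins: tuple[list[int], list[int], list[int]]
    boundaries: tuple[float, float]
    degenerate: bool


def confusion_at(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> ConfusionCounts:
    """Confusion matrix with score >= threshold called positive."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    called = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(called & y)),
        fp=int(np.sum(called & ~y)),
        tn=int(np.sum(~called & ~y)),
        fn=int(np.sum(~called & y)),
    )


def rates(c: ConfusionCounts) -> Rates:
    """TPR, FPR, PPV and FDR; a zero denominator yields NaN."""
    tpr = c.tp / (c.tp + c.fn) if c.tp + c.fn else math.nan
    fpr = c.fp / (c.fp + c.tn) if c.fp + c.tn else math.nan
    ppv = c.tp / (c.tp + c.fp) if c.tp + c.fp else math.nan
    fdr = 1.0 - ppv if not math.isnan(ppv) else math.nan
    return Rates(tpr, fpr, ppv, fdr)


def roc_curve(
    scores: Sequence[float], labels: Sequence[bool]
) -> ROCCurve:
    """ROC curve over all observed score thresholds, with trapezoidal AUC.

    On tie-free data the AUC equals the probability that a random
    positive outscores a random negative (Mann-Whitney statistic).
    Requires both classes to be present.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC requires both positive and negative labels")
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=float(_sk_auc(fpr, tpr)),
    )


def tpr_at_fpr(roc: ROCCurve, fpr_level: float) -> float:
    """Best achieved TPR at FPR <= fpr_level (conservative step lookup).

    No interpolation between curve points: the reported operating point
    is always achievable by an actual threshold.
    """
    if not 0 <= fpr_level <= 1:
        raise ValueError("fpr_level must be in [0, 1]")
    ok = roc.fpr <= fpr_level
    return float(roc.tpr[ok].max()) if ok.any() else 0.0


def success_rate(dockqs: Sequence[float], threshold: float = 0.23) -> float:
    """Fraction of models with DockQ >= threshold (boundary inclusive)."""
    d = np.asarray(dockqs, dtype=float)
    if d.size == 0:
        raise ValueError("success_rate of an empty score list is undefined")
    return float(np.mean(d >= threshold))


def dca_interface_ppv(
    coupling: np.ndarray, native_contacts: set[tuple[int, int]]
) -> DCAAssessment:
    """Precision of the top-N inter-chain coupling scores.

    ``coupling`` is an |A| x |B| matrix of coupling scores between the
    two chains' alignment columns; ``native_contacts`` the set of true
    interface contacts (i, j).  N = |native_contacts| cells with the
    highest scores are taken (ties broken deterministically in
    row-major order) and the precision is the fraction of them that are
    true contacts.
    """
    if not native_contacts:
        raise ValueError("native contact set must be non-empty")
    m = np.asarray(coupling, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("coupling matrix must be finite")
    n = len(native_contacts)
    flat = m.ravel()
    # stable sort on -score keeps row-major order among ties
    order = np.argsort(-flat, kind="stable")[:n]
    top = {tuple(divmod(int(ix), m.shape[1])) for ix in order}
    correct = len(top & set(native_contacts))
    return DCAAssessment(
        n_true_contacts=n, n_correct_in_top_n=correct, ppv=correct / n
    )


_SS_CLASS = {
    "H": "helix",  # alpha helix
    "G": "helix",  # 3-10 helix
    "I": "helix",  # pi helix
    "E": "sheet",  # beta strand
    "B": "sheet",  # isolated beta bridge
    "T": "loop",
    "S": "loop",
    "C": "loop",
    "P": "loop",  # polyproline II (DSSP 4)
    "-": "loop",
    " ": "loop",
}
_SS_PRECEDENCE = ("helix", "sheet", "loop")


def interface_ss_class(dssp_states: str) -> str:
    """Majority secondary-structure class over interface residues.

    Collapses 8-state DSSP annotation to helix (H/G/I), sheet (E/B) or
    loop (everything else).  Ties go to the more structured class
    (helix > sheet > loop).  Unknown state characters raise.
    """
    if not dssp_states:
        raise ValueError("annotation string must be non-empty")
    counts = {"helix": 0, "sheet": 0, "loop": 0}
    for ch in dssp_states:
        cls = _SS_CLASS.get(ch.upper() if ch != " " else ch)
        if cls is None:
            raise ValueError(f"unknown DSSP state character {ch!r}")
        counts[cls] += 1
    return max(_SS_PRECEDENCE, key=lambda c: (counts[c], -_SS_PRECEDENCE.index(c)))


def tertile_split(values: Sequence[float]) -> TertileSplit:
    """Split values into tertiles at the 1/3 and 2/3 empirical quantiles.

    Values <= q(1/3) form the first bin, values <= q(2/3) the second,
    the rest the third.  On tie-free data bin sizes differ by at most
    one.  A constant list collapses into the first bin and is flagged
    degenerate.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("tertile split requires at least 3 values")
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    low = [i for i, x in enumerate(v) if x <= q1]
    mid = [i for i, x in enumerate(v) if q1 < x <= q2]
    high = [i for i, x in enumerate(v) if x > q2]
    return TertileSplit(
        bins=(low, mid, high), boundaries=(float(q1), float(q2)),
        degenerate=bool(q1 == q2),
    )
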