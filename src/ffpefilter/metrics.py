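"""Confusion matrices, the five performance metrics, threshold sweep and
stratified benchmark reports.

Positive class = true variant, negative class = FFPE artifact, so
specificity is the fraction of artifacts removed and sensitivity the
fraction of true variants retained.  Formulas::

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F1          = 2 / (sensitivity^-1 + precision^-1)

Zero-denominator conventions: an undefined metric is reported as 0.0 with
its name recorded in ``undefined``; F1 is 0.0 whenever either component
is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .variants import Label

LOW_MAF_LOWER = 0.01
LOW_MAF_UPPER = 0.05
#: transition/transversion strand-complement groupings used in reports
SUBSTITUTION_GROUPS = {
    "C:G>T:A": ("C>T", "G>A"),  # cytosine-deamination transition
    "G:C>T:A": ("G>T", "C>A"),  # guanine-oxidation transversion
}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    specificity: float
    sensitivity: float
    precision: float
    f1: float
    undefined: frozenset = field(default_factory=frozenset)

    def rounded(self, digits: int = 3) -> "MetricSet":
        return MetricSet(
            *(round_half_up(v, digits) for v in
              (self.accuracy, self.specificity, self.sensitivity, self.precision, self.f1)),
            undefined=self.undefined,
        )


def round_half_up(x: float, digits: int = 3) -> float:
    """Decimal round-half-up, the convention used for report comparison."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_binary(labels: Sequence) -> np.ndarray:
    out = np.empty(len(labels), dtype=int)
    for i, v in enumerate(labels):
        if isinstance(v, Label):
            out[i] = 1 if v is Label.TRUE_VARIANT else 0
        elif isinstance(v, str):
            out[i] = 1 if v in (Label.TRUE_VARIANT.value, "T") else 0
        else:
            out[i] = int(v)
    if not set(np.unique(out)) <= {0, 1}:
        raise ValueError("labels must be two-class")
    return out


def build_confusion(truth: Sequence, predicted: Sequence) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with true variant as the positive class."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted")
    t = _as_binary(truth)
    p = _as_binary(predicted)
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """The five performance metrics with explicit zero-denominator flags."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    undef = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undef.add(name)
            return 0.0
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    specificity = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    sensitivity = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    if sensitivity > 0.0 and precision > 0.0:
        f1 = 2.0 / (1.0 / sensitivity + 1.0 / precision)
    else:
        f1 = 0.0
        if "sensitivity" in undef or "precision" in undef:
            undef.add("f1")
    return MetricSet(accuracy, specificity, sensitivity, precision, f1, frozenset(undef))


def f1_score(truth: Sequence, predicted: Sequence) -> float:
    return compute_metrics(build_confusion(truth, predicted)).f1


def sweep_threshold(
    probabilities: Sequence[float], truth: Sequence
) -> Tuple[float, float]:
    """Exhaustive F1 maximisation over all decision cut points.

    Candidates are 0, the midpoints between consecutive distinct
    probabilities, and 1; predictions use the inclusive rule
    (probability >= threshold -> true variant).  Ties are broken toward
    the lowest threshold, which maximises sensitivity among optima.
    """
    p = np.asarray(probabilities, dtype=float)
    t = _as_binary(truth)
    if len(p) != len(t):
        raise ValueError("length mismatch between probabilities and truth")
    if len(np.unique(t)) < 2:
        raise ValueError("threshold sweep needs both classes in the truth labels")
    distinct = np.unique(p)
    candidates = np.concatenate(([0.0], (distinct[:-1] + distinct[1:]) / 2.0, [1.0]))
    best_t, best_f1 = 0.0, -1.0
    for thr in candidates:
        pred = (p >= thr).astype(int)
        f1 = compute_metrics(build_confusion(t, pred)).f1
        if f1 > best_f1 + 1e-15:
            best_t, best_f1 = float(thr), f1
    return best_t, best_f1


def stratified_report(
    truth: Sequence,
    predicted: Sequence,
    maf: Optional[Sequence[float]] = None,
    substitution: Optional[Sequence[str]] = None,
    cancer_type: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Benchmark-style table: overall, per cancer type, substitution-group
    and low-MAF strata.

    The low-MAF stratum is the open interval 1% < MAF < 5%.  Substitution
    groups pair each SNV type with its reverse-strand complement
    (C:G>T:A = {C>T, G>A}; G:C>T:A = {G>T, C>A}).  Empty strata are kept
    as rows flagged ``empty`` with NaN metrics.
    """
    n = len(truth)
    t = _as_binary(truth)
    p = _as_binary(predicted)
    strata: List[Tuple[str, np.ndarray]] = [("All", np.ones(n, dtype=bool))]
    if cancer_type is not None:
        ct = np.asarray(cancer_type, dtype=object)
        for name in sorted({c for c in ct if c is not None}):
            strata.append((str(name), ct == name))
    if substitution is not None:
        sub = np.asarray(substitution, dtype=object)
        for gname, members in SUBSTITUTION_GROUPS.items():
            strata.append((gname, np.isin(sub, members)))
    if maf is not None:
        m = np.asarray(maf, dtype=float)
        strata.append(
            (f"Low MAF ({LOW_MAF_LOWER:.0%}-{LOW_MAF_UPPER:.0%})",
             (m > LOW_MAF_LOWER) & (m < LOW_MAF_UPPER))
        )
    rows = []
    for name, mask in strata:
        if not mask.any():
            rows.append({"stratum": name, "tp": 0, "tn": 0, "fp": 0, "fn": 0,
                         "specificity": np.nan, "sensitivity": np.nan, "precision": np.nan,
                         "f1": np.nan, "accuracy": np.nan, "empty": True})
            continue
        cm = build_confusion(t[mask], p[mask])
        ms = compute_metrics(cm)
        rows.append({
            "stratum": name, "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
            "specificity": ms.specificity, "sensitivity": ms.sensitivity,
            "precision": ms.precision, "f1": ms.f1, "accuracy": ms.accuracy,
            "empty": False,
        })
    return pd.DataFrame(rows, columns=["stratum", "tp", "tn", "fp", "fn", "specificity",
                                       "sensitivity", "precision", "f1", "accuracy", "empty"])
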