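"""Diagnostic accuracy of FNAC under two reference standards.

A node's *cytology call* is its final FNAC category — the initial result
unless a repeat FNAC revised it; suspicious and malignant categories are
positive calls, benign and ALUS negative (the indeterminate category is
managed conservatively, i.e. grouped with negatives).

Two reference standards are supported:

* ``COMPOSITE`` — histology when the node was excised, clinical
  follow-up otherwise; every node is evaluable.  This mitigates
  partial-verification bias: only a selected quarter of nodes reach the
  histological gold standard.
* ``HISTOLOGY_ONLY`` — the traditional gold standard; only biopsied
  nodes are evaluable, which is exactly the selected subset and hence
  overstates the false-negative fraction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort import PatientPathway, TruthLabel

__all__ = [
    "Reference",
    "Outcome",
    "ConfusionMatrix",
    "AccuracyMetrics",
    "classify_case",
    "confusion_matrix",
    "metrics",
]


class Reference(str, enum.Enum):
    COMPOSITE = "composite"
    HISTOLOGY_ONLY = "histology_only"


class Outcome(str, enum.Enum):
    TP = "tp"
    FP = "fp"
    TN = "tn"
    FN = "fn"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    reference: Reference

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def cells(self) -> tuple:
        return (self.tp, self.fp, self.tn, self.fn)


@dataclass(frozen=True)
class AccuracyMetrics:
    """Derived metrics as fractions; a metric whose denominator is zero
    is reported as None (undefined), never as 0."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    fn_rate: Optional[float]


def classify_case(pathway: PatientPathway, reference: Reference) -> Outcome:
    """Cross-tabulate one node's final cytology call against the truth.

    Under HISTOLOGY_ONLY the node must have been biopsied; truth is then
    the histological result.  Under COMPOSITE, unbiopsied nodes are
    adjudicated by clinical follow-up.
    """
    biopsied = bool(pathway.n_sb_patient)
    if reference is Reference.HISTOLOGY_ONLY and not biopsied:
        raise ValueError(
            f"pathway {pathway.id}: histology-only reference requires a biopsy"
        )
    positive_call = pathway.last_fnac_state.is_cytology_positive
    truth_malignant = pathway.truth_label is TruthLabel.MALIGNANT
    if positive_call:
        return Outcome.TP if truth_malignant else Outcome.FP
    return Outcome.FN if truth_malignant else Outcome.TN


def confusion_matrix(
    cohort: Sequence[PatientPathway], reference: Reference
) -> ConfusionMatrix:
    """Aggregate classify_case over the evaluable part of the cohort."""
    evaluable = (
        cohort
        if reference is Reference.COMPOSITE
        else [p for p in cohort if p.n_sb_patient]
    )
    counts = {o: 0 for o in Outcome}
    for p in evaluable:
        counts[classify_case(p, reference)] += 1
    return ConfusionMatrix(
        tp=counts[Outcome.TP],
        fp=counts[Outcome.FP],
        tn=counts[Outcome.TN],
        fn=counts[Outcome.FN],
        reference=reference,
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def metrics(cm: ConfusionMatrix) -> AccuracyMetrics:
    """Sensitivity, specificity, PPV, NPV and the false-negative rate.

    fn_rate = fn / (tp + fn) = 1 − sensitivity: the fraction of truly
    malignant nodes that cytology called negative.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    return AccuracyMetrics(
        sensitivity=sens,
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        fn_rate=None if sens is None else 1.0 - sens,
    )
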