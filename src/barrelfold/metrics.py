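"""Prediction accuracy metrics at residue and strand level.

Following the usual convention in membrane-strand prediction papers,
"specificity" here is precision TP/(TP+FP) and "sensitivity" is recall
TP/(TP+FN); the F-score combines exactly these two.  Q2 is the percentage
of correctly labeled items in the two-state problem; MCC is the Matthews
correlation, defined as 0 when any confusion-matrix marginal vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqio import LabeledStructure

__all__ = ["MetricsReport", "confusion_metrics", "residue_metrics",
           "strand_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    """Q2 / specificity / sensitivity in percent; F in [0,1]; MCC in [-1,1]."""

    q2: float
    specificity: float
    sensitivity: float
    f_score: float
    mcc: float
    level: str
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict[str, float]:
        return {"q2": self.q2, "specificity": self.specificity,
                "sensitivity": self.sensitivity, "f_score": self.f_score,
                "mcc": self.mcc}


def confusion_metrics(tp: int, fp: int, fn: int, tn: int,
                      level: str = "residues") -> MetricsReport:
    total = tp + fp + fn + tn
    q2 = 100.0 * (tp + tn) / total if total else 0.0
    spec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f = (2 * spec * sens / (spec + sens) / 100.0) if spec + sens else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(q2=q2, specificity=spec, sensitivity=sens,
                         f_score=f, mcc=mcc, level=level,
                         tp=tp, fp=fp, fn=fn, tn=tn)


def residue_metrics(pred: LabeledStructure,
                    truth: LabeledStructure) -> MetricsReport:
    """Per-residue two-state comparison; strand ('S') is the positive class."""
    if pred.sequence.n != truth.sequence.n:
        raise ValueError("prediction and truth have different lengths")
    tp = fp = fn = tn = 0
    for p, t in zip(pred.states, truth.states):
        if p == "S" and t == "S":
            tp += 1
        elif p == "S":
            fp += 1
        elif t == "S":
            fn += 1
        else:
            tn += 1
    return confusion_metrics(tp, fp, fn, tn, level="residues")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def strand_metrics(pred: LabeledStructure, truth: LabeledStructure,
                   overlap_fraction: float = 0.5) -> MetricsReport:
    """Strand-level comparison under an overlap matching rule.

    A predicted strand matches an unmatched truth strand when their overlap
    covers at least ``overlap_fraction`` of the shorter of the two; each
    truth strand is matchable once.  TN is structurally 0 at this level.
    """
    truth_strands = list(truth.strands)
    matched = [False] * len(truth_strands)
    tp = 0
    for ps in pred.strands:
        for idx, ts in enumerate(truth_strands):
            if matched[idx]:
                continue
            shorter = min(ps[1] - ps[0], ts[1] - ts[0]) + 1
            if _overlap(ps, ts) >= overlap_fraction * shorter:
                matched[idx] = True
                tp += 1
                break
    fp = len(pred.strands) - tp
    fn = len(truth_strands) - tp
    return confusion_metrics(tp, fp, fn, 0, level="strands")
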