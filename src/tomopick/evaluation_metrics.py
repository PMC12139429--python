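"""Classification metrics for particle lists against ground truth.

Candidates are processed from highest to lowest LCC and greedily matched to
the nearest unmatched truth position within a Euclidean tolerance: matched
candidates are true positives (each truth entry can be consumed once), the
rest are false positives, and unconsumed truth entries are false negatives.
From the ranked labels the FDR = FP/(TP+FP) and recall = TP/(TP+FN) are
computed per list prefix, giving an ROC-style curve; its summary statistic is
the rectangle under the curve, RUC = max over prefixes of recall * (1 - FDR).
Whole-list precision, recall, and f1 = 2*precision*recall/(precision+recall)
summarize a fixed operating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import CandidateRecord
from .phantom_generator import GroundTruth

__all__ = [
    "LabeledCandidates",
    "label_candidates",
    "classification_curve",
    "summary_metrics",
]


@dataclass
class LabeledCandidates:
    """TP/FP labels for a score-ranked candidate list."""

    labels: list[str]          # "TP" or "FP", in descending-LCC order
    scores: list[float]        # LCC value per candidate, same order
    n_truth: int
    tolerance: float

    @property
    def tp(self) -> int:
        return sum(1 for l in self.labels if l == "TP")

    @property
    def fp(self) -> int:
        return sum(1 for l in self.labels if l == "FP")

    @property
    def fn(self) -> int:
        return self.n_truth - self.tp


def label_candidates(
    candidates: Sequence[CandidateRecord],
    truth: GroundTruth | Sequence[Sequence[float]],
    tolerance: float,
    label: str = "particle",
) -> LabeledCandidates:
    """Greedy one-to-one matching of candidates to truth positions.

    Candidates are visited in descending LCC; each is a TP if an unmatched
    truth entry of the target class lies within ``tolerance`` voxels
    (nearest first), consuming that entry, otherwise an FP.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if isinstance(truth, GroundTruth):
        positions = truth.positions(label)
    else:
        positions = np.asarray(truth, dtype=np.float64).reshape(-1, 3)
    order = sorted(range(len(candidates)), key=lambda i: -candidates[i].lcc)
    available = np.ones(len(positions), dtype=bool)
    labels: list[str] = []
    scores: list[float] = []
    for i in order:
        c = candidates[i]
        scores.append(float(c.lcc))
        if positions.size == 0 or not available.any():
            labels.append("FP")
            continue
        d = np.linalg.norm(positions - np.asarray(c.position, dtype=np.float64),
                           axis=1)
        d[~available] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tolerance:
            available[j] = False
            labels.append("TP")
        else:
            labels.append("FP")
    return LabeledCandidates(labels=labels, scores=scores,
                             n_truth=len(positions), tolerance=tolerance)


def classification_curve(
    labeled: LabeledCandidates,
) -> tuple[list[tuple[float, float, float]], float]:
    """(threshold, FDR, recall) per list prefix, and the RUC.

    Each prefix of the descending-score list is an operating point; the RUC
    is the maximum over prefixes of recall * (1 - FDR), the area of the
    largest rectangle fitting under the ROC-style curve.
    """
    if not labeled.labels:
        raise ValueError("cannot compute a curve from an empty candidate list")
    if labeled.n_truth == 0:
        raise ValueError("recall undefined: zero truth entries")
    tp = 0
    fp = 0
    curve: list[tuple[float, float, float]] = []
    ruc = 0.0
    for lab, score in zip(labeled.labels, labeled.scores):
        if lab == "TP":
            tp += 1
        else:
            fp += 1
        fdr = fp / (tp + fp)
        recall = tp / labeled.n_truth
        curve.append((score, fdr, recall))
        ruc = max(ruc, recall * (1.0 - fdr))
    return curve, ruc


def summary_metrics(labeled: LabeledCandidates) -> dict[str, float]:
    """Whole-list precision, recall, and f1 score."""
    if not labeled.labels:
        raise ValueError("cannot summarize an empty candidate list")
    tp, fp, fn = labeled.tp, labeled.fp, labeled.fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2.0 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}
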