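"""Directed-graph recovery metrics.

A predicted arc is *correct* (CA) when the ground truth has the same arc,
*reversed* (RA) when only the opposite arc exists in the truth, and *extra*
(EA) otherwise.  A truth arc is *missing* (MA) unless it was predicted, or
its reversal was predicted *as a reversal* (an RA prediction is counted
once and excuses its truth arc from MA; a reverse prediction that is itself
a correct arc of a reciprocal pair excuses nothing).  This pairing keeps
SHD = EA + MA + RA a true edit distance, symmetric in its arguments.
Reciprocal ("bidirectional") truth pairs count as two arcs throughout.
From the counts: precision = CA/TA, recall = CA/|G|, F1 their harmonic mean,
and the structural Hamming distance SHD = EA + MA + RA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArcCounts",
    "MetricsReport",
    "as_binary_adjacency",
    "classify_arcs",
    "compute_metrics",
    "evaluate_cohort",
    "edge_frequency",
]


def as_binary_adjacency(a: np.ndarray) -> np.ndarray:
    """Validate and return an n x n 0/1 adjacency with zero diagonal."""
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must contain only 0 and 1")
    if np.trace(a) != 0:
        raise ValueError("adjacency diagonal must be zero")
    return a.astype(np.int64)


@dataclass
class ArcCounts:
    ca: int  # correct
    ea: int  # extra
    ma: int  # missing
    ra: int  # reversed
    ta: int  # total predicted
    truth_size: int  # |G|, arcs in the ground truth

    def __post_init__(self):
        if min(self.ca, self.ea, self.ma, self.ra, self.ta, self.truth_size) < 0:
            raise ValueError("arc counts must be nonnegative")
        if self.ca + self.ea + self.ra != self.ta:
            raise ValueError("CA + EA + RA must equal TA")
        if self.ca > self.truth_size or self.ma > self.truth_size:
            raise ValueError("CA and MA cannot exceed the truth arc count")


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    shd: int
    counts: ArcCounts

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "shd": float(self.shd),
        }


def classify_arcs(pred: np.ndarray, truth: np.ndarray) -> ArcCounts:
    """Compare two binary adjacencies arc by arc."""
    p = as_binary_adjacency(pred)
    g = as_binary_adjacency(truth)
    if p.shape != g.shape:
        raise ValueError(f"size mismatch: pred {p.shape} vs truth {g.shape}")
    ca = int(np.sum((p == 1) & (g == 1)))
    ra = int(np.sum((p == 1) & (g == 0) & (g.T == 1)))
    ea = int(np.sum((p == 1) & (g == 0) & (g.T == 0)))
    # truth arc (i, j) is excused from MA only by an RA prediction (j, i),
    # i.e. pred(j, i) = 1 with no truth arc (j, i) of its own
    excused = (p.T == 1) & (g.T == 0)
    ma = int(np.sum((g == 1) & (p == 0) & ~excused))
    return ArcCounts(ca=ca, ea=ea, ma=ma, ra=ra, ta=int(p.sum()), truth_size=int(g.sum()))


def compute_metrics(counts: ArcCounts) -> MetricsReport:
    """Precision/recall/F1/SHD from arc counts.

    Precision is 0 by convention when nothing was predicted, and F1 is 0
    when precision + recall is 0, so empty predictions are still scored.
    """
    if counts.truth_size == 0:
        raise ValueError("ground truth has no arcs; recall is undefined")
    precision = counts.ca / counts.ta if counts.ta > 0 else 0.0
    recall = counts.ca / counts.truth_size
    denom = precision + recall
    f1 = 2.0 * precision * recall / denom if denom > 0 else 0.0
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        shd=counts.ea + counts.ma + counts.ra,
        counts=counts,
    )


@dataclass
class CohortEvaluation:
    """Per-subject reports plus mean ± population-σ per metric."""

    reports: list[MetricsReport]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)


def evaluate_cohort(
    preds: list[np.ndarray], truths: list[np.ndarray]
) -> CohortEvaluation:
    """Score each subject and aggregate as mean ± standard deviation."""
    if len(preds) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    if not preds:
        raise ValueError("no subjects to evaluate")
    reports = [
        compute_metrics(classify_arcs(p, g)) for p, g in zip(preds, truths)
    ]
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for key in ("precision", "recall", "f1", "shd"):
        vals = np.array([r.as_dict()[key] for r in reports])
        mean[key] = float(vals.mean())
        sd[key] = float(vals.std())  # population sigma
    return CohortEvaluation(reports=reports, mean=mean, sd=sd)


def edge_frequency(graphs: list[np.ndarray], min_fraction: float) -> np.ndarray:
    """Consensus network: arcs present in >= ceil(min_fraction * m) subjects."""
    if not graphs:
        raise ValueError("no graphs given")
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    stack = np.stack([as_binary_adjacency(g) for g in graphs])
    threshold = int(np.ceil(min_fraction * len(graphs)))
    return (stack.sum(axis=0) >= threshold).astype(np.int64)
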