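"""Functional connectivity and FC-guided refinement of directed networks.

Functional connectivity (FC) is the Pearson correlation matrix of region
signals — undirected, symmetric, diagonal 1.  The guidance step treats the
row-softmaxed FC matrix as an attention map and uses it to re-weight the
directed effective-connectivity (EC) graph: correlations say *which* region
pairs interact, the EC graph says *in which direction*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ECGraph

__all__ = ["FCMatrix", "pearson_fc", "guide_ec", "fc_skeleton"]


@dataclass
class FCMatrix:
    """Symmetric Pearson-correlation matrix of region signals."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        if np.abs(v).max() > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def pearson_fc(x_subject: np.ndarray) -> FCMatrix:
    """Pearson correlation of every region pair of one subject's (n, t) data.

    cov(x_i, x_j) / (sigma_i * sigma_j); the normalization constant cancels
    between numerator and denominator so population vs sample is immaterial.
    """
    x = np.asarray(x_subject, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (regions x timepoints) matrix")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"region {int(dead[0])} has zero variance; correlation is undefined"
        )
    w = np.corrcoef(x)
    np.fill_diagonal(w, 1.0)
    # corrcoef can exceed 1 by float error on exactly collinear rows
    return FCMatrix(np.clip((w + w.T) / 2.0, -1.0, 1.0))


def _row_softmax(w: np.ndarray) -> np.ndarray:
    e = np.exp(w - w.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def guide_ec(g: ECGraph, w: FCMatrix, mode: str = "matmul") -> ECGraph:
    """Refine an EC graph with the row-softmaxed FC matrix.

    ``matmul`` (default) takes the matrix product ``G @ rowsoftmax(W)`` —
    each region's outgoing weights are mixed through its targets' correlation
    profiles, preserving row-stochasticity.  ``hadamard`` multiplies
    elementwise instead, purely re-weighting existing entries.
    """
    if g.weights.shape != w.values.shape:
        raise ValueError(
            f"EC graph is {g.weights.shape} but FC matrix is {w.values.shape}"
        )
    s = _row_softmax(w.values)
    if mode == "matmul":
        guided = g.weights @ s
    elif mode == "hadamard":
        guided = g.weights * s
    else:
        raise ValueError(f"unknown guidance mode {mode!r}")
    return ECGraph(guided, normalized=(mode == "matmul" and g.normalized))


def fc_skeleton(w: FCMatrix, tau_fc: float) -> set[frozenset[int]]:
    """Undirected edges {i, j} whose |correlation| exceeds ``tau_fc``."""
    if not (0.0 <= tau_fc < 1.0):
        raise ValueError("tau_fc must lie in [0, 1)")
    n = w.n_regions
    return {
        frozenset((i, j))
        for i in range(n)
        for j in range(i + 1, n)
        if abs(w.values[i, j]) > tau_fc
    }
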