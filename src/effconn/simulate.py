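"""Synthetic cohorts with known directed ground-truth networks.

Generates random directed graphs (optionally with reciprocal, "bidirectional"
arc pairs) and fMRI-like multi-subject time series driven by those graphs.
The forward model is a lag-p vector autoregression on the graph: at each step
every region receives the coupling-weighted sum of its parents' lagged
signals, optionally squashed through tanh, plus optional shared exogenous
input, a global confound common to all regions, and white observation noise.
An optional haemodynamic smoothing convolves each region with a fixed
double-gamma kernel.  Subjects in a cohort share most of the network but may
differ by a few flipped arcs, mimicking inter-individual variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .data import CohortTimeSeries

__all__ = [
    "GroundTruthGraph",
    "SimOptions",
    "StabilityError",
    "make_graph",
    "make_stable_graph",
    "simulate_subject",
    "simulate_cohort",
    "hrf_kernel",
]

BURN_IN = 100  # transient steps discarded before the returned series
_EXOG_SCALE = 0.5  # amplitude of shared-input and confound series


class StabilityError(ValueError):
    """The coupled dynamics matrix has spectral radius >= 1."""


@dataclass
class GroundTruthGraph:
    """Binary directed network; ``adjacency[i, j] == 1`` means arc i -> j."""

    adjacency: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.trace(a) != 0:
            raise ValueError("self-loops are not allowed")
        self.adjacency = a.astype(np.int64)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_arcs(self) -> int:
        return int(self.adjacency.sum())

    @property
    def arc_list(self) -> list[tuple[int, int]]:
        return [(int(i), int(j)) for i, j in np.argwhere(self.adjacency == 1)]


@dataclass
class SimOptions:
    """Knobs of the synthetic forward model.

    ``noise_sd`` may be a scalar or a per-region sequence.  The coupled
    dynamics matrix ``adjacency * coupling_strength`` must have spectral
    radius below 1 or simulation is refused.
    """

    coupling_strength: float = 0.5
    lag_order: int = 1
    noise_sd: float | Sequence[float] = 1.0
    shared_input: bool = False
    global_confound: bool = False
    nonlinear: bool = False
    hrf_smoothing: bool = False
    subject_graph_flip_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.lag_order < 1:
            raise ValueError("lag_order must be >= 1")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.subject_graph_flip_prob < 1.0):
            raise ValueError("subject_graph_flip_prob must lie in [0, 1)")


def _spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def _check_stable(graph: GroundTruthGraph, coupling: float) -> np.ndarray:
    a = graph.adjacency * float(coupling)
    rho = _spectral_radius(a)
    if rho >= 1.0:
        raise StabilityError(
            f"dynamics matrix has spectral radius {rho:.3f} >= 1; "
            "reduce coupling_strength or use a sparser graph"
        )
    return a


def make_graph(
    n_nodes: int, n_arcs: int, n_bidirectional: int, seed: int
) -> GroundTruthGraph:
    """Random directed graph with exact arc and reciprocal-pair counts.

    The graph is weakly connected whenever enough distinct node pairs are
    touched to allow it (``n_arcs - n_bidirectional >= n_nodes - 1``; a
    reciprocal pair spends two arcs on one pair) and is deterministic for a
    fixed seed.
    """
    n_pairs = n_nodes * (n_nodes - 1) // 2
    n_single = n_arcs - 2 * n_bidirectional
    if n_arcs > n_nodes * (n_nodes - 1):
        raise ValueError(f"{n_arcs} arcs do not fit on {n_nodes} nodes")
    if n_single < 0:
        raise ValueError("2 * n_bidirectional exceeds n_arcs")
    if n_bidirectional + n_single > n_pairs:
        raise ValueError(
            f"{n_arcs} arcs with only {n_bidirectional} reciprocal pairs do not "
            f"fit on {n_nodes} nodes"
        )

    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    need_connected = n_arcs - n_bidirectional >= n_nodes - 1
    for _ in range(5000):
        order = rng.permutation(len(pairs))
        chosen = [pairs[k] for k in order[: n_bidirectional + n_single]]
        adj = np.zeros((n_nodes, n_nodes), dtype=np.int64)
        for idx, (i, j) in enumerate(chosen):
            if idx < n_bidirectional:
                adj[i, j] = adj[j, i] = 1
            elif rng.random() < 0.5:
                adj[i, j] = 1
            else:
                adj[j, i] = 1
        if need_connected:
            g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
            if not nx.is_weakly_connected(g):
                continue
        return GroundTruthGraph(adj)
    raise RuntimeError(
        "could not draw a weakly connected graph with the requested counts"
    )  # pragma: no cover - reachable only for pathological count combinations


def make_stable_graph(
    n_nodes: int,
    n_arcs: int,
    n_bidirectional: int,
    coupling_strength: float,
    seed: int,
    max_tries: int = 200,
) -> GroundTruthGraph:
    """Draw graphs until one lies in the simulator's stability domain.

    Convenience for pipelines: redraws with derived seeds until
    ``adjacency * coupling_strength`` has spectral radius < 1.
    """
    for k in range(max_tries):
        graph = make_graph(n_nodes, n_arcs, n_bidirectional, seed + 7919 * k)
        if _spectral_radius(graph.adjacency * coupling_strength) < 1.0:
            return graph
    raise StabilityError(
        f"no stable graph found in {max_tries} draws at coupling {coupling_strength}"
    )


def hrf_kernel(length: int = 12, peak: float = 5.0, undershoot: float = 11.0) -> np.ndarray:
    """Discretized double-gamma haemodynamic response, unit area.

    Shape parameters are chosen so the positive lobe peaks at ``peak``
    samples (gamma mode = shape - 1 at unit scale).
    """
    x = np.arange(length, dtype=np.float64)
    lobe = stats.gamma.pdf(x, peak + 1.0)
    dip = stats.gamma.pdf(x, undershoot + 1.0)
    kernel = lobe - dip / 6.0
    return kernel / kernel.sum()


def _drive(history: np.ndarray, a_t: np.ndarray, lag: int, step: int) -> np.ndarray:
    # history holds x_0 .. x_{step-1}; regions receive parents' lag-`lag` signal
    if step - lag < 0:
        return np.zeros(a_t.shape[0])
    return a_t @ history[step - lag]


def simulate_subject(
    graph: GroundTruthGraph, t: int, opts: SimOptions, seed: int
) -> np.ndarray:
    """One subject's (n, t) series from the graph-coupled autoregression.

    The recursion starts from rest (zero state); the first ``BURN_IN`` steps
    are discarded so the returned points are past the initial transient.
    """
    if t < opts.lag_order + 2:
        raise ValueError(f"t must be >= lag_order + 2, got t={t}")
    a = _check_stable(graph, opts.coupling_strength)
    a_t = a.T  # row j of a_t collects the parents of region j
    n = graph.n_nodes
    total = t + BURN_IN
    rng = np.random.default_rng(seed)

    noise_sd = np.broadcast_to(np.asarray(opts.noise_sd, dtype=np.float64), (n,))
    noise = rng.normal(0.0, 1.0, size=(total, n)) * noise_sd

    exog = np.zeros((total, n))
    if opts.shared_input:
        # one common driving series injected into >= 2 randomly chosen regions
        k = int(rng.integers(2, n + 1)) if n >= 2 else n
        targets = rng.choice(n, size=k, replace=False)
        series = rng.normal(0.0, 1.0, size=total) * _EXOG_SCALE
        exog[:, targets] += series[:, None]
    if opts.global_confound:
        confound = rng.normal(0.0, 1.0, size=total) * _EXOG_SCALE
        exog += confound[:, None]

    x = np.zeros((total, n))
    for step in range(total):
        det = _drive(x, a_t, opts.lag_order, step)
        if opts.nonlinear:
            det = np.tanh(det)
        x[step] = det + exog[step] + noise[step]

    out = x[BURN_IN:].T  # (n, t)
    if opts.hrf_smoothing:
        kernel = hrf_kernel()
        out = np.apply_along_axis(
            lambda row: np.convolve(row, kernel, mode="full")[:t], 1, out
        )
    return out


def _flip_graph(
    base: GroundTruthGraph, flip_prob: float, rng: np.random.Generator
) -> np.ndarray:
    adj = base.adjacency.copy()
    off = ~np.eye(base.n_nodes, dtype=bool)
    flips = (rng.random(adj.shape) < flip_prob) & off
    adj[flips] = 1 - adj[flips]
    return adj


def simulate_cohort(
    graph: GroundTruthGraph, m: int, t: int, opts: SimOptions, seed: int
) -> tuple[CohortTimeSeries, list[GroundTruthGraph]]:
    """Simulate ``m`` subjects whose networks are noisy copies of ``graph``.

    Each subject's network flips every off-diagonal entry of the base
    adjacency independently with probability ``subject_graph_flip_prob``
    (redrawn, up to 100 times, if the flipped network is unstable).  Returns
    the cohort together with the per-subject ground truths.
    """
    if m < 1:
        raise ValueError("need at least one subject")
    child = np.random.SeedSequence(seed).generate_state(2 * m)
    data = np.empty((m, graph.n_nodes, t))
    truths: list[GroundTruthGraph] = []
    for s in range(m):
        flip_rng = np.random.default_rng(int(child[2 * s]))
        subject_graph = None
        last_err: StabilityError | None = None
        for _ in range(100):
            candidate = GroundTruthGraph(
                _flip_graph(graph, opts.subject_graph_flip_prob, flip_rng)
            )
            try:
                _check_stable(candidate, opts.coupling_strength)
            except StabilityError as err:
                last_err = err
                continue
            subject_graph = candidate
            break
        if subject_graph is None:
            raise last_err  # type: ignore[misc]
        truths.append(subject_graph)
        data[s] = simulate_subject(subject_graph, t, opts, int(child[2 * s + 1]))
    return CohortTimeSeries(data), truths
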