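"""Amortized training, test-time adaptation, and graph binarization.

One encoder–decoder parameter set is fitted jointly across subjects
(amortized learning): subjects are processed in groups, each group's
reconstruction drives one gradient step, and the shared parameters absorb
the network structure common to the cohort.  A new, unseen subject is then
handled by a few epochs of *test-time adaptation* — brief fine-tuning of a
copy of the trained state on that subject alone — instead of refitting from
scratch.

The loss is an evidence-lower-bound style objective: a fixed-variance
Gaussian reconstruction term plus, per graph row, the KL divergence to a
uniform prior over off-diagonal targets, plus an L1 sparsity penalty on the
graph weights.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .data import CohortTimeSeries
from .model import DecoderConfig, ECGraph, ECModel, EncoderConfig, ModelState
from .nn import Adam

__all__ = [
    "TrainingConfig",
    "TrainReport",
    "DivergenceError",
    "elbo_loss",
    "sparsity_penalty",
    "train_amortized",
    "adapt_subject",
    "binarize",
]

_EPS = 1e-12  # probability floor inside the KL term


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class TrainingConfig:
    lr: float = 0.0025
    adapt_lr: float = 0.05
    epochs: int = 200
    adapt_epochs: int = 10
    amortize_m: int = 5
    sparsity_weight: float = 0.1
    binarize_threshold: float = 0.3
    prior: str = "uniform-rows"
    likelihood_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.adapt_lr) <= 0:
            raise ValueError("learning rates must be positive")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.prior != "uniform-rows":
            raise ValueError(f"unknown prior {self.prior!r}")
        if self.amortize_m < 1:
            raise ValueError("amortize_m must be >= 1")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrainReport:
    loss_trace: list[float]
    graphs: list[ECGraph]
    seed: int
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# loss terms (public numpy forms + internal tensor forms)


def _kl_uniform_rows(weights: np.ndarray) -> float:
    """Sum over rows of KL(row || uniform over off-diagonal targets)."""
    n = weights.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    p = np.clip(weights[off], _EPS, None).reshape(n, n - 1)
    q = 1.0 / (n - 1)
    return float(np.sum(p * np.log(p / q)))


def elbo_loss(
    x: CohortTimeSeries | np.ndarray,
    x_hat: np.ndarray,
    graphs: list[ECGraph],
    cfg: TrainingConfig,
) -> float:
    """Gaussian reconstruction error plus KL of each graph row to the prior.

    ``x_hat`` holds one-step predictions for the last ``t - K`` timepoints of
    ``x``; the reconstruction term is sum((x - x_hat)^2) / (2 sd^2).
    """
    data = x.data if isinstance(x, CohortTimeSeries) else np.asarray(x)
    if data.ndim == 2:
        data = data[None]
    x_hat = np.asarray(x_hat)
    if x_hat.ndim == 2:
        x_hat = x_hat[None]
    k = data.shape[-1] - x_hat.shape[-1]
    if k < 0 or x_hat.shape[:2] != data.shape[:2]:
        raise ValueError("reconstruction is not aligned with the input")
    resid = data[..., k:] - x_hat
    recon = float(np.sum(resid**2)) / (2.0 * cfg.likelihood_sd**2)
    kl = sum(_kl_uniform_rows(g.weights) for g in graphs)
    return recon + kl


def sparsity_penalty(graphs: list[ECGraph], weight: float) -> float:
    """L1 penalty: weight times the sum of absolute graph entries."""
    return float(weight) * float(sum(np.abs(g.weights).sum() for g in graphs))


def _loss_tensor(
    x_tail: np.ndarray, x_hat: Tensor, g: Tensor, cfg: TrainingConfig
) -> Tensor:
    """Differentiable single-subject loss mirroring the public numpy forms."""
    resid = Tensor(x_tail) - x_hat
    recon = T.tsum(resid * resid) * (1.0 / (2.0 * cfg.likelihood_sd**2))
    n = g.shape[0]
    loss = recon
    if n >= 2:
        off = ~np.eye(n, dtype=bool)
        p = T.clamp_min(g[off], _EPS)
        kl = T.tsum(p * T.log(p * float(n - 1)))
        loss = loss + kl
    if cfg.sparsity_weight:
        # graph weights are nonnegative, so the L1 norm is their plain sum
        loss = loss + cfg.sparsity_weight * T.tsum(g)
    return loss


# ---------------------------------------------------------------------------
# training


def _chunks(indices: list[int], size: int) -> list[list[int]]:
    return [indices[i : i + size] for i in range(0, len(indices), size)]


def _run_epochs(
    model: ECModel,
    data: np.ndarray,
    cfg: TrainingConfig,
    optimizer: Adam,
    epochs: int,
    group_size: int,
) -> list[float]:
    k = model.decoder_config.lag_window
    groups = _chunks(list(range(data.shape[0])), group_size)
    trace: list[float] = []
    for epoch in range(epochs):
        epoch_loss = 0.0
        for group in groups:
            optimizer.zero_grad()
            loss: Tensor | None = None
            for s in group:
                x = Tensor(data[s])
                g, x_hat = model.forward_subject(x)
                term = _loss_tensor(data[s][:, k:], x_hat, g, cfg)
                loss = term if loss is None else loss + term
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item()
        if not np.isfinite(epoch_loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        trace.append(epoch_loss)
    return trace


def train_amortized(
    cohort: CohortTimeSeries,
    cfg: TrainingConfig | None = None,
    encoder_config: EncoderConfig | None = None,
    decoder_config: DecoderConfig | None = None,
) -> tuple[ModelState, TrainReport]:
    """Fit one shared model to a cohort by grouped gradient descent.

    Subjects are processed ``amortize_m`` at a time per forward/backward
    pass (a trailing smaller group is kept, not dropped).  Returns the
    trained state and a report with the per-epoch loss trace and each
    subject's final weighted graph.
    """
    cfg = cfg or TrainingConfig()
    model = ECModel(
        cohort.n_timepoints, encoder_config, decoder_config, seed=cfg.seed
    )
    optimizer = Adam(model.parameters(), lr=cfg.lr)
    trace = _run_epochs(
        model, cohort.data, cfg, optimizer, cfg.epochs, cfg.amortize_m
    )
    graphs = [model.encode_subject(cohort.subject(s)) for s in range(cohort.n_subjects)]
    state = ModelState(
        model=model,
        seed=cfg.seed,
        training_config=cfg.as_dict(),
        n_regions=cohort.n_regions,
    )
    report = TrainReport(
        loss_trace=trace, graphs=graphs, seed=cfg.seed, config=cfg.as_dict()
    )
    return state, report


def _sgd_epochs(
    model: ECModel, x: np.ndarray, cfg: TrainingConfig, epochs: int, lr: float
) -> None:
    """Plain gradient steps on the per-element mean objective.

    Adaptation deliberately uses unnormalized gradient descent rather than
    the adaptive-moment optimizer of the amortized phase: adaptive steps are
    lr-sized for every parameter regardless of gradient magnitude, which at
    the (much larger) adaptation rate erases the trained state in a handful
    of steps, while plain descent scales updates by how far the new subject
    actually pulls each parameter.  The loss is divided by the number of
    predicted values so the rate is independent of series length.
    """
    params = model.parameters()
    k = model.decoder_config.lag_window
    n_el = x.shape[0] * (x.shape[1] - k)
    for _ in range(epochs):
        for p in params:
            p.grad = None
        g, x_hat = model.forward_subject(Tensor(x))
        loss = _loss_tensor(x[:, k:], x_hat, g, cfg) * (1.0 / n_el)
        loss.backward()
        if not np.isfinite(loss.item()):
            raise DivergenceError("non-finite loss during adaptation")
        for p in params:
            if p.grad is not None:
                p.data -= lr * p.grad


def adapt_subject(
    state: ModelState, x_new: np.ndarray, cfg: TrainingConfig | None = None
) -> ECGraph:
    """Estimate an unseen subject's graph by brief test-time adaptation.

    Fine-tunes a *copy* of the trained parameters for ``adapt_epochs`` at
    ``adapt_lr`` on the single subject; the original state is untouched.
    With ``adapt_epochs=0`` this is the amortized model's zero-shot graph.
    """
    if cfg is None:
        cfg = (
            TrainingConfig(**state.training_config)
            if state.training_config
            else TrainingConfig()
        )
    x_new = np.asarray(x_new, dtype=np.float64)
    if x_new.ndim != 2:
        raise ValueError("x_new must be a single-subject (n, t) matrix")
    if state.n_regions is not None and x_new.shape[0] != state.n_regions:
        raise ValueError(
            f"model was trained on {state.n_regions} regions, got {x_new.shape[0]}"
        )
    if x_new.shape[1] != state.model.n_timepoints:
        raise ValueError(
            f"model expects t={state.model.n_timepoints}, got t={x_new.shape[1]}"
        )
    adapted = state.model.copy()
    if cfg.adapt_epochs > 0:
        _sgd_epochs(adapted, x_new, cfg, cfg.adapt_epochs, cfg.adapt_lr)
    return adapted.encode_subject(x_new)


def binarize(g: ECGraph, threshold: float) -> np.ndarray:
    """Arc (i, j) kept iff its weight strictly exceeds the threshold."""
    binary = (g.weights > threshold).astype(np.int64)
    np.fill_diagonal(binary, 0)
    return binary
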