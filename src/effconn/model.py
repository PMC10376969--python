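"""Transformer graph encoder and Granger-style MLP decoder.

The encoder treats the *regions* of one subject as the token sequence: each
region's whole time course is embedded to an h-vector, passed through a stack
of multi-head self-attention blocks (residual + layer normalization, no
positional encoding — regions are unordered), and a pairwise feed-forward
head scores every ordered region pair.  Scores are row-softmaxed with the
diagonal masked, giving a row-stochastic directed graph G whose entry (i, j)
is the inferred influence of region i on region j.

The decoder enforces the Granger reading of G: the next value of region j is
predicted only from the G-weighted mix of the *other* regions' recent
history (a K-step window), through a small MLP shared across regions.
Training the two jointly makes reconstruction quality a proxy for how well G
matches the true coupling.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .data import CohortTimeSeries
from .nn import MLP, Adam, LayerNorm, Linear, get_activation

__all__ = [
    "EncoderConfig",
    "DecoderConfig",
    "ECGraph",
    "GraphEncoder",
    "Decoder",
    "ECModel",
    "ModelState",
    "scaled_dot_attention",
    "self_attention_head",
    "embed_regions",
    "encode_graph",
    "decode_next",
    "reconstruct",
]


@dataclass
class EncoderConfig:
    """Architecture of the graph encoder.

    Defaults are the reference configuration (6 layers, 4 heads, 2048 hidden
    units); :meth:`small` is a light preset for desk-scale experiments.
    """

    n_layers: int = 6
    n_heads: int = 4
    hidden_dim: int = 2048
    ff_dim: int | None = None
    activation: str = "relu"
    mask_diagonal: bool = True

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.ff_dim is None:
            self.ff_dim = self.hidden_dim

    @property
    def head_dim(self) -> int:
        return self.hidden_dim // self.n_heads

    @classmethod
    def small(cls) -> "EncoderConfig":
        return cls(n_layers=2, n_heads=4, hidden_dim=128)


@dataclass
class DecoderConfig:
    """Architecture of the next-step decoder.

    ``lag_window`` is K, the number of most recent timepoints aggregated per
    incoming edge; the MLP maps that K-vector to the next scalar value.
    """

    n_hidden_layers: int = 3
    lag_window: int = 5
    hidden_dim: int = 16
    activation: str = "relu"

    def __post_init__(self):
        if self.lag_window < 1:
            raise ValueError("lag_window must be >= 1")
        if self.n_hidden_layers < 1:
            raise ValueError("n_hidden_layers must be >= 1")

    @classmethod
    def stacked(cls) -> "DecoderConfig":
        """Alternative deeper preset: two blocks of three linear layers."""
        return cls(n_hidden_layers=6)


@dataclass
class ECGraph:
    """Nonnegative weighted directed graph; (i, j) = influence of i on j."""

    weights: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("graph weights must be square")
        if w.min() < -1e-9:
            raise ValueError("graph weights must be nonnegative")
        if self.normalized:
            sums = w.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("normalized graph rows must sum to 1")
        self.weights = np.clip(w, 0.0, None)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# encoder


class _EncoderBlock:
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        h = cfg.hidden_dim
        self.cfg = cfg
        self.wq = Linear(h, h, rng)
        self.wk = Linear(h, h, rng)
        self.wv = Linear(h, h, rng)
        self.wo = Linear(h, h, rng)
        self.ln1 = LayerNorm(h)
        self.ln2 = LayerNorm(h)
        self.ff1 = Linear(h, cfg.ff_dim, rng)
        self.ff2 = Linear(cfg.ff_dim, h, rng)
        self.act = get_activation(cfg.activation)

    def __call__(self, x: Tensor) -> Tensor:
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        d = self.cfg.head_dim
        heads = []
        for l in range(self.cfg.n_heads):
            sl = slice(l * d, (l + 1) * d)
            heads.append(
                _attention(q[:, sl], k[:, sl], v[:, sl])
            )
        attended = self.wo(T.concat(heads, axis=1))
        x = self.ln1(x + attended)
        return self.ln2(x + self.ff2(self.act(self.ff1(x))))

    def parameters(self) -> list[Tensor]:
        mods = (self.wq, self.wk, self.wv, self.wo, self.ln1, self.ln2, self.ff1, self.ff2)
        return [p for m in mods for p in m.parameters()]


def _attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    d = q.shape[-1]
    logits = (q @ T.transpose(k)) * (1.0 / np.sqrt(d))
    return T.softmax(logits, axis=-1) @ v


class _PairwiseGraphHead:
    """Two-layer feed-forward scorer of ordered region pairs.

    logit(i, j) = v . ReLU(W_src f_i + W_dst f_j + b); being a function of the
    two token features only, it is exactly equivariant under region
    permutation.
    """

    def __init__(self, h: int, rng: np.random.Generator):
        self.src = Linear(h, h, rng)
        self.dst = Linear(h, h, rng)
        self.out = Linear(h, 1, rng)

    def __call__(self, f: Tensor) -> Tensor:
        n, h = f.shape
        a = T.reshape(self.src(f), (n, 1, h))
        b = T.reshape(self.dst(f), (1, n, h))
        pair = T.relu(a + b)
        scores = self.out(T.reshape(pair, (n * n, h)))
        return T.reshape(scores, (n, n))

    def parameters(self) -> list[Tensor]:
        return self.src.parameters() + self.dst.parameters() + self.out.parameters()


class GraphEncoder:
    """Cohort time series -> row-stochastic directed graph, one per subject."""

    def __init__(self, n_timepoints: int, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.n_timepoints = n_timepoints
        self.embed = Linear(n_timepoints, cfg.hidden_dim, rng)
        self.blocks = [_EncoderBlock(cfg, rng) for _ in range(cfg.n_layers)]
        self.head = _PairwiseGraphHead(cfg.hidden_dim, rng)

    def embed_tokens(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.n_timepoints:
            raise ValueError(
                f"encoder was built for t={self.n_timepoints}, got t={x.shape[-1]}"
            )
        return self.embed(x)

    def features(self, x: Tensor) -> Tensor:
        f = self.embed_tokens(x)
        for block in self.blocks:
            f = block(f)
        return f

    def __call__(self, x: Tensor) -> Tensor:
        logits = self.head(self.features(x))
        n = logits.shape[0]
        if self.cfg.mask_diagonal and n > 1:
            mask = np.zeros((n, n))
            np.fill_diagonal(mask, -np.inf)
            logits = logits + Tensor(mask)
        return T.softmax(logits, axis=-1)

    def parameters(self) -> list[Tensor]:
        params = self.embed.parameters()
        for block in self.blocks:
            params += block.parameters()
        return params + self.head.parameters()


# ---------------------------------------------------------------------------
# decoder


class Decoder:
    """Predict each region's next value from its G-weighted incoming history."""

    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        dims = [cfg.lag_window] + [cfg.hidden_dim] * cfg.n_hidden_layers + [1]
        self.mlp = MLP(dims, cfg.activation, rng)

    def decode_step(self, x_window: Tensor, g: Tensor) -> Tensor:
        """One step: (n, K) window + graph -> n-vector of next values."""
        k = self.cfg.lag_window
        if x_window.shape[-1] != k:
            raise ValueError(f"window must have K={k} columns, got {x_window.shape[-1]}")
        msg = T.transpose(g) @ x_window  # (n, K) incoming weighted sums
        return T.reshape(self.mlp(msg), (x_window.shape[0],))

    def forward_series(self, x: Tensor, g: Tensor) -> Tensor:
        """Teacher-forced one-step predictions for every valid t: (n, t - K)."""
        k = self.cfg.lag_window
        y = T.transpose(g) @ x  # messages for all t at once
        win = T.sliding_windows(y, k)  # (n, t - K, K)
        n, n_win, _ = win.shape
        out = self.mlp(T.reshape(win, (n * n_win, k)))
        return T.reshape(out, (n, n_win))

    def parameters(self) -> list[Tensor]:
        return self.mlp.parameters()


# ---------------------------------------------------------------------------
# joint model


class ECModel:
    """Encoder + decoder sharing one parameter set across all subjects."""

    def __init__(
        self,
        n_timepoints: int,
        encoder_config: EncoderConfig | None = None,
        decoder_config: DecoderConfig | None = None,
        seed: int = 0,
    ):
        self.encoder_config = encoder_config or EncoderConfig()
        self.decoder_config = decoder_config or DecoderConfig()
        self.n_timepoints = n_timepoints
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = GraphEncoder(n_timepoints, self.encoder_config, rng)
        self.decoder = Decoder(self.decoder_config, rng)

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.decoder.parameters()

    def forward_subject(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """One subject's (graph, teacher-forced reconstruction)."""
        g = self.encoder(x)
        return g, self.decoder.forward_series(x, g)

    def encode_subject(self, x_subject: np.ndarray) -> ECGraph:
        g = self.encoder(Tensor(x_subject))
        return ECGraph(g.data, normalized=True)

    def copy(self) -> "ECModel":
        return copy.deepcopy(self)


@dataclass
class ModelState:
    """Trained parameters plus the configuration that produced them."""

    model: ECModel
    seed: int
    training_config: dict = field(default_factory=dict)
    n_regions: int | None = None  # region count of the training cohort, if known

    @property
    def encoder_config(self) -> EncoderConfig:
        return self.model.encoder_config

    @property
    def decoder_config(self) -> DecoderConfig:
        return self.model.decoder_config


# ---------------------------------------------------------------------------
# functional operations (numpy in, numpy out)


def scaled_dot_attention(
    q: np.ndarray, k: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """rowsoftmax(Q K^T / sqrt(D)) V; returns (output, attention weights)."""
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    d = q.shape[-1]
    logits = q @ k.T / np.sqrt(d)
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite attention logits")
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ v, weights


def self_attention_head(
    x: np.ndarray,
    w_q: np.ndarray,
    w_k: np.ndarray,
    w_v: np.ndarray,
    b_q: float | np.ndarray = 0.0,
    b_k: float | np.ndarray = 0.0,
    b_v: float | np.ndarray = 0.0,
) -> np.ndarray:
    """One attention head over region tokens: project then attend."""
    x = np.asarray(x, dtype=np.float64)
    q = x @ np.asarray(w_q) + b_q
    k = x @ np.asarray(w_k) + b_k
    v = x @ np.asarray(w_v) + b_v
    out, _ = scaled_dot_attention(q, k, v)
    return out


def embed_regions(x: CohortTimeSeries | np.ndarray, model: ECModel) -> np.ndarray:
    """Embed every region's time course: (m, n, t) -> (m, n, h)."""
    data = x.data if isinstance(x, CohortTimeSeries) else np.asarray(x)
    if data.ndim == 2:
        data = data[None]
    return np.stack(
        [model.encoder.embed_tokens(Tensor(subj)).data for subj in data]
    )


def encode_graph(x: CohortTimeSeries | np.ndarray, model: ECModel) -> list[ECGraph]:
    """Per-subject row-stochastic graphs for a whole cohort."""
    data = x.data if isinstance(x, CohortTimeSeries) else np.asarray(x)
    if data.ndim == 2:
        data = data[None]
    return [model.encode_subject(subj) for subj in data]


def decode_next(x_window: np.ndarray, g: ECGraph, decoder: Decoder) -> np.ndarray:
    """Next-value prediction for each region from a (n, K) history window."""
    x_window = np.asarray(x_window, dtype=np.float64)
    k = decoder.cfg.lag_window
    if x_window.shape[-1] < k:
        raise ValueError(f"window has {x_window.shape[-1]} timepoints, needs K={k}")
    window = x_window[:, -k:]
    return decoder.decode_step(Tensor(window), Tensor(g.weights)).data


def reconstruct(
    x: CohortTimeSeries | np.ndarray, graphs: list[ECGraph], model: ECModel
) -> np.ndarray:
    """Teacher-forced one-step predictions: (m, n, t) -> (m, n, t - K)."""
    data = x.data if isinstance(x, CohortTimeSeries) else np.asarray(x)
    if data.ndim == 2:
        data = data[None]
    if len(graphs) != data.shape[0]:
        raise ValueError("need one graph per subject")
    k = model.decoder.cfg.lag_window
    if data.shape[-1] <= k:
        raise ValueError(f"need more than K={k} timepoints")
    return np.stack(
        [
            model.decoder.forward_series(Tensor(subj), Tensor(g.weights)).data
            for subj, g in zip(data, graphs)
        ]
    )
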