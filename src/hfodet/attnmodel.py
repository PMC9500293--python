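"""The additive multi-head self-attention HFO detector and its ablations.

Model family
------------
Every variant shares a dense front end that maps one 2-s signal window
(4,800 samples by default) to 512 features. The attention variants reshape
those features into n = 8 tokens of width d = 64 and pass them through

* ``attn_1`` — a multi-head additive self-attention layer (k heads project
  tokens to d/k-dimensional subspaces, score them with an additive
  compatibility function ``f(x_i) = w . sigma(W1 x_i)``, softmax the scores,
  and re-weight each projected token by its importance; heads are
  concatenated and re-projected by an output matrix),
* ``attn_2`` — a single full-width additive self-attention layer,
* ``msadr`` — both, multi-head followed by single self-attention,
* ``raw`` / ``smo`` — neither (a plain feed-forward net, the reference DNN).

The re-weighted token sequence is flattened and classified by a
dense(128) - norm - dense(32) - norm - sigmoid head. Training minimizes
binary cross-entropy with Adam. Both attention layers re-weight tokens
(``p_i * x_i``, preserving the n x d sequence); the weighted-sum pooling form
of additive attention is exposed separately as :func:`self_attention_pool`.

The whole network is implemented in numpy with explicit backpropagation;
gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

_logger = logging.getLogger("hfodet.attnmodel")

from hfodet.core import HFO, NC, UNKNOWN, ConfigError, LabeledSegment, derive_rng
from hfodet.sigio import bandpass, resolve_filter

VARIANTS = ("raw", "smo", "attn_1", "attn_2", "msadr")
ABLATION_VARIANTS = ("raw", "attn_1", "attn_2", "msadr")

_EPS_PROB = 1e-7


def _activation(name: str):
    if name == "tanh":
        return np.tanh, lambda z, a: 1.0 - a**2
    if name == "relu":
        return lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)
    raise ConfigError(f"unknown activation {name!r}; choose 'tanh' or 'relu'")


# ---------------------------------------------------------------------------
# Functional attention primitives (single instance, float64)
# ---------------------------------------------------------------------------


@dataclass
class AttentionParams:
    """Parameters of one additive attention scorer at token dimension d.

    ``W2`` participates only in the query-conditioned form
    ``f(x_i, q) = w . sigma(W1 x_i + W2 q)``; self-attention drops the query.
    """

    W1: np.ndarray
    w: np.ndarray
    W2: np.ndarray | None = None
    activation: str = "tanh"

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.W2 is not None:
            self.W2 = np.asarray(self.W2, dtype=float)
        d = self.w.size
        if self.W1.shape != (d, d) or (self.W2 is not None and self.W2.shape != (d, d)):
            raise ConfigError(f"attention parameter shapes inconsistent with d={d}")


@dataclass
class MultiHeadParams:
    """Parameters of a k-head additive self-attention layer at width d."""

    Wx: list[np.ndarray]  # k projections, each d x (d/k)
    heads: list[AttentionParams]  # per-head scorers at dimension d/k
    WO: np.ndarray  # d x d output projection

    def __post_init__(self) -> None:
        self.Wx = [np.asarray(m, dtype=float) for m in self.Wx]
        self.WO = np.asarray(self.WO, dtype=float)
        if len(self.Wx) != len(self.heads) or not self.Wx:
            raise ConfigError("need one projection per head")
        d = self.WO.shape[0]
        k = len(self.Wx)
        if d % k != 0 or self.WO.shape != (d, d):
            raise ConfigError(f"token dimension {d} must be divisible by head count {k}")
        dk = d // k
        for m, h in zip(self.Wx, self.heads):
            if m.shape != (d, dk) or h.w.size != dk:
                raise ConfigError("head projection/scorer shapes inconsistent")

    @property
    def k(self) -> int:
        return len(self.Wx)


def additive_score(x_i: np.ndarray, params: AttentionParams, q: np.ndarray | None = None) -> float:
    """Additive compatibility score ``w . sigma(W1 x_i [+ W2 q])``."""
    x_i = np.asarray(x_i, dtype=float).ravel()
    if x_i.size != params.w.size:
        raise ConfigError(f"x_i has dimension {x_i.size}, parameters expect {params.w.size}")
    act, _ = _activation(params.activation)
    pre = params.W1 @ x_i
    if q is not None:
        if params.W2 is None:
            raise ConfigError("query-conditioned score needs W2")
        q = np.asarray(q, dtype=float).ravel()
        if q.size != params.w.size:
            raise ConfigError("query dimension mismatch")
        pre = pre + params.W2 @ q
    return float(params.w @ act(pre))


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Softmax of the score vector (max-subtracted for numerical stability)."""
    s = np.asarray(scores, dtype=float).ravel()
    if s.size == 0:
        raise ConfigError("cannot normalize an empty score vector")
    e = np.exp(s - s.max())
    return e / e.sum()


def _scores(x: np.ndarray, params: AttentionParams) -> np.ndarray:
    act, _ = _activation(params.activation)
    return act(x @ params.W1.T) @ params.w


def self_attention_pool(x: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Importance-weighted sum of the token sequence: ``sum_i p(z=i|x) x_i``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ConfigError("x must be a non-empty n x d sequence")
    if x.shape[1] != params.w.size:
        raise ConfigError("token dimension mismatch")
    p = attention_weights(_scores(x, params))
    return p @ x


def self_attention_reweight(x: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Each token scaled by its importance weight: ``y_i = p(z=i|x) x_i``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ConfigError("x must be a non-empty n x d sequence")
    if x.shape[1] != params.w.size:
        raise ConfigError("token dimension mismatch")
    p = attention_weights(_scores(x, params))
    return p[:, None] * x


def multi_head_self_attention(x: np.ndarray, params: MultiHeadParams) -> np.ndarray:
    """k-head additive self-attention; output shape equals input shape n x d.

    Each head projects the sequence to n x (d/k), re-weights tokens within the
    head by their softmax importance, and the concatenated heads are mixed by
    the output projection WO.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ConfigError("x must be an n x d sequence")
    d = params.WO.shape[0]
    if x.shape[1] != d:
        raise ConfigError(f"token dimension {x.shape[1]} != parameter dimension {d}")
    outs = []
    for Wx, head in zip(params.Wx, params.heads):
        proj = x @ Wx
        outs.append(self_attention_reweight(proj, head))
    return np.concatenate(outs, axis=1) @ params.WO


def cross_entropy(y: int, p: float) -> float:
    """Binary cross-entropy ``-y log p - (1-y) log(1-p)`` with p clipped to [eps, 1-eps]."""
    if y not in (0, 1):
        raise ConfigError(f"target label must be 0 or 1, got {y!r}")
    pc = min(max(float(p), _EPS_PROB), 1.0 - _EPS_PROB)
    return float(-y * np.log(pc) - (1 - y) * np.log(1.0 - pc))


# ---------------------------------------------------------------------------
# Layers with backprop
# ---------------------------------------------------------------------------


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class _Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1] if len(shape) > 1 else 1
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dropout(_Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not (0 <= p < 1):
            raise ConfigError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, activation: str | None, rng, name: str, dtype):
        self.W = Param(_glorot(rng, (n_in, n_out), dtype), f"{name}/W")
        self.b = Param(np.zeros(n_out, dtype=dtype), f"{name}/b")
        self.activation = activation
        self._x = None
        self._z = None
        self._a = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation is None:
            self._z = None
            return z
        act, _ = _activation(self.activation)
        self._z = z
        self._a = act(z)
        return self._a

    def backward(self, g):
        if self.activation is not None:
            _, dact = _activation(self.activation)
            g = g * dact(self._z, self._a)
        self.W.grad = self._x.T @ g
        self.b.grad = g.sum(axis=0)
        return g @ self.W.value.T


class BatchNorm(_Layer):
    """Batch normalization over the batch axis; running stats at inference."""

    def __init__(self, n_feat: int, name: str, dtype, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_feat, dtype=dtype), f"{name}/gamma")
        self.beta = Param(np.zeros(n_feat, dtype=dtype), f"{name}/beta")
        self.running_mean = np.zeros(n_feat, dtype=dtype)
        self.running_var = np.ones(n_feat, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g):
        xhat, inv, m = self._cache
        self.gamma.grad = (g * xhat).sum(axis=0)
        self.beta.grad = g.sum(axis=0)
        gx = g * self.gamma.value
        return inv / m * (m * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))


class Reshape(_Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape
        self._in = None

    def forward(self, x, training):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, g):
        return g.reshape(self._in)


class Flatten(_Layer):
    def __init__(self):
        self._in = None

    def forward(self, x, training):
        self._in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._in)


def _batched_reweight_forward(P, W1, w, activation):
    """Shared forward of additive self-attention re-weighting on (B, n, dk)."""
    act, _ = _activation(activation)
    Z = P @ W1.T
    S = act(Z)
    s = S @ w
    s = s - s.max(axis=1, keepdims=True)
    E = np.exp(s)
    A = E / E.sum(axis=1, keepdims=True)
    Y = A[..., None] * P
    return Y, (P, Z, S, A)


def _batched_reweight_backward(G, cache, W1, w, activation):
    """Gradients of the re-weighting block: returns (dP, dW1, dw)."""
    P, Z, S, A = cache
    _, dact = _activation(activation)
    dA = np.sum(G * P, axis=-1)
    dP = A[..., None] * G
    ds = A * (dA - np.sum(dA * A, axis=1, keepdims=True))
    dS = ds[..., None] * w
    dZ = dS * dact(Z, S)
    dw = np.einsum("bnd,bn->d", S, ds)
    dW1 = np.einsum("bna,bnc->ac", dZ, P)
    dP = dP + dZ @ W1
    return dP, dW1, dw


class SelfAttentionLayer(_Layer):
    """Full-width additive self-attention re-weighting: (B, n, d) -> (B, n, d)."""

    def __init__(self, d: int, activation: str, rng, name: str, dtype):
        self.W1 = Param(_glorot(rng, (d, d), dtype), f"{name}/W1")
        self.w = Param(_glorot(rng, (d,), dtype), f"{name}/w")
        self.activation = activation
        self._cache = None

    def params(self):
        return [self.W1, self.w]

    def forward(self, x, training):
        y, cache = _batched_reweight_forward(x, self.W1.value, self.w.value, self.activation)
        self._cache = cache
        return y

    def backward(self, g):
        dx, dW1, dw = _batched_reweight_backward(g, self._cache, self.W1.value, self.w.value, self.activation)
        self.W1.grad = dW1
        self.w.grad = dw
        return dx


class MultiHeadSelfAttentionLayer(_Layer):
    """k-head additive self-attention: project, re-weight per head, concat, mix."""

    def __init__(self, d: int, k: int, activation: str, rng, name: str, dtype):
        if d % k != 0:
            raise ConfigError(f"token dimension {d} not divisible by head count {k}")
        dk = d // k
        self.k = k
        self.dk = dk
        self.activation = activation
        self.Wx = [Param(_glorot(rng, (d, dk), dtype), f"{name}/head{h}/Wx") for h in range(k)]
        self.W1 = [Param(_glorot(rng, (dk, dk), dtype), f"{name}/head{h}/W1") for h in range(k)]
        self.w = [Param(_glorot(rng, (dk,), dtype), f"{name}/head{h}/w") for h in range(k)]
        self.WO = Param(_glorot(rng, (d, d), dtype), f"{name}/WO")
        self._cache = None

    def params(self):
        out = []
        for h in range(self.k):
            out += [self.Wx[h], self.W1[h], self.w[h]]
        out.append(self.WO)
        return out

    def forward(self, x, training):
        heads, caches = [], []
        for h in range(self.k):
            P = x @ self.Wx[h].value
            Y, cache = _batched_reweight_forward(P, self.W1[h].value, self.w[h].value, self.activation)
            heads.append(Y)
            caches.append(cache)
        C = np.concatenate(heads, axis=-1)
        self._cache = (x, C, caches)
        return C @ self.WO.value

    def backward(self, g):
        x, C, caches = self._cache
        self.WO.grad = np.einsum("bnd,bne->de", C, g)
        dC = g @ self.WO.value.T
        dx = np.zeros_like(x)
        for h in range(self.k):
            Gh = dC[..., h * self.dk : (h + 1) * self.dk]
            dP, dW1, dw = _batched_reweight_backward(
                Gh, caches[h], self.W1[h].value, self.w[h].value, self.activation
            )
            self.W1[h].grad = dW1
            self.w[h].grad = dw
            self.Wx[h].grad = np.einsum("bnd,bnk->dk", x, dP)
            dx = dx + dP @ self.Wx[h].value.T
        return dx


# ---------------------------------------------------------------------------
# Model specification, assembly, training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyperparameters.

    The detector consumes 2-s candidate windows (``input_length`` raw samples)
    either as the amplitude spectral density of the 80-500 Hz HFO band
    (``input_repr="spectrum"``, Welch estimate, phase- and position-invariant
    — the default) or as the band-passed waveform itself
    (``input_repr="waveform"`` with ``input_filter``).

    The front-end width (``hidden_units[0]``) is reshaped into
    ``token_count x token_dim`` tokens for the attention layers, so
    ``token_count * token_dim`` must equal it and ``token_dim`` must divide by
    ``heads``. Defaults: n = 8 tokens of d = 64, k = 8 heads, dropout 0.05,
    Adam at 1e-4, 10 epochs, batch 32.
    """

    variant: str = "msadr"
    input_length: int = 4800
    token_count: int = 8
    token_dim: int = 64
    heads: int = 8
    dropout_p: float = 0.05
    hidden_units: tuple[int, ...] = (512, 128, 32)
    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0
    attention_activation: str = "tanh"
    input_repr: str = "spectrum"  # "spectrum" | "waveform"
    spectrum_band: tuple[float, float] = (80.0, 500.0)
    welch_nperseg: int = 400
    input_filter: str | None = "screen"  # band preset for waveform mode
    sampling_rate_hz: float = 2400.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.input_length < 1:
            raise ConfigError("input_length must be positive")
        if len(self.hidden_units) != 3:
            raise ConfigError("hidden_units must list three widths (front end, head, bottleneck)")
        if self.token_count * self.token_dim != self.hidden_units[0]:
            raise ConfigError(
                f"token_count * token_dim = {self.token_count * self.token_dim} must equal "
                f"the front-end width {self.hidden_units[0]}"
            )
        if self.token_dim % self.heads != 0:
            raise ConfigError(f"token_dim {self.token_dim} not divisible by heads {self.heads}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")
        if self.input_repr not in ("spectrum", "waveform"):
            raise ConfigError(f"unknown input_repr {self.input_repr!r}")
        if self.input_repr == "spectrum":
            lo, hi = self.spectrum_band
            if not (0 < lo < hi <= self.sampling_rate_hz / 2):
                raise ConfigError("spectrum_band must lie within (0, Nyquist]")
            if not (2 <= self.welch_nperseg <= self.input_length):
                raise ConfigError("welch_nperseg must lie in [2, input_length]")
        resolve_filter(self.input_filter)

    @property
    def feature_dim(self) -> int:
        """Width of the network input after the representation transform."""
        if self.input_repr == "waveform":
            return self.input_length
        freqs = np.fft.rfftfreq(self.welch_nperseg, d=1.0 / self.sampling_rate_hz)
        lo, hi = self.spectrum_band
        return int(np.count_nonzero((freqs >= lo) & (freqs <= hi)))


class _Network:
    def __init__(self, layers: list[_Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        """Returns logits (pre-sigmoid), shape (B,)."""
        for layer in self.layers:
            x = layer.forward(x, training)
        return x[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        g = dlogit[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)


@dataclass
class TrainedModel:
    """A built (and possibly trained) detector with its normalization stats."""

    spec: ModelSpec
    network: _Network
    training_log: list[float] = field(default_factory=list)
    norm_mean: float = 0.0
    norm_std: float = 1.0
    trained: bool = False

    @property
    def parameters(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.network.params()}

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.network.params()))

    @property
    def has_attention(self) -> bool:
        return any(
            isinstance(layer, (SelfAttentionLayer, MultiHeadSelfAttentionLayer))
            for layer in self.network.layers
        )


@dataclass
class DetectionResult:
    """Per-segment predicted HFO probability — the unit of ranking."""

    segment_id: str
    patient_id: str
    channel_id: str
    start_s: float
    probability: float
    label: str = UNKNOWN


def build_model(spec: ModelSpec, dtype: str = "float32") -> TrainedModel:
    """Assemble an untrained network for the requested variant.

    raw/smo: dropout - dense(512) - dense(128) - norm - dense(32) - norm - sigmoid.
    Attention variants insert norm + tokenize + attention + flatten between the
    front end and the dense(128) head.
    """
    rng = derive_rng(spec.seed, "init")
    dt = np.dtype(dtype)
    h0, h1, h2 = spec.hidden_units
    n, d, k = spec.token_count, spec.token_dim, spec.heads
    act = spec.attention_activation

    layers: list[_Layer] = [Dropout(spec.dropout_p, derive_rng(spec.seed, "dropout"))]
    layers.append(Dense(spec.feature_dim, h0, "relu", rng, "front", dt))
    if spec.variant in ("raw", "smo"):
        head_in = h0
    else:
        layers.append(BatchNorm(h0, "front_norm", dt))
        layers.append(Reshape((n, d)))
        if spec.variant in ("attn_1", "msadr"):
            layers.append(MultiHeadSelfAttentionLayer(d, k, act, rng, "multihead", dt))
        if spec.variant in ("attn_2", "msadr"):
            layers.append(SelfAttentionLayer(d, act, rng, "selfattn", dt))
        layers.append(Flatten())
        head_in = n * d
    layers.append(Dense(head_in, h1, "relu", rng, "head1", dt))
    layers.append(BatchNorm(h1, "norm1", dt))
    layers.append(Dense(h1, h2, "relu", rng, "head2", dt))
    layers.append(BatchNorm(h2, "norm2", dt))
    layers.append(Dense(h2, 1, None, rng, "out", dt))  # logit; sigmoid applied in predict/loss
    return TrainedModel(spec=spec, network=_Network(layers))


class _Adam:
    def __init__(self, params: list[Param], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad.astype(p.value.dtype, copy=False)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.value -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def prepare_inputs(segments: list[LabeledSegment], spec: ModelSpec, dtype: str = "float32") -> np.ndarray:
    """Transform segment waveforms into the network's input representation.

    ``spectrum`` mode: square root of the Welch power spectral density (i.e.
    the amplitude spectral density) restricted to ``spectrum_band``.
    ``waveform`` mode: the band-passed (or raw) time series.
    """
    lengths = {s.n_samples for s in segments}
    if lengths != {spec.input_length}:
        raise ConfigError(f"segment lengths {sorted(lengths)} != spec.input_length {spec.input_length}")
    x = np.stack([s.samples for s in segments])
    if spec.input_repr == "spectrum":
        from scipy import signal as _signal

        freqs, pxx = _signal.welch(
            x, fs=spec.sampling_rate_hz, nperseg=spec.welch_nperseg,
            noverlap=spec.welch_nperseg // 2, axis=1,
        )
        lo, hi = spec.spectrum_band
        x = np.sqrt(pxx[:, (freqs >= lo) & (freqs <= hi)])
    else:
        fspec = resolve_filter(spec.input_filter)
        if fspec is not None:
            x = bandpass(x, fspec, spec.sampling_rate_hz)
    return np.ascontiguousarray(x, dtype=dtype)


def train(model: TrainedModel, segments: list[LabeledSegment], spec: ModelSpec | None = None) -> TrainedModel:
    """Mini-batch Adam training of the binary cross-entropy objective.

    Records the mean per-epoch loss in ``model.training_log``. Deterministic
    given the spec seed (initialization, dropout, and shuffling each use their
    own derived stream).
    """
    spec = spec or model.spec
    if len(segments) < 2:
        raise ConfigError("need at least two training segments")
    y = np.array([s.y for s in segments], dtype=float)
    if len(set(y.tolist())) < 2:
        raise ConfigError("training set must contain both classes")
    dtype = model.network.params()[0].value.dtype
    x = prepare_inputs(segments, spec, dtype=str(dtype))
    model.norm_mean = float(x.mean())
    model.norm_std = float(x.std()) or 1.0
    x = (x - dtype.type(model.norm_mean)) / dtype.type(model.norm_std)
    y = y.astype(dtype)

    opt = _Adam(model.network.params(), spec.learning_rate)
    shuffle_rng = derive_rng(spec.seed, "shuffle")
    n = x.shape[0]
    model.training_log = []
    for _epoch in range(spec.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.network.forward(xb, training=True)
            p = _sigmoid(logits)
            pc = np.clip(p, _EPS_PROB, 1.0 - _EPS_PROB)
            losses.append(float(np.mean(-yb * np.log(pc) - (1 - yb) * np.log(1 - pc))))
            dlogit = (p - yb) / len(idx)
            model.network.backward(dlogit.astype(dtype))
            opt.step()
        model.training_log.append(float(np.mean(losses)))
        _logger.info("epoch %d/%d mean_loss=%.4f", _epoch + 1, spec.epochs, model.training_log[-1])
    model.trained = True
    return model


def predict(model: TrainedModel, segments: list[LabeledSegment], batch_size: int = 256) -> list[DetectionResult]:
    """One HFO probability per segment, order-preserving.

    Inference disables dropout and uses frozen batch-norm running statistics,
    so results are independent of batch composition.
    """
    dtype = model.network.params()[0].value.dtype
    x = prepare_inputs(segments, model.spec, dtype=str(dtype))
    x = (x - dtype.type(model.norm_mean)) / dtype.type(model.norm_std)
    probs = np.empty(x.shape[0])
    for start in range(0, x.shape[0], batch_size):
        logits = model.network.forward(x[start : start + batch_size], training=False)
        probs[start : start + batch_size] = _sigmoid(logits.astype(float))
    return [
        DetectionResult(
            segment_id=s.segment_id,
            patient_id=s.patient_id,
            channel_id=s.channel_id,
            start_s=s.start_s,
            probability=float(p),
            label=s.label,
        )
        for s, p in zip(segments, probs)
    ]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path) -> None:
    """Serialize parameters, normalization stats and spec to one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as fh:
        spec_dict = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(model.spec).items()}
        fh.attrs["spec"] = json.dumps(spec_dict)
        fh.attrs["norm_mean"] = model.norm_mean
        fh.attrs["norm_std"] = model.norm_std
        fh.attrs["trained"] = model.trained
        fh.create_dataset("training_log", data=np.asarray(model.training_log, dtype=float))
        for p in model.network.params():
            fh.create_dataset(f"params/{p.name}", data=p.value)
        for layer in model.network.layers:
            if isinstance(layer, BatchNorm):
                base = layer.gamma.name.rsplit("/", 1)[0]
                fh.create_dataset(f"state/{base}/running_mean", data=layer.running_mean)
                fh.create_dataset(f"state/{base}/running_var", data=layer.running_var)


def load_model(path) -> TrainedModel:
    import h5py

    with h5py.File(path, "r") as fh:
        spec_dict = json.loads(fh.attrs["spec"])
        for key in ("hidden_units", "spectrum_band"):
            if key in spec_dict and isinstance(spec_dict[key], list):
                spec_dict[key] = tuple(spec_dict[key])
        spec = ModelSpec(**spec_dict)
        model = build_model(spec)
        for p in model.network.params():
            p.value = np.asarray(fh[f"params/{p.name}"])[()].astype(p.value.dtype)
        for layer in model.network.layers:
            if isinstance(layer, BatchNorm):
                base = layer.gamma.name.rsplit("/", 1)[0]
                layer.running_mean = np.asarray(fh[f"state/{base}/running_mean"])
                layer.running_var = np.asarray(fh[f"state/{base}/running_var"])
        model.norm_mean = float(fh.attrs["norm_mean"])
        model.norm_std = float(fh.attrs["norm_std"])
        model.trained = bool(fh.attrs["trained"])
        model.training_log = [float(v) for v in fh["training_log"]]
    return model
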