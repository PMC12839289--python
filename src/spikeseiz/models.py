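"""Spiking and convolutional architectures for windowed seizure detection.

Three classifiers share a probability-of-seizure interface:

* **HybridSNN** — per-timestep Linear(2C -> 192) + LayerNorm + leaky
  integrate-and-fire (LIF) with per-neuron learnable decay, dropout, and a
  Linear(192 -> 2) + output LIF whose membrane potential, averaged over the
  T = 128 timesteps, gives the class logits.  9,988 trainable parameters at
  the 46-input reference configuration.
* **ConvSNN** — a Conv1d stem (46 -> 96, k=3, no bias) + BatchNorm + GELU,
  residual depthwise-separable temporal blocks (k=9), 4-head temporal
  self-attention over the 96-dim embeddings with a post-residual LayerNorm,
  and the same spiking head at width 96 -> 192 -> 2.  80,932 parameters in
  the reference configuration.
* **CNNBaseline** — an offline 1-D CNN over 2560-sample (10 s)
  channel-averaged segments: three valid convolutions with max-pooling,
  global average pooling and two dense layers ending in one sigmoid unit.
  43,521 parameters.

LIF convention: ``U' = beta * U + I``; a unit spikes when ``U' >= theta``
(theta = 1) and is then reset by subtraction (default) or to zero.  Learnable
decays are stored as unconstrained logits squashed through a logistic so beta
stays in (0, 1).  Backpropagation through the spike threshold uses the
fast-sigmoid surrogate with slope 25.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._autograd import Parameter, Tensor, concat, no_grad, spike, SURROGATE_SLOPE

__all__ = [
    "LIFParams",
    "ModelSpec",
    "lif_step",
    "beta_from_tau",
    "surrogate_spike",
    "Module",
    "HybridSNN",
    "ConvSNN",
    "CNNBaseline",
    "build_hybrid_snn",
    "build_convsnn",
    "build_cnn_baseline",
    "build_model",
    "count_parameters",
    "describe_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Functional LIF primitives


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron parameters.

    ``beta`` is the per-step membrane decay; when built from a time constant,
    ``beta = exp(-dt / tau_mem)`` (tau ~ 20 ms at dt = 1/256 s gives ~0.8226).
    """

    beta: float = 0.97
    threshold: float = 1.0
    tau_mem: float | None = None
    dt: float | None = None
    reset_mode: str = "subtract"  # or "zero"

    @classmethod
    def from_tau(cls, dt: float, tau: float, threshold: float = 1.0,
                 reset_mode: str = "subtract") -> "LIFParams":
        return cls(beta=beta_from_tau(dt, tau), threshold=threshold,
                   tau_mem=tau, dt=dt, reset_mode=reset_mode)


def beta_from_tau(dt: float, tau: float) -> float:
    """Membrane decay per step for timestep dt and time constant tau."""
    if dt <= 0 or tau <= 0:
        raise ValueError("dt and tau must be positive")
    return math.exp(-dt / tau)


def lif_step(
    U: np.ndarray, I: np.ndarray, params: LIFParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LIF update: integrate, threshold (inclusive), reset.

    Returns ``(new_membrane, spikes)`` with ``U' = beta U + I`` and a spike
    wherever ``U' >= theta``; spiking units are reset by subtracting theta
    (``subtract``) or zeroed (``zero``).
    """
    U = np.asarray(U, dtype=np.float64)
    I = np.asarray(I, dtype=np.float64)
    u_new = params.beta * U + I
    s = (u_new >= params.threshold).astype(np.float64)
    if params.reset_mode == "subtract":
        u_new = u_new - params.threshold * s
    elif params.reset_mode == "zero":
        u_new = u_new * (1 - s)
    else:
        raise ValueError(f"unknown reset mode {params.reset_mode!r}")
    return u_new, s


def surrogate_spike(
    u_minus_theta: np.ndarray, slope: float = SURROGATE_SLOPE
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Heaviside (inclusive at 0) and fast-sigmoid backward slope.

    Returns ``(spikes, d_spike/d_u)`` where the surrogate derivative is
    ``slope / (1 + slope |u - theta|)^2``.
    """
    u = np.asarray(u_minus_theta, dtype=np.float64)
    fwd = (u >= 0).astype(np.float64)
    back = slope / (1 + slope * np.abs(u)) ** 2
    return fwd, back


# ---------------------------------------------------------------------------
# Module machinery


class Module:
    """Minimal layer container with named parameters and train/eval modes."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        yield m
                        yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield from m.named_parameters(f"{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match model parameters")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.array(state[k], dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, bias: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / math.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    """Normalization over the trailing feature axis with affine parameters."""

    def __init__(self, n_features: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class BatchNorm1d(Module):
    """Batch normalization over (batch, time) per channel for B x C x L input."""

    def __init__(self, n_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
        else:
            mu = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
            xc = x - mu
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * Tensor(mask)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = (c_in // groups) * k
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(c_out, c_in // groups, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, self.stride, self.padding, self.groups)


class LIFCell(Module):
    """LIF layer with a per-neuron learnable decay (logistic reparameterized).

    ``step`` integrates one timestep and returns ``(spikes, membrane)`` where
    the membrane is the post-integration, pre-reset potential (the quantity
    read out as a logit in the output layer).
    """

    def __init__(self, n_units: int, beta_init: float = 0.97,
                 threshold: float = 1.0, reset_mode: str = "subtract"):
        super().__init__()
        logit = math.log(beta_init / (1 - beta_init))
        self.beta_logit = Parameter(np.full(n_units, logit))
        self.threshold = threshold
        self.reset_mode = reset_mode
        self._state: Tensor | None = None

    def reset_state(self):
        self._state = None

    def step(self, I: Tensor) -> tuple[Tensor, Tensor]:
        beta = self.beta_logit.sigmoid()
        if self._state is None:
            u = I
        else:
            u = beta * self._state + I
        s = spike(u - self.threshold)
        # The reset uses the detached spike so gradients do not flow through
        # the reset path (which would contribute a (1 - theta*k) factor per
        # step near threshold and destabilize BPTT).
        s_const = Tensor(s.data)
        if self.reset_mode == "subtract":
            self._state = u - s_const * self.threshold
        else:
            self._state = u * (1.0 - s_const)
        return s, u


class MultiheadSelfAttention(Module):
    """Temporal self-attention over B x T x D sequences (post-norm residual)."""

    def __init__(self, d_model: int, n_heads: int, rng=None):
        super().__init__()
        assert d_model % n_heads == 0
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        rng = rng or np.random.default_rng(0)
        self.q = Linear(d_model, d_model, rng=rng)
        self.k = Linear(d_model, d_model, rng=rng)
        self.v = Linear(d_model, d_model, rng=rng)
        self.out = Linear(d_model, d_model, rng=rng)
        self.ln = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        H, Dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # B x T x D -> B*H x T x Dh
            return t.reshape(B, T, H, Dh).transpose(0, 2, 1, 3).reshape(B * H, T, Dh)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(Dh))
        smax = Tensor(scores.data.max(axis=-1, keepdims=True))  # detached shift
        e = (scores - smax).exp()
        attn = e / e.sum(axis=-1, keepdims=True)
        ctx = attn @ v
        ctx = ctx.reshape(B, H, T, Dh).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.ln(x + self.out(ctx))


# ---------------------------------------------------------------------------
# Architectures


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters; defaults reproduce the documented counts."""

    kind: str = "hybrid_snn"  # hybrid_snn | conv_snn | cnn_baseline
    in_channels: int = 46
    hidden: int = 192
    dropout: float = 0.20
    T: int = 128
    conv_stem_width: int = 96
    ds_kernel: int = 9
    n_heads: int = 4
    n_ds_blocks: int = 1
    ds_strides: tuple[int, ...] = (1,)
    n_classes: int = 2
    lif_beta_init: float = 0.97
    cnn_input_len: int = 2560
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        d["ds_strides"] = tuple(d.get("ds_strides", (1,)))
        return cls(**d)


class HybridSNN(Module):
    """Feed-forward spiking classifier over dual-coded 2C x T spike windows."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        if spec.kind != "hybrid_snn":
            raise ValueError("spec.kind must be 'hybrid_snn'")
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.fc1 = Linear(spec.in_channels, spec.hidden, rng=rng)
        self.ln = LayerNorm(spec.hidden)
        self.lif1 = LIFCell(spec.hidden, beta_init=spec.lif_beta_init)
        self.drop = Dropout(spec.dropout, rng=np.random.default_rng(spec.seed + 1))
        self.fc2 = Linear(spec.hidden, spec.n_classes, rng=rng)
        self.lif_out = LIFCell(spec.n_classes, beta_init=spec.lif_beta_init)

    def __call__(self, x: Tensor) -> Tensor:
        """x: B x C x T spike tensor -> B x n_classes time-averaged logits."""
        B, C, T = x.shape
        self.lif1.reset_state()
        self.lif_out.reset_state()
        acc = None
        for t in range(T):
            h = self.fc1(x[:, :, t])
            h = self.ln(h)
            s, _ = self.lif1.step(h)
            s = self.drop(s)
            o = self.fc2(s)
            _, mem = self.lif_out.step(o)
            acc = mem if acc is None else acc + mem
        return acc * (1.0 / T)


class DSBlock(Module):
    """Residual depthwise-separable temporal convolution block."""

    def __init__(self, width: int, k: int, stride: int, dropout: float, rng):
        super().__init__()
        pad = k // 2
        self.depthwise = Conv1d(width, width, k, stride=stride, padding=pad,
                                groups=width, bias=True, rng=rng)
        self.pointwise = Conv1d(width, width, 1, bias=True, rng=rng)
        self.bn = BatchNorm1d(width)
        self.drop = Dropout(dropout, rng=np.random.default_rng(12345))
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        y = self.pointwise(self.depthwise(x))
        y = self.drop(self.bn(y))
        res = x if self.stride == 1 else x[:, :, :: self.stride]
        if res.shape[-1] != y.shape[-1]:
            res = res[:, :, : y.shape[-1]]
        return y + res


class ConvSNN(Module):
    """Convolutional stem + temporal attention + spiking classification head."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        if spec.kind != "conv_snn":
            raise ValueError("spec.kind must be 'conv_snn'")
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        W = spec.conv_stem_width
        self.stem = Conv1d(spec.in_channels, W, 3, padding=1, bias=False, rng=rng)
        self.stem_bn = BatchNorm1d(W)
        strides = spec.ds_strides
        if len(strides) < spec.n_ds_blocks:
            strides = strides + (1,) * (spec.n_ds_blocks - len(strides))
        self.blocks = [
            DSBlock(W, spec.ds_kernel, strides[i], spec.dropout, rng)
            for i in range(spec.n_ds_blocks)
        ]
        self.attn = MultiheadSelfAttention(W, spec.n_heads, rng=rng)
        head_beta = beta_from_tau(1.0 / 256.0, 0.020)
        self.fc1 = Linear(W, spec.hidden, rng=rng)
        self.ln = LayerNorm(spec.hidden)
        self.lif1 = LIFCell(spec.hidden, beta_init=head_beta)
        self.drop = Dropout(spec.dropout, rng=np.random.default_rng(spec.seed + 1))
        self.fc2 = Linear(spec.hidden, spec.n_classes, rng=rng)
        self.lif_out = LIFCell(spec.n_classes, beta_init=head_beta)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.stem_bn(self.stem(x)).gelu()
        for blk in self.blocks:
            h = blk(h)
        h = h.transpose(0, 2, 1)  # B x T' x W
        h = self.attn(h)
        B, T, W = h.shape
        self.lif1.reset_state()
        self.lif_out.reset_state()
        acc = None
        for t in range(T):
            z = self.fc1(h[:, t, :])
            z = self.ln(z)
            s, _ = self.lif1.step(z)
            s = self.drop(s)
            o = self.fc2(s)
            _, mem = self.lif_out.step(o)
            acc = mem if acc is None else acc + mem
        return acc * (1.0 / T)


class CNNBaseline(Module):
    """Offline 1-D CNN over single-channel 2560-sample (10 s) segments.

    All convolutions are valid (no padding); the single input channel is the
    mean across EEG channels. Output is one pre-sigmoid logit.
    """

    def __init__(self, spec: ModelSpec):
        super().__init__()
        if spec.kind != "cnn_baseline":
            raise ValueError("spec.kind must be 'cnn_baseline'")
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.conv1 = Conv1d(1, 32, 5, bias=True, rng=rng)
        self.conv2 = Conv1d(32, 64, 5, bias=True, rng=rng)
        self.conv3 = Conv1d(64, 128, 3, bias=True, rng=rng)
        self.dense1 = Linear(128, 64, rng=rng)
        self.dense2 = Linear(64, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        """x: B x 1 x 2560 -> B x 1 logit."""
        h = self.conv1(x).relu().maxpool1d(2)
        h = self.conv2(h).relu().maxpool1d(2)
        h = self.conv3(h).relu()
        h = h.mean(axis=2)  # global average pooling -> B x 128
        h = self.dense1(h).relu()
        return self.dense2(h)

    def intermediate_lengths(self, n_in: int | None = None) -> list[int]:
        """Temporal lengths after each conv/pool stage (for a 2560-sample input)."""
        L = n_in if n_in is not None else self.spec.cnn_input_len
        out = []
        for k, pool in ((5, True), (5, True), (3, False)):
            L = L - (k - 1)
            out.append(L)
            if pool:
                L //= 2
                out.append(L)
        return out


def build_hybrid_snn(spec: ModelSpec | None = None) -> HybridSNN:
    return HybridSNN(spec or ModelSpec(kind="hybrid_snn"))


def build_convsnn(spec: ModelSpec | None = None) -> ConvSNN:
    return ConvSNN(spec or ModelSpec(kind="conv_snn"))


def build_cnn_baseline(spec: ModelSpec | None = None) -> CNNBaseline:
    return CNNBaseline(spec or ModelSpec(kind="cnn_baseline"))


def build_model(spec: ModelSpec) -> Module:
    builders = {
        "hybrid_snn": build_hybrid_snn,
        "conv_snn": build_convsnn,
        "cnn_baseline": build_cnn_baseline,
    }
    if spec.kind not in builders:
        raise ValueError(f"unknown model kind {spec.kind!r}")
    return builders[spec.kind](spec)


def count_parameters(module: Module) -> int:
    """Number of trainable scalars (learnable decays and affine norms included)."""
    return int(sum(p.data.size for p in module.parameters() if p.requires_grad))


def describe_parameters(model: Module) -> list[tuple[str, int]]:
    """Per-layer (name, trainable parameter count) summary table."""
    rows: list[tuple[str, int]] = []
    if isinstance(model, ConvSNN):
        rows.append(("Conv1D stem + BN + GELU", count_parameters(model.stem) + count_parameters(model.stem_bn)))
        for i, blk in enumerate(model.blocks, 1):
            rows.append((f"Residual DS-Conv Block {i} + BN + Dropout", count_parameters(blk)))
        rows.append(("Temporal MHSA + LN", count_parameters(model.attn)))
        rows.append(("FC + LN + LIF + Dropout", count_parameters(model.fc1) + count_parameters(model.ln) + count_parameters(model.lif1)))
        rows.append(("FC + LIF (output)", count_parameters(model.fc2) + count_parameters(model.lif_out)))
    elif isinstance(model, HybridSNN):
        rows.append(("Linear + LayerNorm + LIF + Dropout", count_parameters(model.fc1) + count_parameters(model.ln) + count_parameters(model.lif1)))
        rows.append(("Linear + LIF (output)", count_parameters(model.fc2) + count_parameters(model.lif_out)))
    elif isinstance(model, CNNBaseline):
        for name, mod in (("Conv1D (32 filters, kernel=5)", model.conv1),
                          ("Conv1D (64 filters, kernel=5)", model.conv2),
                          ("Conv1D (128 filters, kernel=3)", model.conv3),
                          ("Dense (64, ReLU)", model.dense1),
                          ("Dense (1, Sigmoid)", model.dense2)):
            rows.append((name, count_parameters(mod)))
    rows.append(("Total", count_parameters(model)))
    return rows


def predict_proba(model: Module, X: np.ndarray, temperature: float = 1.0,
                  batch_size: int = 256) -> np.ndarray:
    """Seizure probability per window (eval mode, no graph)."""
    was_training = model.training
    model.eval()
    out = []
    with no_grad():
        for i in range(0, X.shape[0], batch_size):
            logits = model(Tensor(X[i : i + batch_size])).data
            if logits.shape[1] == 1:  # sigmoid head (CNN baseline)
                p = 1.0 / (1.0 + np.exp(-logits[:, 0] / temperature))
            else:
                z = logits / temperature
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                p = e[:, 1] / e.sum(axis=1)
            out.append(p)
    if was_training:
        model.train()
    return np.concatenate(out)


def save_checkpoint(model: Module, spec: ModelSpec, path: str | Path) -> None:
    """Flat named-tensor archive plus the JSON-serialized spec."""
    arrays = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez_compressed(path, __spec__=spec.to_json(), **arrays)


def load_checkpoint(path: str | Path) -> tuple[Module, ModelSpec]:
    with np.load(path, allow_pickle=True) as z:
        spec = ModelSpec.from_json(str(z["__spec__"]))
        model = build_model(spec)
        state = {k.replace("/", "."): z[k] for k in z.files if k != "__spec__"}
    model.load_state_dict(state)
    return model, spec
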