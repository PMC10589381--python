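"""Neural-network layers on top of the autograd tensor.

Initialization draws from an explicit ``numpy.random.Generator`` so every
model build is reproducible from a single seed.  Parameters are float32.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, stack

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "MaxPool2d",
    "BatchNorm",
    "LayerNorm",
    "LSTM",
    "GRU",
    "TransformerEncoder",
]


class Module:
    """Minimal parameter container with train/eval mode and state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def add_param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        setattr(self, name, t)
        return t

    def add_buffer(self, name: str, data: np.ndarray) -> np.ndarray:
        arr = np.asarray(data, dtype=np.float32)
        self._buffers[name] = arr
        setattr(self, name, arr)
        return arr

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data.copy() for k, v in self._params.items()}
        out.update({prefix + k: v.copy() for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, t in self._params.items():
            t.data = np.asarray(state[prefix + k], dtype=np.float32)
        for k in list(self._buffers):
            arr = np.asarray(state[prefix + k], dtype=np.float32)
            self._buffers[k] = arr
            object.__setattr__(self, k, arr)
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.add_param("weight", _kaiming_uniform(rng, (in_features, out_features), in_features))
        self.add_param("bias", _kaiming_uniform(rng, (out_features,), in_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Valid (unpadded) 5x5-style convolution, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.add_param("weight", _kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.add_param("bias", _kaiming_uniform(rng, (out_ch,), fan_in))
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias)


class MaxPool2d(Module):
    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return x.max_pool2d(self.k)


class BatchNorm(Module):
    """Batch normalization over (N, F) or (N, C, H, W) inputs.

    eps 1e-5, running-stat momentum 0.1; batch statistics in training mode,
    running statistics in eval mode.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.add_param("gamma", np.ones(num_features))
        self.add_param("beta", np.zeros(num_features))
        self.add_buffer("running_mean", np.zeros(num_features))
        self.add_buffer("running_var", np.ones(num_features))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            axes, shape = (0,), (1, -1)
        elif x.ndim == 4:
            axes, shape = (0, 2, 3), (1, -1, 1, 1)
        else:
            raise ValueError(f"BatchNorm expects 2-D or 4-D input, got {x.ndim}-D")
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            n = x.data.size / self.gamma.data.size
            unbiased = var.data * (n / max(n - 1.0, 1.0))
            rm = (1 - m) * self._buffers["running_mean"] + m * mean.data.reshape(-1)
            rv = (1 - m) * self._buffers["running_var"] + m * unbiased.reshape(-1)
            self._buffers["running_mean"] = rm.astype(np.float32)
            self._buffers["running_var"] = rv.astype(np.float32)
            object.__setattr__(self, "running_mean", self._buffers["running_mean"])
            object.__setattr__(self, "running_var", self._buffers["running_var"])
        else:
            mean = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.add_param("gamma", np.ones(dim))
        self.add_param("beta", np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class _RecurrentBase(Module):
    n_gates: int

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        for layer in range(num_layers):
            d_in = input_size if layer == 0 else hidden_size
            g = self.n_gates * hidden_size
            self.add_param(f"w_ih{layer}", _kaiming_uniform(rng, (d_in, g), hidden_size))
            self.add_param(f"w_hh{layer}", _kaiming_uniform(rng, (hidden_size, g), hidden_size))
            self.add_param(f"b_ih{layer}", _kaiming_uniform(rng, (g,), hidden_size))
            self.add_param(f"b_hh{layer}", _kaiming_uniform(rng, (g,), hidden_size))


class LSTM(_RecurrentBase):
    """Stacked LSTM; input (B, T, D) -> output (B, T, H)."""

    n_gates = 4

    def forward(self, x: Tensor) -> Tensor:
        b, t = x.shape[0], x.shape[1]
        h_dim = self.hidden_size
        for layer in range(self.num_layers):
            w_ih = self._params[f"w_ih{layer}"]
            w_hh = self._params[f"w_hh{layer}"]
            bias = self._params[f"b_ih{layer}"] + self._params[f"b_hh{layer}"]
            h = Tensor(np.zeros((b, h_dim), dtype=np.float32))
            c = Tensor(np.zeros((b, h_dim), dtype=np.float32))
            outs = []
            for step in range(t):
                xt = x[:, step]
                gates = xt @ w_ih + h @ w_hh + bias
                i = gates[:, 0 * h_dim:1 * h_dim].sigmoid()
                f = gates[:, 1 * h_dim:2 * h_dim].sigmoid()
                g = gates[:, 2 * h_dim:3 * h_dim].tanh()
                o = gates[:, 3 * h_dim:4 * h_dim].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outs.append(h)
            x = stack(outs, axis=1)
        return x


class GRU(_RecurrentBase):
    """Stacked GRU; input (B, T, D) -> output (B, T, H)."""

    n_gates = 3

    def forward(self, x: Tensor) -> Tensor:
        b, t = x.shape[0], x.shape[1]
        h_dim = self.hidden_size
        for layer in range(self.num_layers):
            w_ih = self._params[f"w_ih{layer}"]
            w_hh = self._params[f"w_hh{layer}"]
            b_ih = self._params[f"b_ih{layer}"]
            b_hh = self._params[f"b_hh{layer}"]
            h = Tensor(np.zeros((b, h_dim), dtype=np.float32))
            outs = []
            for step in range(t):
                xt = x[:, step]
                gx = xt @ w_ih + b_ih
                gh = h @ w_hh + b_hh
                r = (gx[:, 0 * h_dim:1 * h_dim] + gh[:, 0 * h_dim:1 * h_dim]).sigmoid()
                z = (gx[:, 1 * h_dim:2 * h_dim] + gh[:, 1 * h_dim:2 * h_dim]).sigmoid()
                n = (gx[:, 2 * h_dim:3 * h_dim] + r * gh[:, 2 * h_dim:3 * h_dim]).tanh()
                h = (1.0 - z) * n + z * h
                outs.append(h)
            x = stack(outs, axis=1)
        return x


class _Attention(Module):
    def __init__(self, dim: int, heads: int, dim_head: int, rng: np.random.Generator):
        super().__init__()
        inner = heads * dim_head
        self.heads = heads
        self.dim_head = dim_head
        self.to_qkv = Linear(dim, 3 * inner, rng)
        self.to_out = Linear(inner, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        h, dh = self.heads, self.dim_head
        qkv = self.to_qkv(x)  # (B, T, 3*inner)
        qkv = qkv.reshape(b, t, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3, B, H, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, h * dh)
        return self.to_out(out)


class _FeedForward(Module):
    def __init__(self, dim: int, mlp_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, mlp_dim, rng)
        self.fc2 = Linear(mlp_dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).leaky_relu())


class TransformerEncoder(Module):
    """Pre-norm transformer encoder with learned positional embeddings.

    Day order carries the movement signal, so positions are embedded
    explicitly and added to the per-frame features before the blocks.
    """

    def __init__(self, dim: int, depth: int, heads: int, mlp_dim: int,
                 dim_head: int, seq_length: int, rng: np.random.Generator):
        super().__init__()
        self.add_param("pos_embedding", 0.02 * rng.standard_normal((1, seq_length, dim)))
        self.depth = depth
        for i in range(depth):
            setattr(self, f"norm_attn{i}", LayerNorm(dim))
            setattr(self, f"attn{i}", _Attention(dim, heads, dim_head, rng))
            setattr(self, f"norm_ff{i}", LayerNorm(dim))
            setattr(self, f"ff{i}", _FeedForward(dim, mlp_dim, rng))
        self.final_norm = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.pos_embedding
        for i in range(self.depth):
            x = x + self._modules[f"attn{i}"](self._modules[f"norm_attn{i}"](x))
            x = x + self._modules[f"ff{i}"](self._modules[f"norm_ff{i}"](x))
        return self.final_norm(x)
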