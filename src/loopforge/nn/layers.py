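"""Neural-network building blocks on top of the autograd engine.

Modules hold :class:`~loopforge.nn.autograd.Tensor` parameters, collect them
recursively, and carry a train/eval flag that controls dropout and batch-norm
statistics.  Initialisation draws from an explicit ``numpy.random.Generator``
so models are reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, gather

__all__ = [
    "Module",
    "ModuleList",
    "Linear",
    "Embedding",
    "Dropout",
    "BatchNorm",
    "LayerNorm",
    "GraphNorm",
    "relu",
    "leaky_relu",
    "sigmoid",
    "silu",
    "elu",
    "softmax",
    "safe_norm",
]


class Module:
    """Base class: parameter collection plus a propagating train/eval flag."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = value.astype(np.float64).copy()
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise KeyError(f"unexpected parameter {key}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")


class ModuleList(list):
    pass


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.weight = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_tokens: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 1.0, size=(n_tokens, d)), requires_grad=True)

    def __call__(self, tokens: np.ndarray) -> Tensor:
        return gather(self.weight, np.asarray(tokens, dtype=np.int64))


class Dropout(Module):
    def __init__(self, p: float = 0.0):
        super().__init__()
        self.p = float(p)
        self.rng = np.random.default_rng(0)

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class BatchNorm(Module):
    """1-D batch normalisation over the row axis with running statistics."""

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data[0]
            )
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class GraphNorm(Module):
    """Per-graph normalisation over all nodes, per channel, with a learnable
    mean scale.  Statistics are always computed from the current graph, so the
    layer is deterministic in both train and eval mode."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.alpha = Tensor(np.ones(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        centered = x - mu * self.alpha
        var = (centered**2).mean(axis=0, keepdims=True)
        return centered / ((var + self.eps) ** 0.5) * self.gamma + self.beta


# -- activations -------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    return x * Tensor((x.data > 0).astype(np.float64))


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = np.where(x.data > 0, 1.0, slope)
    return x * Tensor(mask)


def sigmoid(x: Tensor) -> Tensor:
    # tanh formulation: numerically stable for large |x|
    return (x * 0.5).tanh() * 0.5 + 0.5


def silu(x: Tensor) -> Tensor:
    return x * sigmoid(x)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x * Tensor((x.data > 0).astype(np.float64))
    neg_mask = Tensor((x.data <= 0).astype(np.float64))
    # clip the exponent argument for numerical safety; gradient unaffected on
    # the active branch
    neg = ((x * neg_mask).exp() - 1.0) * alpha * neg_mask
    return pos + neg


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def safe_norm(x: Tensor, axis: int = -1, keepdims: bool = False, eps: float = 1e-8) -> Tensor:
    """Euclidean norm with an epsilon inside the square root so the gradient
    is finite at zero vectors."""
    return ((x**2).sum(axis=axis, keepdims=keepdims) + eps**2).sqrt() - eps
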