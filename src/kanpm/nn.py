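"""Neural building blocks on top of the autodiff engine.

Modules track parameters and buffers recursively through attribute
introspection, expose ``state_dict``/``load_state_dict`` for checkpointing,
and switch between training and evaluation behaviour via ``train()``/``eval()``
(dropout and batch-norm statistics follow the mode).
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # ---- traversal -----------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if name.startswith("_") and name != "_buffers":
                continue
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = np.asarray(value)

    def named_buffers(self, prefix: str = ""):
        for name, val in self._buffers.items():
            yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    # ---- mode ----------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # ---- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for name, arr in state.items():
            if name.startswith("buffer:"):
                self._set_buffer(name[len("buffer:"):], arr)
            else:
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r}")
                if params[name].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {name!r}: "
                        f"{params[name].data.shape} vs {arr.shape}"
                    )
                params[name].data = arr.astype(params[name].data.dtype).copy()

    def _set_buffer(self, dotted: str, arr: np.ndarray):
        mod = self
        parts = dotted.split(".")
        i = 0
        while i < len(parts) - 1:
            attr = getattr(mod, parts[i], None)
            if isinstance(attr, Module):
                mod = attr
                i += 1
            elif isinstance(attr, (list, tuple)):
                mod = attr[int(parts[i + 1])]
                i += 2
            else:
                raise KeyError(f"unknown buffer {dotted!r}")
        mod._buffers[parts[-1]] = np.asarray(arr).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _kaiming_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming_uniform(rng, in_dim, (in_dim, out_dim)))
        self.bias = Parameter(_kaiming_uniform(rng, in_dim, (out_dim,))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = ad.add(out, self.bias)
        return out


class BatchNorm1d(Module):
    """Per-feature normalization over the leading (row) axis.

    Training uses batch statistics and updates running estimates; evaluation
    uses the running estimates, so eval-mode forwards are deterministic and
    independent of batch composition.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.register_buffer("running_mean", np.zeros(dim, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(dim, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = ad.tmean(x, axis=0, keepdims=True)
            var = ad.tmean(ad.power(ad.add(x, ad.mul(mu, -1.0)), 2.0),
                           axis=0, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel()
            ).astype(DTYPE)
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel()
            ).astype(DTYPE)
        else:
            mu = Tensor(self._buffers["running_mean"])
            var = Tensor(self._buffers["running_var"])
        xhat = ad.div(ad.add(x, ad.mul(mu, -1.0)),
                      ad.tsqrt(ad.add(var, self.eps)))
        return ad.add(ad.mul(xhat, self.gamma), self.beta)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = ad.tmean(x, axis=-1, keepdims=True)
        centered = ad.add(x, ad.mul(mu, -1.0))
        var = ad.tmean(ad.power(centered, 2.0), axis=-1, keepdims=True)
        xhat = ad.div(centered, ad.tsqrt(ad.add(var, self.eps)))
        return ad.add(ad.mul(xhat, self.gamma), self.beta)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        return ad.dropout(x, self.p, self.rng, self.training)


class Adam:
    """Adam optimizer (Kingma & Ba) with bias-corrected moments."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
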