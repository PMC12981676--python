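"""Kolmogorov-Arnold network regression head (with an MLP alternative).

A KAN layer replaces the fixed activations of a linear layer with learned
univariate functions on every edge: for input x ∈ R^in and output index q,

    out_q = Σ_p [ base_pq · SiLU(x̃_p) + Σ_k c_pqk · B_k(x̃_p) ]

where B_k are cubic B-spline basis functions on a uniform grid over [-1, 1]
and x̃ is the running min-max normalization of x into the grid domain
(monotonically expanded during training, frozen at evaluation; out-of-range
values are clamped so the compactly supported splines never see dead input).

``bspline_basis`` exposes the raw Cox-de Boor evaluation for analysis; the
network path uses the same recursion together with the analytic derivative
for backpropagation through the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .nn import DTYPE, Linear, Module, Parameter

__all__ = [
    "KanLayerParams",
    "uniform_grid",
    "bspline_basis",
    "KanLayer",
    "KanBlock",
    "MLPHead",
    "make_head",
]


def uniform_grid(grid_size: int = 5, order: int = 3,
                 lo: float = -1.0, hi: float = 1.0) -> np.ndarray:
    """Knot vector: ``grid_size`` intervals on [lo, hi], extended by
    ``order`` uniformly spaced knots on each side."""
    h = (hi - lo) / grid_size
    return np.arange(-order, grid_size + order + 1) * h + lo


@dataclass
class KanLayerParams:
    in_dim: int
    out_dim: int
    grid_size: int = 5
    spline_order: int = 3

    @property
    def n_basis(self) -> int:
        return self.grid_size + self.spline_order


def _basis_and_deriv(x: np.ndarray, knots: np.ndarray, order: int):
    """Cox-de Boor recursion: basis values and d/dx, vectorized over x.

    ``x`` may have any shape; the result appends a basis axis of length
    len(knots) - order - 1.  The right edge of the base domain is treated
    as closed so the domain maximum still lies in the last interval.
    """
    x = np.asarray(x)
    hi = knots[-(order + 1)]  # top of the base (unextended) domain
    xe = x[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        ind = (xe >= knots[:-1]) & (xe < knots[1:])
        # close the right edge of the base domain: x == hi belongs to the
        # interval ending at hi, not the (extended) one starting there
        at_hi = xe == hi
        closing = (knots[:-1] < hi) & (hi <= knots[1:])
        B = np.where(at_hi, closing, ind).astype(x.dtype)
        prev = B
        for d in range(1, order + 1):
            prev = B
            left = (xe - knots[:-(d + 1)]) / (knots[d:-1] - knots[:-(d + 1)])
            right = (knots[d + 1:] - xe) / (knots[d + 1:] - knots[1:-d])
            B = left * prev[..., :-1] + right * prev[..., 1:]
    if order == 0:
        dB = np.zeros_like(B)
    else:
        denom_l = knots[order:-1] - knots[:-(order + 1)]
        denom_r = knots[order + 1:] - knots[1:-order]
        dB = order * (prev[..., :-1] / denom_l - prev[..., 1:] / denom_r)
    return B, dB


def bspline_basis(x, grid: np.ndarray, order: int = 3) -> np.ndarray:
    """Evaluate all B-spline basis functions at ``x`` (Cox-de Boor).

    ``grid`` is the extended knot vector (see :func:`uniform_grid`); values
    outside the base domain are clamped onto it before evaluation.  Basis
    values are >= 0 and sum to 1 at interior points (partition of unity).
    """
    grid = np.asarray(grid, dtype=np.float64)
    if order < 1:
        raise ValueError("order must be >= 1")
    lo, hi = grid[order], grid[-(order + 1)]
    x = np.clip(np.asarray(x, dtype=np.float64), lo, hi)
    B, _ = _basis_and_deriv(x, grid, order)
    return B


def _bspline_tensor(x: Tensor, knots: np.ndarray, order: int) -> Tensor:
    """Autodiff node for the basis evaluation (analytic d/dx)."""
    B, dB = _basis_and_deriv(x.data, knots.astype(x.data.dtype), order)

    def back(g):
        ad._accum(x, (np.asarray(g) * dB).sum(axis=-1))

    return ad._make(B, (x,), back)


class _RunningMinMax(Module):
    """Per-feature running min/max mapped onto [-1, 1], expanded only while
    training and frozen at evaluation."""

    def __init__(self, dim: int):
        super().__init__()
        self.register_buffer("lo", -np.ones(dim, dtype=DTYPE))
        self.register_buffer("hi", np.ones(dim, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            self._buffers["lo"] = np.minimum(
                self._buffers["lo"], x.data.min(axis=0)).astype(DTYPE)
            self._buffers["hi"] = np.maximum(
                self._buffers["hi"], x.data.max(axis=0)).astype(DTYPE)
        lo, hi = self._buffers["lo"], self._buffers["hi"]
        scale = (2.0 / np.maximum(hi - lo, 1e-8)).astype(DTYPE)
        xn = ad.add(ad.mul(ad.add(x, Tensor(-lo)), Tensor(scale)), -1.0)
        return ad.clip(xn, -1.0, 1.0)


class KanLayer(Module):
    def __init__(self, params: KanLayerParams, rng: np.random.Generator):
        super().__init__()
        self.params = params
        self.knots = uniform_grid(params.grid_size, params.spline_order)
        if not np.all(np.diff(self.knots) > 0):
            raise ValueError("knot vector must be strictly increasing")
        K = params.n_basis
        self.norm = _RunningMinMax(params.in_dim)
        self.coef = Parameter(
            rng.standard_normal((params.in_dim * K, params.out_dim)) * 0.1
            / np.sqrt(params.in_dim))
        self.base = Parameter(
            rng.uniform(-1, 1, (params.in_dim, params.out_dim))
            / np.sqrt(params.in_dim))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.params.in_dim:
            raise ValueError(
                f"KAN layer expects width {self.params.in_dim}, got {x.shape[-1]}")
        xn = self.norm(x)
        B = _bspline_tensor(xn, self.knots, self.params.spline_order)
        Bflat = ad.reshape(B, (x.shape[0], -1))
        spline = ad.matmul(Bflat, self.coef)
        return ad.add(spline, ad.matmul(ad.silu(xn), self.base))


class KanBlock(Module):
    """Stacked KAN layers ending in a scalar prediction."""

    def __init__(self, widths, rng: np.random.Generator,
                 grid_size: int = 5, spline_order: int = 3):
        super().__init__()
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        self.widths = tuple(widths)
        self.layers = [
            KanLayer(KanLayerParams(widths[i], widths[i + 1],
                                    grid_size, spline_order), rng)
            for i in range(len(widths) - 1)
        ]

    def __call__(self, z: Tensor) -> Tensor:
        if z.shape[-1] != self.widths[0]:
            raise ValueError(
                f"head expects width {self.widths[0]}, got {z.shape[-1]}")
        h = z
        for layer in self.layers:
            h = layer(h)
        return ad.reshape(h, (z.shape[0],))


class MLPHead(Module):
    """Linear+ReLU stack with the same widths (the no-KAN ablation)."""

    def __init__(self, widths, rng: np.random.Generator):
        super().__init__()
        self.widths = tuple(widths)
        self.layers = [
            Linear(widths[i], widths[i + 1], rng)
            for i in range(len(widths) - 1)
        ]

    def __call__(self, z: Tensor) -> Tensor:
        if z.shape[-1] != self.widths[0]:
            raise ValueError(
                f"head expects width {self.widths[0]}, got {z.shape[-1]}")
        h = z
        for layer in self.layers[:-1]:
            h = ad.relu(layer(h))
        h = self.layers[-1](h)
        return ad.reshape(h, (z.shape[0],))


def make_head(z_dim: int, hidden, use_kan: bool, rng: np.random.Generator,
              grid_size: int = 5, spline_order: int = 3) -> Module:
    widths = [z_dim, *hidden, 1]
    if use_kan:
        return KanBlock(widths, rng, grid_size, spline_order)
    return MLPHead(widths, rng)
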