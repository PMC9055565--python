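"""Minimal reverse-mode automatic differentiation on numpy arrays.

The readout networks used in this package are stacks of 1x1 convolutions
(per-location linear maps), per-location channel normalization, softplus
nonlinearities, and two fixed-structure linear operators (Gaussian blur and
bilinear upsampling).  All of these have simple analytic vector-Jacobian
products, so a small tape-based engine over float64 numpy arrays is
sufficient and keeps gradients exact enough for finite-difference
verification.

Only the operations actually used by the model are provided.  Tensors are
float64 throughout; shapes follow numpy broadcasting for elementwise ops.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "concat_rows",
    "tile_cols",
    "matmul",
    "softplus",
    "logsumexp_rows",
    "gather_rows",
    "apply_rowcol",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._vjp = vjp  # callable grad_out -> tuple of parent grads (or None)

    # ---- structural -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        out = Tensor(
            self.data + other.data,
            parents=(self, other),
            vjp=lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(
            self.data * other.data,
            parents=(self, other),
            vjp=lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor(
            self.data**e,
            parents=(self,),
            vjp=lambda g: (g * e * self.data ** (e - 1.0),),
        )
        return out

    # ---- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(
            self.data.reshape(*shape),
            parents=(self,),
            vjp=lambda g: (g.reshape(self.data.shape),),
        )
        return out

    # ---- elementwise transcendental -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, parents=(self,), vjp=lambda g: (g * out_data,))

    def log(self):
        return Tensor(
            np.log(self.data), parents=(self,), vjp=lambda g: (g / self.data,)
        )

    # ---- autodiff -------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of a scalar (or given seed) into the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._vjp is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            parent_grads = t._vjp(g)
            for p, pg in zip(t._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def item(self):
        return float(self.data)


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


# ---- linear algebra ------------------------------------------------------
def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product; the workhorse behind every 1x1 convolution."""
    a, b = tensor(a), tensor(b)
    out = Tensor(
        a.data @ b.data,
        parents=(a, b),
        vjp=lambda g: (g @ b.data.T, a.data.T @ g),
    )
    return out


def concat_rows(parts) -> Tensor:
    """Concatenate (C_i, N) tensors along the channel axis."""
    parts = [tensor(p) for p in parts]
    sizes = [p.data.shape[0] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=0))

    return Tensor(
        np.concatenate([p.data for p in parts], axis=0),
        parents=tuple(parts),
        vjp=vjp,
    )


def tile_cols(t: Tensor, reps: int) -> Tensor:
    """Tile a (C, N) tensor to (C, reps*N); backward sums the copies."""
    t = tensor(t)
    n = t.data.shape[1]

    def vjp(g):
        return (g.reshape(g.shape[0], reps, n).sum(axis=1),)

    return Tensor(np.tile(t.data, (1, reps)), parents=(t,), vjp=vjp)


# ---- nonlinearity --------------------------------------------------------
def softplus(t: Tensor) -> Tensor:
    t = tensor(t)
    out_data = np.logaddexp(0.0, t.data)
    sig = 1.0 / (1.0 + np.exp(-t.data))
    return Tensor(out_data, parents=(t,), vjp=lambda g: (g * sig,))


def layer_norm(x: Tensor, scale: Tensor, shift: Tensor, eps: float = 1e-12) -> Tensor:
    """Per-location channel normalization of (C, N) with scale/shift (C, 1).

    Fused op: normalizes over axis 0 (channels) at every location, then
    applies the per-channel affine; single analytic vjp instead of a chain
    of elementwise nodes.
    """
    x, scale, shift = tensor(x), tensor(scale), tensor(shift)
    xd = x.data
    mu = xd.mean(axis=0, keepdims=True)
    centered = xd - mu
    var = np.mean(centered * centered, axis=0, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv
    out_data = scale.data * xhat + shift.data

    def vjp(g):
        dscale = (g * xhat).sum(axis=1, keepdims=True)
        dshift = g.sum(axis=1, keepdims=True)
        dxhat = g * scale.data
        dx = inv * (
            dxhat
            - dxhat.mean(axis=0, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=0, keepdims=True)
        )
        return dx, dscale, dshift

    return Tensor(out_data, parents=(x, scale, shift), vjp=vjp)


# ---- density-specific ops ------------------------------------------------
def logsumexp_rows(t: Tensor) -> Tensor:
    """Row-wise logsumexp of a (B, N) tensor -> (B,)."""
    t = tensor(t)
    m = t.data.max(axis=1, keepdims=True)
    s = np.exp(t.data - m).sum(axis=1, keepdims=True)
    out_data = (m + np.log(s)).ravel()
    softmax = np.exp(t.data - m) / s
    return Tensor(out_data, parents=(t,), vjp=lambda g: (g[:, None] * softmax,))


def gather_rows(t: Tensor, idx) -> Tensor:
    """Pick one entry per row of a (B, N) tensor -> (B,)."""
    t = tensor(t)
    idx = np.asarray(idx, dtype=np.intp)
    rows = np.arange(t.data.shape[0])

    def vjp(g):
        out = np.zeros_like(t.data)
        out[rows, idx] = g
        return (out,)

    return Tensor(t.data[rows, idx], parents=(t,), vjp=vjp)


def gather_cols(t: Tensor, idx) -> Tensor:
    """Pick entries idx from a single-row (1, N) tensor -> (len(idx),)."""
    t = tensor(t)
    idx = np.asarray(idx, dtype=np.intp)

    def vjp(g):
        out = np.zeros_like(t.data)
        np.add.at(out[0], idx, g)
        return (out,)

    return Tensor(t.data[0, idx], parents=(t,), vjp=vjp)


def apply_rowcol(t: Tensor, row_op: np.ndarray, col_op: np.ndarray) -> Tensor:
    """Apply fixed linear maps along the two spatial axes of (B, H, W).

    out[b] = row_op @ t[b] @ col_op.T — used for Gaussian blur and bilinear
    upsampling, whose 1-D operators are small dense matrices.
    """
    t = tensor(t)
    out_data = np.einsum("ih,bhw,jw->bij", row_op, t.data, col_op, optimize=True)

    def vjp(g):
        return (np.einsum("ih,bij,jw->bhw", row_op, g, col_op, optimize=True),)

    return Tensor(out_data, parents=(t,), vjp=vjp)
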