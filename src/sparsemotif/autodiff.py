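"""Minimal reverse-mode automatic differentiation on numpy arrays.

The unfolded network is a fixed computational graph built from a small set of
primitives: broadcasted arithmetic, elementwise nonlinearities, reductions,
slicing/concatenation, and six convolution/correlation kernels that move
between one-hot sequences, sequence-level codes, code images and image-level
codes.  A full deep-learning framework is unnecessary for this; a tape over
numpy keeps the dependency surface small and the semantics transparent.

Gradients of every primitive are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "exp",
    "sqrt",
    "concatenate",
    "conv_codes",
    "corr_seq",
    "zcorr_seq",
    "conv_image",
    "corr_image",
    "zcorr_image",
    "top_alpha_mask",
    "rc_flip",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the tape: an ndarray plus a backward closure."""

    # make numpy defer binary ops to our reflected dunders
    __array_ufunc__ = None
    __slots__ = ("data", "grad", "_backward", "_prev")

    def __init__(self, data, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._prev = _prev
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))
        a, b = self.data, other.data

        def bw(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))
        a, b = self.data, other.data

        def bw(g):
            return (_unbroadcast(g / b, a.shape),
                    _unbroadcast(-g * a / (b * b), b.shape))

        out._backward = bw
        return out

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor(self.data ** p, (self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.data.shape

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- indexing -------------------------------------------------------
    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))
        shape = self.data.shape

        def bw(g):
            full = np.zeros(shape)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bw
        return out

    # -- autodiff driver ------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        # iterative DFS: unfolded graphs easily exceed the recursion limit
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._prev, grads):
                p.grad = p.grad + g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------------
# elementwise / structural primitives
# ----------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))
    mask = x.data > 0

    def bw(g):
        return (g * mask,)

    out._backward = bw
    return out


def exp(x: Tensor) -> Tensor:
    out = Tensor(np.exp(x.data), (x,))
    out._backward = lambda g: (g * out.data,)
    return out


def sqrt(x: Tensor) -> Tensor:
    out = Tensor(np.sqrt(x.data), (x,))
    out._backward = lambda g: (g * 0.5 / out.data,)
    return out


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = bw
    return out


def top_alpha_mask(x: Tensor, mask: np.ndarray) -> Tensor:
    """Hard-sparsity projection with straight-through-on-support gradient.

    `mask` selects the entries kept by the top-alpha projection (computed
    outside the tape from x.data); the gradient flows only to kept entries.
    """
    out = Tensor(x.data * mask, (x,))
    out._backward = lambda g: (g * mask,)
    return out


def rc_flip(d: Tensor) -> Tensor:
    """Reverse complement of a stacked filter bank [M, 4, l].

    With rows ordered (A, C, G, T), complementation is a row reversal, so the
    reverse complement is a flip of both trailing axes.  Linear involution.
    """
    out = Tensor(d.data[:, ::-1, ::-1].copy(), (d,))
    out._backward = lambda g: (g[:, ::-1, ::-1].copy(),)
    return out


# ----------------------------------------------------------------------
# convolution/correlation kernels
#
# Shapes: S [N,4,L] one-hot batch; D [M,4,l] sequence filters;
#         X [N,P,M] codes (P = L-l+1); F [K,h,C] image filters (C = 2M);
#         Z [N,Q,K] image codes (Q = P-h+1); R [N,P,C] code images.
# The three kernels at each level are mutual vector-Jacobian products.
# ----------------------------------------------------------------------

def _np_conv_codes(X, D):
    ell = D.shape[2]
    Xp = np.pad(X, ((0, 0), (ell - 1, ell - 1), (0, 0)))
    W = sliding_window_view(Xp, ell, axis=1)          # [N, L, M, l]
    return np.einsum("nlmj,mbj->nbl", W, D[:, :, ::-1], optimize=True)


def _np_corr_seq(S, D):
    ell = D.shape[2]
    W = sliding_window_view(S, ell, axis=2)           # [N, 4, P, l]
    return np.einsum("nbpj,mbj->npm", W, D, optimize=True)


def _np_zcorr_seq(X, S):
    P = X.shape[1]
    ell = S.shape[2] - P + 1
    W = sliding_window_view(S, ell, axis=2)           # [N, 4, P, l]
    return np.einsum("npm,nbpj->mbj", X, W, optimize=True)


def _np_conv_image(Z, F):
    h = F.shape[1]
    Zp = np.pad(Z, ((0, 0), (h - 1, h - 1), (0, 0)))
    W = sliding_window_view(Zp, h, axis=1)            # [N, P, K, h]
    return np.einsum("npkj,kjc->npc", W, F[:, ::-1, :], optimize=True)


def _np_corr_image(R, F):
    h = F.shape[1]
    W = sliding_window_view(R, h, axis=1)             # [N, Q, C, h]
    return np.einsum("nqcj,kjc->nqk", W, F, optimize=True)


def _np_zcorr_image(Z, R):
    Q = Z.shape[1]
    h = R.shape[1] - Q + 1
    W = sliding_window_view(R, h, axis=1)             # [N, Q, C, h]
    return np.einsum("nqk,nqcj->kjc", Z, W, optimize=True)


def conv_codes(X: Tensor, D: Tensor) -> Tensor:
    """Sum of filter placements: out[n,b,c] = sum_{m,j} X[n,c-j,m] D[m,b,j]."""
    out = Tensor(_np_conv_codes(X.data, D.data), (X, D))

    def bw(g):
        return (_np_corr_seq(g, D.data), _np_zcorr_seq(X.data, g))

    out._backward = bw
    return out


def corr_seq(S: Tensor, D: Tensor) -> Tensor:
    """Valid cross-correlation: out[n,p,m] = sum_{b,j} S[n,b,p+j] D[m,b,j]."""
    out = Tensor(_np_corr_seq(S.data, D.data), (S, D))

    def bw(g):
        return (_np_conv_codes(g, D.data), _np_zcorr_seq(g, S.data))

    out._backward = bw
    return out


def zcorr_seq(X: Tensor, S: Tensor) -> Tensor:
    """Filter-shaped correlation: out[m,b,j] = sum_{n,p} X[n,p,m] S[n,b,p+j]."""
    out = Tensor(_np_zcorr_seq(X.data, S.data), (X, S))

    def bw(g):
        return (_np_corr_seq(S.data, g), _np_conv_codes(X.data, g))

    out._backward = bw
    return out


def conv_image(Z: Tensor, F: Tensor) -> Tensor:
    """out[n,p,c] = sum_{k,j} Z[n,p-j,k] F[k,j,c]."""
    out = Tensor(_np_conv_image(Z.data, F.data), (Z, F))

    def bw(g):
        return (_np_corr_image(g, F.data), _np_zcorr_image(Z.data, g))

    out._backward = bw
    return out


def corr_image(R: Tensor, F: Tensor) -> Tensor:
    """out[n,q,k] = sum_{j,c} R[n,q+j,c] F[k,j,c]."""
    out = Tensor(_np_corr_image(R.data, F.data), (R, F))

    def bw(g):
        return (_np_conv_image(g, F.data), _np_zcorr_image(g, R.data))

    out._backward = bw
    return out


def zcorr_image(Z: Tensor, R: Tensor) -> Tensor:
    """out[k,j,c] = sum_{n,q} Z[n,q,k] R[n,q+j,c]."""
    out = Tensor(_np_zcorr_image(Z.data, R.data), (Z, R))

    def bw(g):
        return (_np_corr_image(R.data, g), _np_conv_image(Z.data, g))

    out._backward = bw
    return out
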