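"""Backend-generic iterates of the alternating solver.

Every function here is written once against a tiny dispatch layer and runs
either on plain numpy arrays (the classical solver) or on autodiff Tensors
(the unfolded network).  This is deliberate: deep unfolding is a
parameterization of the classical iterates, not a new algorithm, so the two
paths must execute literally the same code.

Batch shapes (all sequences in a batch share a length L):
    S  [N, 4, L]   one-hot sequences
    D  [M, 4, l]   sequence filters (PFM columns)
    X  [N, P, M]   forward-strand codes, P = L - l + 1
    Y  [N, P, M]   reverse-complement-strand codes
    F  [K, h, 2M]  image filters
    Z  [N, Q, K]   image codes, Q = P - h + 1
    U  [N, P, 2M]  scaled duals of the code-phase ADMM split
    Th [N, P, 2M]  scaled duals of the filter-phase split

The image-matching target is beta * (X, Y) throughout: in the Z-step, in
both dual updates, in the F-step and in the loss; the code-step coupling is
the exact gradient of rho/2 ||L_m - beta x_m + Gamma_m||^2.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "B",
    "project_top_alpha",
    "top_alpha_batch",
    "code_phase_iter",
    "filter_phase_iter",
    "loss_terms",
]


def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


class B:
    """Dispatch: numpy semantics for ndarrays, tape semantics for Tensors."""

    @staticmethod
    def relu(x):
        return ad.relu(x) if _is_t(x) else np.maximum(x, 0.0)

    @staticmethod
    def exp(x):
        return ad.exp(x) if _is_t(x) else np.exp(x)

    @staticmethod
    def sqrt(x):
        return ad.sqrt(x) if _is_t(x) else np.sqrt(x)

    @staticmethod
    def concat(xs, axis):
        return (ad.concatenate(xs, axis=axis) if _is_t(*xs)
                else np.concatenate(xs, axis=axis))

    @staticmethod
    def rc(d):
        return ad.rc_flip(d) if _is_t(d) else d[:, ::-1, ::-1]

    @staticmethod
    def conv_codes(X, D):
        if _is_t(X, D):
            return ad.conv_codes(ad.as_tensor(X), ad.as_tensor(D))
        return ad._np_conv_codes(X, D)

    @staticmethod
    def corr_seq(S, D):
        if _is_t(S, D):
            return ad.corr_seq(ad.as_tensor(S), ad.as_tensor(D))
        return ad._np_corr_seq(S, D)

    @staticmethod
    def zcorr_seq(X, S):
        if _is_t(X, S):
            return ad.zcorr_seq(ad.as_tensor(X), ad.as_tensor(S))
        return ad._np_zcorr_seq(X, S)

    @staticmethod
    def conv_image(Z, F):
        if _is_t(Z, F):
            return ad.conv_image(ad.as_tensor(Z), ad.as_tensor(F))
        return ad._np_conv_image(Z, F)

    @staticmethod
    def corr_image(R, F):
        if _is_t(R, F):
            return ad.corr_image(ad.as_tensor(R), ad.as_tensor(F))
        return ad._np_corr_image(R, F)

    @staticmethod
    def zcorr_image(Z, R):
        if _is_t(Z, R):
            return ad.zcorr_image(ad.as_tensor(Z), ad.as_tensor(R))
        return ad._np_zcorr_image(Z, R)

    @staticmethod
    def data(x):
        return x.data if isinstance(x, Tensor) else x


# ----------------------------------------------------------------------
# hard sparsity
# ----------------------------------------------------------------------

def project_top_alpha(Z: np.ndarray, alpha: int) -> np.ndarray:
    """Keep the alpha largest-|.| entries of a single matrix, zero the rest.

    Ties are broken in favour of the smallest flat index.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    flat = np.abs(Z).ravel()
    if alpha == 0:
        return np.zeros_like(Z)
    if alpha >= flat.size:
        return Z.copy()
    # stable selection: sort by (-|value|, flat index)
    order = np.lexsort((np.arange(flat.size), -flat))
    keep = order[:alpha]
    mask = np.zeros(flat.size, dtype=bool)
    mask[keep] = True
    # never keep exact zeros
    mask &= flat > 0
    return (Z.ravel() * mask).reshape(Z.shape)


def _top_alpha_mask_batch(Zdata: np.ndarray, alpha: int) -> np.ndarray:
    """Per-sequence keep-mask for a [N, Q, K] stack."""
    N = Zdata.shape[0]
    mask = np.zeros_like(Zdata, dtype=bool)
    for n in range(N):
        flat = np.abs(Zdata[n]).ravel()
        if alpha >= flat.size:
            m = flat > 0
        else:
            order = np.lexsort((np.arange(flat.size), -flat))
            m = np.zeros(flat.size, dtype=bool)
            m[order[:alpha]] = True
            m &= flat > 0
        mask[n] = m.reshape(Zdata[n].shape)
    return mask


def top_alpha_batch(Z, alpha: int):
    """Batched projection; straight-through-on-support under autodiff."""
    if isinstance(Z, Tensor):
        mask = _top_alpha_mask_batch(Z.data, alpha)
        return ad.top_alpha_mask(Z, mask)
    mask = _top_alpha_mask_batch(Z, alpha)
    return Z * mask


# ----------------------------------------------------------------------
# one ADMM iteration of the code phase (filters fixed)
# ----------------------------------------------------------------------

def code_phase_iter(X, Y, Z, U, D, S, F, lam, rho, eta, gamma,
                    alpha, beta, n_sweeps=3):
    """ISTA sweeps for (X, Y), projected Z-step, scaled dual step.

    Each sweep takes a simultaneous non-negative soft-threshold step for all
    filters and both strands against the shared residual
    delta = sum_h d_h * x_h + rc(d_h) * y_h - s evaluated at the sweep's
    entry codes.  The image coupling (through F*z and the duals U) uses the
    previous iterate of Z, per the ADMM splitting.
    """
    M = B.data(D).shape[0]
    Drc = B.rc(D)
    FZ = B.conv_image(Z, F)  # fixed within the sweeps (previous-iterate Z)

    for _ in range(n_sweeps):
        delta = B.conv_codes(X, D) + B.conv_codes(Y, Drc) - S
        gx = B.corr_seq(delta, D) + (rho * beta) * (
            beta * X - FZ[:, :, :M] - U[:, :, :M])
        gy = B.corr_seq(delta, Drc) + (rho * beta) * (
            beta * Y - FZ[:, :, M:] - U[:, :, M:])
        X = B.relu(X - eta * gx - lam * eta)
        Y = B.relu(Y - eta * gy - lam * eta)

    C = beta * B.concat([X, Y], 2)

    # projected gradient step on the quadratic penalty, then hard sparsity
    R = B.conv_image(Z, F) - C + U
    Gz = rho * B.corr_image(R, F)
    Z = top_alpha_batch(Z - gamma * Gz, alpha)

    # scaled dual update with the new iterates
    U = U + B.conv_image(Z, F) - C
    return X, Y, Z, U


# ----------------------------------------------------------------------
# one iteration of the filter phase (codes fixed)
# ----------------------------------------------------------------------

def filter_phase_iter(X, Y, Z, Theta, D, S, F, mu, tau, pi, omega, beta,
                      eps=1e-12):
    """Mirror-descent step for the PFM filters, ISTA step for image filters.

    The PFM update multiplies by exp(-pi * grad) and renormalizes each
    column, which keeps every column strictly inside the simplex.  The image
    filter update is a non-negative soft-threshold followed by Frobenius
    normalization (guarded against all-zero filters).
    """
    N = B.data(S).shape[0]
    Drc = B.rc(D)
    recon = B.conv_codes(X, D) + B.conv_codes(Y, Drc)
    delta = recon - S

    # gradient of the data term w.r.t. D, including the strand-chain term;
    # averaged over the batch so step sizes are batch-size invariant
    gD = (B.zcorr_seq(X, delta) + B.rc(B.zcorr_seq(Y, delta))) * (1.0 / N)
    Dn = D * B.exp(-pi * gD)
    D_new = Dn / Dn.sum(axis=1, keepdims=True)

    C = beta * B.concat([X, Y], 2)
    Rp = B.conv_image(Z, F) - C + Theta
    gF = (tau / N) * B.zcorr_image(Z, Rp)
    F_thr = B.relu(F - omega * gF - mu * omega)
    sq = (F_thr * F_thr).sum(axis=1, keepdims=True).sum(axis=2, keepdims=True)
    norm = B.sqrt(sq + eps)
    F_new = F_thr / norm

    Theta = Theta + B.conv_image(Z, F_new) - C
    return D_new, F_new, Theta


def loss_terms(X, Y, Z, D, S, F, beta):
    """The two-term training loss, averaged over the batch.

    (1/N) sum_n [ ||sum d*x + rc(d)*y - s||^2 + ||sum F*z - beta (X,Y)||_F^2 ]
    """
    N = B.data(S).shape[0]
    Drc = B.rc(D)
    r = B.conv_codes(X, D) + B.conv_codes(Y, Drc) - S
    seq_term = (r * r).sum()
    ri = B.conv_image(Z, F) - beta * B.concat([X, Y], 2)
    img_term = (ri * ri).sum()
    return seq_term * (1.0 / N), img_term * (1.0 / N)
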