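"""Deep unfolding of the alternating solver.

The forward pass executes 2*K1 layers interleaving the code-phase iterates
(ISTA sweeps for X/Y, projected top-alpha step for Z, dual step) followed by
2*K2 layers of filter iterates (mirror descent for the PFM filters, ISTA +
Frobenius normalization for the image filters).  Codes and all scaled duals
enter layer 1 at exactly zero.  The trainable parameters are the filters,
the sparsity parameters (lambda, mu), the shared ADMM penalty, and one step
size per layer; all scalars live in log-space so backpropagation cannot
drive them negative.

Training minimizes the mean of the two reconstruction residuals (sequence
level and image level) with the AdaBelief adaptive-moment update rule.
After every optimizer step the filter parameters are projected back to
their constraint sets (PFM column simplex; non-negative unit-Frobenius).

The hard top-alpha projection is handled straight-through-on-support:
gradients flow only through the entries the projection keeps.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import autodiff as ad
from . import layers
from .autodiff import Tensor
from .solvers import SolverConfig, init_filters
from .sparse_model import CodePair, ImageCode


@dataclasses.dataclass
class NetHyper:
    """Architecture and training hyperparameters.

    Defaults are the full-scale configuration: M=50 PFM filters of width 8,
    K=24 image filters of height 12, alpha=32 non-zeros per image code,
    beta=100 image scaling, K1=6 code layers, K2=3 filter layers, q=3
    components per configuration, AdaBelief with batches of 6.
    """

    M: int = 50
    filter_len: int = 8
    K: int = 24
    filter_height: int = 12
    alpha: int = 32
    beta: float = 100.0
    K1: int = 6
    K2: int = 3
    q: int = 3
    batch_size: int = 6
    epochs: int = 20
    learning_rate: float = 1e-3
    seed: int = 0
    tie_penalties: bool = True

    def solver_config(self) -> SolverConfig:
        return SolverConfig(
            M=self.M, filter_len=self.filter_len, K=self.K,
            filter_height=self.filter_height, alpha=self.alpha,
            beta=self.beta,
        )


def count_parameters(hyper: NetHyper) -> int:
    """Number of trainable scalars in the unfolded network.

    Filter weights M*4*l + K*h*2M, plus the scalar group {lambda, mu,
    penalty} — the ADMM penalty is shared between the code-phase and
    filter-phase splits (3 scalars; set ``tie_penalties=False`` for separate
    rho and tau, giving one more) — plus 2*K1 + 2*K2 per-layer step sizes.
    """
    n = hyper.M * 4 * hyper.filter_len
    n += hyper.K * hyper.filter_height * 2 * hyper.M
    n += 3 if hyper.tie_penalties else 4
    n += 2 * hyper.K1 + 2 * hyper.K2
    return n


@dataclasses.dataclass
class NetParams:
    """Trainable parameters; scalars stored in log-space."""

    seq_filters: np.ndarray       # [M, 4, l], kept on the column simplex
    image_filters: np.ndarray     # [K, h, 2M], non-negative, unit Frobenius
    log_lam: np.ndarray           # ()
    log_mu: np.ndarray            # ()
    log_rho: np.ndarray           # (); shared penalty when tied
    log_tau: np.ndarray | None    # () or None when tied to rho
    log_eta: np.ndarray           # [K1]
    log_gamma: np.ndarray         # [K1]
    log_pi: np.ndarray            # [K2]
    log_omega: np.ndarray         # [K2]

    def trainable(self) -> dict[str, np.ndarray]:
        out = {
            "seq_filters": self.seq_filters,
            "image_filters": self.image_filters,
            "log_lam": self.log_lam,
            "log_mu": self.log_mu,
            "log_rho": self.log_rho,
            "log_eta": self.log_eta,
            "log_gamma": self.log_gamma,
            "log_pi": self.log_pi,
            "log_omega": self.log_omega,
        }
        if self.log_tau is not None:
            out["log_tau"] = self.log_tau
        return out

    @property
    def lam(self) -> float:
        return float(np.exp(self.log_lam))

    @property
    def mu(self) -> float:
        return float(np.exp(self.log_mu))

    @property
    def rho(self) -> float:
        return float(np.exp(self.log_rho))

    @property
    def tau(self) -> float:
        src = self.log_rho if self.log_tau is None else self.log_tau
        return float(np.exp(src))

    def save(self, path, hyper: NetHyper):
        blob = {k: v for k, v in self.trainable().items()}
        blob["hyper"] = np.array(
            [hyper.M, hyper.filter_len, hyper.K, hyper.filter_height,
             hyper.alpha, hyper.beta, hyper.K1, hyper.K2, hyper.q,
             hyper.batch_size, hyper.epochs, hyper.learning_rate,
             hyper.seed, float(hyper.tie_penalties)])
        np.savez(path, **blob)

    @classmethod
    def load(cls, path) -> tuple["NetParams", NetHyper]:
        blob = np.load(path)
        h = blob["hyper"]
        hyper = NetHyper(
            M=int(h[0]), filter_len=int(h[1]), K=int(h[2]),
            filter_height=int(h[3]), alpha=int(h[4]), beta=float(h[5]),
            K1=int(h[6]), K2=int(h[7]), q=int(h[8]), batch_size=int(h[9]),
            epochs=int(h[10]), learning_rate=float(h[11]), seed=int(h[12]),
            tie_penalties=bool(h[13]))
        params = cls(
            seq_filters=blob["seq_filters"],
            image_filters=blob["image_filters"],
            log_lam=blob["log_lam"], log_mu=blob["log_mu"],
            log_rho=blob["log_rho"],
            log_tau=blob["log_tau"] if "log_tau" in blob.files else None,
            log_eta=blob["log_eta"], log_gamma=blob["log_gamma"],
            log_pi=blob["log_pi"], log_omega=blob["log_omega"])
        return params, hyper


def init_params(hyper: NetHyper, cfg: SolverConfig | None = None,
                seqs=None) -> NetParams:
    """Data-seeded (or random) filters; per-layer step sizes initialized to
    the classical relative defaults scaled by power-iteration Lipschitz
    estimates of the initial filter banks (the network then learns them)."""
    from .solvers import code_lipschitz, image_lipschitz

    cfg = cfg or SolverConfig()
    D, F = init_filters(hyper.solver_config(), hyper.seed, seqs=seqs)
    if seqs is not None and len(seqs) > 0:
        first = seqs[0].matrix if hasattr(seqs[0], "matrix") else seqs[0]
        P = first.shape[1] - hyper.filter_len + 1
    else:
        P = 64
    Q = max(P - hyper.filter_height + 1, 1)
    eta0 = cfg.eta / code_lipschitz(D, cfg.rho, hyper.beta, P)
    gamma0 = cfg.gamma / (cfg.rho * image_lipschitz(F, Q))
    omega0 = 20.0  # no codes exist yet to scale the F-step; learned anyway
    return NetParams(
        seq_filters=D,
        image_filters=F,
        log_lam=np.array(math.log(cfg.lam)),
        log_mu=np.array(math.log(cfg.mu)),
        log_rho=np.array(math.log(cfg.rho)),
        log_tau=None if hyper.tie_penalties else np.array(math.log(cfg.tau)),
        log_eta=np.full(hyper.K1, math.log(eta0)),
        log_gamma=np.full(hyper.K1, math.log(gamma0)),
        log_pi=np.full(hyper.K2, math.log(cfg.pi)),
        log_omega=np.full(hyper.K2, math.log(omega0)),
    )


class NonFiniteLoss(RuntimeError):
    pass


def forward(params: NetParams, S: np.ndarray, hyper: NetHyper,
            with_grad: bool = True):
    """Run the unfolded network on a stacked batch S [N, 4, L].

    Returns (leaves, outputs) where ``leaves`` maps parameter names to leaf
    Tensors (empty when with_grad=False) and ``outputs`` holds the final
    codes, filters and loss terms.
    """
    N, _, L = S.shape
    P = L - hyper.filter_len + 1
    Q = P - hyper.filter_height + 1
    if N == 0 or Q < 1:
        raise ValueError("empty batch or sequences too short")

    if with_grad:
        leaves = {k: Tensor(v) for k, v in params.trainable().items()}
        D = leaves["seq_filters"]
        F = leaves["image_filters"]
        lam = ad.exp(leaves["log_lam"])
        mu = ad.exp(leaves["log_mu"])
        rho = ad.exp(leaves["log_rho"])
        tau = ad.exp(leaves["log_tau"]) if "log_tau" in leaves else rho
        eta = ad.exp(leaves["log_eta"])
        gamma = ad.exp(leaves["log_gamma"])
        pi = ad.exp(leaves["log_pi"])
        omega = ad.exp(leaves["log_omega"])
        step = lambda v, t: v[t]
    else:
        leaves = {}
        D, F = params.seq_filters, params.image_filters
        lam, mu, rho, tau = params.lam, params.mu, params.rho, params.tau
        eta, gamma = np.exp(params.log_eta), np.exp(params.log_gamma)
        pi, omega = np.exp(params.log_pi), np.exp(params.log_omega)
        step = lambda v, t: float(v[t])

    X = np.zeros((N, P, hyper.M))
    Y = np.zeros((N, P, hyper.M))
    Z = np.zeros((N, Q, hyper.K))
    U = np.zeros((N, P, 2 * hyper.M))
    Theta = np.zeros((N, P, 2 * hyper.M))

    for t in range(hyper.K1):
        X, Y, Z, U = layers.code_phase_iter(
            X, Y, Z, U, D, S, F, lam, rho,
            step(eta, t), step(gamma, t), hyper.alpha, hyper.beta)

    D_out, F_out = D, F
    for t in range(hyper.K2):
        D_out, F_out, Theta = layers.filter_phase_iter(
            X, Y, Z, Theta, D_out, S, F_out, mu, tau,
            step(pi, t), step(omega, t), hyper.beta)

    seq_term, img_term = layers.loss_terms(X, Y, Z, D_out, S, F_out,
                                           hyper.beta)
    loss = seq_term + img_term

    loss_val = float(layers.B.data(loss))
    if not np.isfinite(loss_val):
        raise NonFiniteLoss("non-finite loss after the forward pass")

    outputs = {
        "X": layers.B.data(X), "Y": layers.B.data(Y),
        "Z": layers.B.data(Z),
        "D": layers.B.data(D_out), "F": layers.B.data(F_out),
        "loss": loss, "loss_value": loss_val,
        "seq_term": float(layers.B.data(seq_term)),
        "img_term": float(layers.B.data(img_term)),
    }
    return leaves, outputs


def loss_value(codes, filters, S: np.ndarray, beta: float) -> float:
    """Standalone evaluation of the two-term loss for given codes/filters."""
    X, Y, Z = codes
    D, F = filters
    seq_term, img_term = layers.loss_terms(X, Y, Z, D, S, F, beta)
    return float(seq_term + img_term)


class AdaBelief:
    """AdaBelief: adapts the step by the variance of the gradient around its
    running mean rather than the raw second moment."""

    def __init__(self, shapes: dict, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-16):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.s = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            diff = g - self.m[k]
            self.s[k] = self.b2 * self.s[k] + (1 - self.b2) * diff ** 2 \
                + self.eps
            mhat = self.m[k] / bc1
            shat = self.s[k] / bc2
            params[k] -= self.lr * mhat / (np.sqrt(shat) + self.eps)


def project_params(params: NetParams):
    """Return filters to their constraint sets after an optimizer step."""
    D = np.clip(params.seq_filters, 1e-8, None)
    params.seq_filters[:] = D / D.sum(axis=1, keepdims=True)
    F = np.clip(params.image_filters, 0.0, None)
    norms = np.sqrt((F ** 2).sum(axis=(1, 2), keepdims=True))
    dead = norms[:, 0, 0] <= 1e-12
    if np.any(dead):
        # a zero filter cannot be normalized; reset it to uniform mass
        F[dead] = 1.0
        norms = np.sqrt((F ** 2).sum(axis=(1, 2), keepdims=True))
    params.image_filters[:] = F / norms


def train(seqs, hyper: NetHyper, params: NetParams | None = None,
          verbose: bool = False):
    """Minibatch AdaBelief training; deterministic given ``hyper.seed``.

    ``seqs`` is a list of one-hot matrices; batches are drawn within
    equal-length groups (code-image shapes differ with L).  Returns the
    trained parameters and the per-epoch mean loss trace.
    """
    mats = [s.matrix if hasattr(s, "matrix") else np.asarray(s) for s in seqs]
    if len(mats) < hyper.batch_size:
        raise ValueError("need at least batch_size training sequences")
    if params is None:
        params = init_params(hyper, seqs=mats)
    groups: dict[int, list[int]] = {}
    for i, m in enumerate(mats):
        groups.setdefault(m.shape[1], []).append(i)
    stacks = {L: np.stack([mats[i] for i in idx]) for L, idx in groups.items()}

    store = params.trainable()
    opt = AdaBelief({k: v.shape for k, v in store.items()},
                    lr=hyper.learning_rate)
    rng = np.random.default_rng(hyper.seed)
    trace = []
    for epoch in range(hyper.epochs):
        epoch_losses = []
        batches = []
        for L, idx in groups.items():
            order = rng.permutation(len(idx))
            for lo in range(0, len(idx), hyper.batch_size):
                sel = order[lo:lo + hyper.batch_size]
                if len(sel) == 0:
                    continue
                batches.append((L, sel))
        for L, sel in batches:
            S = stacks[L][sel]
            leaves, out = forward(params, S, hyper, with_grad=True)
            out["loss"].backward()
            grads = {k: t.grad for k, t in leaves.items()}
            opt.step(store, grads)
            project_params(params)
            epoch_losses.append(out["loss_value"])
        trace.append(float(np.mean(epoch_losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{hyper.epochs}: loss {trace[-1]:.4f}")
    return params, trace


def infer_codes(params: NetParams, seqs, hyper: NetHyper):
    """Gradient-free forward pass; per-sequence codes in input order.

    The image code of every sequence has at most alpha non-zeros (the final
    layer ends with the hard projection).
    """
    mats = [s.matrix if hasattr(s, "matrix") else np.asarray(s) for s in seqs]
    groups: dict[int, list[int]] = {}
    for i, m in enumerate(mats):
        groups.setdefault(m.shape[1], []).append(i)
    codes = [None] * len(mats)
    for L, idx in groups.items():
        S = np.stack([mats[i] for i in idx])
        _, out = forward(params, S, hyper, with_grad=False)
        for j, i in enumerate(idx):
            codes[i] = (CodePair(out["X"][j], out["Y"][j]),
                        ImageCode(out["Z"][j], hyper.alpha))
    return codes
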