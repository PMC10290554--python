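"""Classical alternating minimization for the two-level representation.

With filters held fixed, the per-sequence codes are solved by ADMM: ISTA
sweeps with a non-negative soft threshold for the strand codes (X, Y), a
projected gradient step with hard top-alpha sparsity for the image code Z,
and a scaled dual update.  With codes held fixed, the PFM filters take
mirror-descent steps under the negative-entropy geometry of the column
simplex, and the image filters take non-negative ISTA steps followed by
Frobenius normalization.

Iteration budgets are fixed counts rather than tolerance-based stopping, so
the classical path mirrors the finite-depth unfolded network exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import layers
from .layers import B, project_top_alpha
from .sparse_model import CodePair, ImageCode, ImageFilterBank, SeqFilterBank


class SolverDivergence(RuntimeError):
    pass


def soft_threshold_nonneg(v: np.ndarray, t: float) -> np.ndarray:
    """Elementwise max(v - t, 0); the proximal map of t*||.||_1 over v >= 0."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    return np.maximum(np.asarray(v, dtype=float) - t, 0.0)


@dataclasses.dataclass
class SolverConfig:
    """Hyperparameters of the representation and of the classical fitter.

    Filter counts/shapes follow the model; penalties and step sizes are the
    serviceable fixed defaults of the classical path (the unfolded network
    learns its own).
    """

    M: int = 12
    filter_len: int = 8
    K: int = 8
    filter_height: int = 6
    alpha: int = 32
    beta: float = 100.0
    lam: float = 2.0
    mu: float = 1e-3
    rho: float = 1e-6
    tau: float = 1e-6
    eta: float = 0.9       # relative: fraction of 1/L of the code quadratic
    gamma: float = 0.9     # relative: fraction of 1/L of the Z quadratic
    pi: float = 20.0
    omega: float = 0.9     # relative: fraction of 1/L of the F quadratic
    n_sweeps: int = 3
    admm_iters: int = 10
    filter_iters: int = 3
    outer_rounds: int = 8
    reseed_every: int = 5       # 0 disables dead/duplicate-filter reseeding
    reseed_usage_frac: float = 0.02
    reseed_dup_corr: float = 0.98

    @property
    def span(self) -> int:
        """Nucleotides covered by one image component: h + l - 1."""
        return self.filter_height + self.filter_len - 1


@dataclasses.dataclass
class SolverState:
    """Batched codes and scaled duals for one equal-length group."""

    X: np.ndarray       # [N, P, M]
    Y: np.ndarray       # [N, P, M]
    Z: np.ndarray       # [N, Q, K]
    U: np.ndarray       # (Gamma, Upsilon) concatenated, [N, P, 2M]
    Theta: np.ndarray   # filter-phase duals, [N, P, 2M]


def init_state(n: int, L: int, cfg: SolverConfig) -> SolverState:
    """Codes and all duals start at zero."""
    P = L - cfg.filter_len + 1
    Q = P - cfg.filter_height + 1
    if Q < 1:
        raise ValueError(f"sequence length {L} too short for the filter sizes")
    return SolverState(
        X=np.zeros((n, P, cfg.M)),
        Y=np.zeros((n, P, cfg.M)),
        Z=np.zeros((n, Q, cfg.K)),
        U=np.zeros((n, P, 2 * cfg.M)),
        Theta=np.zeros((n, P, 2 * cfg.M)),
    )


def init_filters(cfg: SolverConfig, seed: int, seqs=None,
                 conservation: float = 0.7
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Initial filter banks.

    PFM filters are seeded from softened random length-l windows of the data
    when ``seqs`` (one-hot matrices) is given: the observed base gets
    ``conservation`` mass, the rest is spread uniformly.  Seeding from the
    data is what lets the sparsity threshold separate genuine repeated sites
    (which score high against their own seed) from background; with no data,
    columns are drawn from a symmetric Dirichlet(1).  Image filters are
    |N(0, 1)| entries, Frobenius-normalized.
    """
    rng = np.random.default_rng(seed)
    if seqs is not None and len(seqs) > 0:
        mats = [s.matrix if hasattr(s, "matrix") else np.asarray(s)
                for s in seqs]
        D = np.zeros((cfg.M, 4, cfg.filter_len))
        for m in range(cfg.M):
            s = mats[rng.integers(len(mats))]
            if s.shape[1] < cfg.filter_len:
                raise ValueError("sequence shorter than the filter width")
            # pick the peak-mass window of the chosen sequence; on one-hot
            # data all windows carry equal mass and the tiny random
            # tie-break reduces this to a uniform offset draw, while on
            # sparse real-valued data it aligns the seed with the covered
            # stretch instead of a shifted overlap
            from numpy.lib.stride_tricks import sliding_window_view

            mass = sliding_window_view(
                s, cfg.filter_len, axis=1).sum(axis=(0, 2))
            p = int(np.argmax(mass + rng.uniform(0.0, 1e-6, mass.size)))
            win = s[:, p:p + cfg.filter_len]
            D[m] = (1.0 - conservation) / 3.0 * (1.0 - win) + conservation * win
            D[m] /= D[m].sum(axis=0, keepdims=True)
    else:
        D = rng.dirichlet(np.ones(4), size=(cfg.M, cfg.filter_len))
        D = np.transpose(D, (0, 2, 1))  # [M, 4, l]
        D /= D.sum(axis=1, keepdims=True)
    F = np.abs(rng.standard_normal((cfg.K, cfg.filter_height, 2 * cfg.M)))
    F /= np.sqrt((F ** 2).sum(axis=(1, 2), keepdims=True))
    return D, F


def code_lipschitz(D: np.ndarray, rho: float, beta: float, P: int,
                   n_iter: int = 12, seed: int = 0) -> float:
    """Largest eigenvalue of the code-phase quadratic's Hessian.

    Power iteration on (X, Y) -> A^T A (X, Y) + rho*beta^2 (X, Y), where A
    stacks both strands of every filter at every offset.  Fixed step sizes
    are only stable below 2/L, and L grows with M and with filter
    sharpness, so the effective step is expressed as a fraction of 1/L.
    """
    rng = np.random.default_rng(seed)
    M = D.shape[0]
    Drc = D[:, ::-1, ::-1]
    X = rng.standard_normal((1, P, M))
    Y = rng.standard_normal((1, P, M))
    lam_est = 1.0
    for _ in range(n_iter):
        norm = np.sqrt((X ** 2).sum() + (Y ** 2).sum())
        X, Y = X / norm, Y / norm
        r = B.conv_codes(X, D) + B.conv_codes(Y, Drc)
        Xn = B.corr_seq(r, D) + rho * beta ** 2 * X
        Yn = B.corr_seq(r, Drc) + rho * beta ** 2 * Y
        lam_est = float((X * Xn).sum() + (Y * Yn).sum())
        X, Y = Xn, Yn
    return max(lam_est, 1e-12)


def image_lipschitz(F: np.ndarray, Q: int, n_iter: int = 12,
                    seed: int = 0) -> float:
    """Largest eigenvalue of Z -> corr(conv(Z, F), F) (unit-rho scale)."""
    rng = np.random.default_rng(seed)
    K = F.shape[0]
    Z = rng.standard_normal((1, Q, K))
    lam_est = 1.0
    for _ in range(n_iter):
        Z = Z / np.sqrt((Z ** 2).sum())
        Zn = B.corr_image(B.conv_image(Z, F), F)
        lam_est = float((Z * Zn).sum())
        Z = Zn
    return max(lam_est, 1e-12)


def filter_step_lipschitz(Z: np.ndarray, F_shape: tuple, n_iter: int = 8,
                          seed: int = 0) -> float:
    """Largest eigenvalue of F -> (1/N) sum_n z (x) (z * F)."""
    rng = np.random.default_rng(seed)
    N = Z.shape[0]
    F = rng.standard_normal(F_shape)
    lam_est = 1.0
    for _ in range(n_iter):
        norm = np.sqrt((F ** 2).sum())
        if norm <= 1e-30:       # zero operator (e.g. Z identically zero)
            return np.inf
        F = F / norm
        Fn = B.zcorr_image(Z, B.conv_image(Z, F)) / N
        lam_est = float((F * Fn).sum())
        F = Fn
    return max(lam_est, 1e-12)


def ista_code_step(X: np.ndarray, Y: np.ndarray, m: int, D: np.ndarray,
                   S: np.ndarray, FZ: np.ndarray, U: np.ndarray,
                   lam: float, rho: float, eta: float, beta: float = 1.0):
    """One ISTA update of (x_m, y_m) for every sequence, filters fixed.

    x_m <- S+_{lam*eta}( x_m - eta*(d_m (x) delta + rho*beta*(beta*x_m -
    L_m - Gamma_m)) ) and symmetrically for y_m with the reverse-complement
    filter and the right halves (R_m, Upsilon_m) of the image/duals.
    Returns the updated (x_m, y_m) columns, [N, P].
    """
    if eta <= 0:
        raise ValueError("step size eta must be > 0")
    M = D.shape[0]
    Drc = D[:, ::-1, ::-1]
    delta = B.conv_codes(X, D) + B.conv_codes(Y, Drc) - S
    Dm, Dm_rc = D[m:m + 1], Drc[m:m + 1]
    xm = X[:, :, m:m + 1]
    gx = B.corr_seq(delta, Dm) + rho * beta * (
        beta * xm - FZ[:, :, m:m + 1] - U[:, :, m:m + 1])
    xm_new = soft_threshold_nonneg(xm - eta * gx, lam * eta)
    delta = delta + B.conv_codes(xm_new - xm, Dm)
    ym = Y[:, :, m:m + 1]
    gy = B.corr_seq(delta, Dm_rc) + rho * beta * (
        beta * ym - FZ[:, :, M + m:M + m + 1] - U[:, :, M + m:M + m + 1])
    ym_new = soft_threshold_nonneg(ym - eta * gy, lam * eta)
    return xm_new[:, :, 0], ym_new[:, :, 0]


def _check_finite(arr, what: str, it: int):
    if not np.all(np.isfinite(arr)):
        raise SolverDivergence(f"non-finite values in {what} at iteration {it}")


def admm_solve_codes(state: SolverState, D: np.ndarray, F: np.ndarray,
                     S: np.ndarray, cfg: SolverConfig, iters: int,
                     record_residuals: bool = False):
    """Run `iters` ADMM iterations on the codes with filters fixed.

    Returns the state (updated in place) and, optionally, the trace of the
    primal residual ||sum_k F*z - beta (X, Y)||_F per iteration.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    P = state.X.shape[1]
    Q = state.Z.shape[1]
    eta_eff = cfg.eta / code_lipschitz(D, cfg.rho, cfg.beta, P)
    if cfg.rho > 0:
        gamma_eff = cfg.gamma / (cfg.rho * image_lipschitz(F, Q))
    else:
        gamma_eff = 0.0  # Z gradient vanishes with the penalty
    residuals = []
    for it in range(iters):
        with np.errstate(over="ignore", invalid="ignore"):
            out = layers.code_phase_iter(
                state.X, state.Y, state.Z, state.U, D, S, F,
                cfg.lam, cfg.rho, eta_eff, gamma_eff, cfg.alpha, cfg.beta,
                n_sweeps=cfg.n_sweeps,
            )
        state.X, state.Y, state.Z, state.U = out
        _check_finite(state.Z, "Z", it)
        _check_finite(state.X, "X", it)
        if record_residuals:
            C = cfg.beta * np.concatenate([state.X, state.Y], axis=2)
            r = layers.B.conv_image(state.Z, F) - C
            residuals.append(float(np.sqrt((r ** 2).sum())))
    return (state, residuals) if record_residuals else state


def mirror_descent_step_d(D: np.ndarray, X: np.ndarray, Y: np.ndarray,
                          S: np.ndarray, step: float) -> np.ndarray:
    """One entropic mirror-descent step on the PFM filters.

    d <- d * exp(-step * g), renormalized per column; g is the batch-mean
    gradient of the sequence reconstruction error, with the
    reverse-complement chain term included.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if np.any(D.sum(axis=1) <= 0):
        raise ValueError("zero column mass in a PFM filter")
    N = S.shape[0]
    Drc = D[:, ::-1, ::-1]
    delta = B.conv_codes(X, D) + B.conv_codes(Y, Drc) - S
    gD = (B.zcorr_seq(X, delta) + B.zcorr_seq(Y, delta)[:, ::-1, ::-1]) / N
    Dn = D * np.exp(-step * gD)
    return Dn / Dn.sum(axis=1, keepdims=True)


def ista_step_F(F: np.ndarray, Z: np.ndarray, X: np.ndarray, Y: np.ndarray,
                Theta: np.ndarray, cfg: SolverConfig, rng=None):
    """Non-negative ISTA step on image filters + Frobenius normalization.

    A filter zeroed out entirely by the threshold is redrawn at random
    (normalizing a zero matrix is undefined); pass ``rng`` to control the
    redraw.
    """
    N = Z.shape[0]
    omega_eff = cfg.omega / (cfg.tau * filter_step_lipschitz(Z, F.shape))
    C = cfg.beta * np.concatenate([X, Y], axis=2)
    Rp = B.conv_image(Z, F) - C + Theta
    gF = (cfg.tau / N) * B.zcorr_image(Z, Rp)
    F_thr = np.maximum(F - omega_eff * gF - cfg.mu * omega_eff, 0.0)
    norms = np.sqrt((F_thr ** 2).sum(axis=(1, 2), keepdims=True))
    dead = norms[:, 0, 0] <= 1e-12
    if np.any(dead):
        if rng is None:
            rng = np.random.default_rng(0)
        redraw = np.abs(rng.standard_normal(F_thr[dead].shape))
        F_thr[dead] = redraw
        norms = np.sqrt((F_thr ** 2).sum(axis=(1, 2), keepdims=True))
    return F_thr / norms


def fit_classical(seqs, cfg: SolverConfig, seed: int,
                  trace_objective: bool = False, init=None):
    """Alternate code ADMM and filter updates for ``cfg.outer_rounds``.

    ``seqs`` is a list of one-hot matrices (4 x L); sequences are grouped by
    length and solved batch-wise.  Returns the learned banks, per-sequence
    codes aligned with the input order, and (optionally) the objective trace.
    """
    mats = [s.matrix if hasattr(s, "matrix") else np.asarray(s) for s in seqs]
    if len(mats) == 0:
        raise ValueError("need at least one sequence")
    if init is not None:
        D, F = init[0].copy(), init[1].copy()
    else:
        D, F = init_filters(cfg, seed, seqs=mats)
    groups: dict[int, list[int]] = {}
    for i, m in enumerate(mats):
        groups.setdefault(m.shape[1], []).append(i)
    stacks = {L: np.stack([mats[i] for i in idx]) for L, idx in groups.items()}
    states = {L: init_state(len(idx), L, cfg) for L, idx in groups.items()}
    rng = np.random.default_rng(seed + 1)

    trace = []
    for rnd in range(cfg.outer_rounds):
        for L, S in stacks.items():
            # codes and duals restart at zero every round, mirroring the
            # zero-initialized forward pass of the unfolded architecture
            states[L] = init_state(S.shape[0], L, cfg)
            admm_solve_codes(states[L], D, F, S, cfg, cfg.admm_iters)
        omega_eff = {
            L: cfg.omega / (cfg.tau
                            * filter_step_lipschitz(states[L].Z, F.shape))
            for L in stacks
        }
        for _ in range(cfg.filter_iters):
            for L, S in stacks.items():
                st = states[L]
                X, Y = st.X, st.Y
                D_new, F_new, Theta = layers.filter_phase_iter(
                    X, Y, st.Z, st.Theta, D, S, F,
                    cfg.mu, cfg.tau, cfg.pi, omega_eff[L], cfg.beta,
                )
                st.Theta = Theta
                D, F = D_new, F_new
                # redraw any filter that the threshold zeroed out
                norms = np.sqrt((F ** 2).sum(axis=(1, 2)))
                dead = norms <= 1e-6
                if np.any(dead):
                    redraw = np.abs(rng.standard_normal(F[dead].shape))
                    redraw /= np.sqrt((redraw ** 2).sum(axis=(1, 2),
                                                        keepdims=True))
                    F[dead] = redraw
        if (cfg.reseed_every and rnd >= 1
                and rnd % cfg.reseed_every == 0
                and rnd < cfg.outer_rounds - cfg.reseed_every):
            D = _reseed_filters(D, states, stacks, cfg, rng)
        if trace_objective:
            trace.append(_objective_value(states, stacks, D, F, cfg))

    codes = _collect_codes(states, groups, cfg)
    banks = SeqFilterBank(D), ImageFilterBank(F)
    if trace_objective:
        return banks[0], banks[1], codes, trace
    return banks[0], banks[1], codes


def _reseed_filters(D, states, stacks, cfg, rng):
    """Replace unused or duplicate PFM filters with softened windows drawn
    from the worst-reconstructed stretches of the data.

    The standard dead-atom treatment in dictionary learning: a filter whose
    codes carry (almost) no mass, or which duplicates another filter,
    contributes nothing, while the largest residual windows mark structure
    the current bank cannot represent.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    usage = np.zeros(cfg.M)
    for L, S in stacks.items():
        st = states[L]
        usage += st.X.sum(axis=(0, 1)) + st.Y.sum(axis=(0, 1))
    dead = usage < cfg.reseed_usage_frac * max(usage.max(), 1e-12)
    # mark later duplicates of earlier filters (either strand)
    flat = D.reshape(cfg.M, -1)
    flat_rc = D[:, ::-1, ::-1].reshape(cfg.M, -1)
    for m in range(cfg.M):
        if dead[m]:
            continue
        for m2 in range(m + 1, cfg.M):
            if dead[m2]:
                continue
            c = max(np.corrcoef(flat[m], flat[m2])[0, 1],
                    np.corrcoef(flat[m], flat_rc[m2])[0, 1])
            if c > cfg.reseed_dup_corr:
                dead[m2] = True
    if not np.any(dead):
        return D
    # rank residual windows across the dataset
    candidates = []
    for L, S in stacks.items():
        st = states[L]
        r = B.conv_codes(st.X, D) + B.conv_codes(
            st.Y, D[:, ::-1, ::-1]) - S
        win = sliding_window_view(r ** 2, cfg.filter_len, axis=2)
        mass = win.sum(axis=(1, 3))                 # [N, P]
        order = np.dstack(np.unravel_index(
            np.argsort(mass, axis=None)[::-1], mass.shape))[0]
        for n_idx, p_idx in order[:4 * cfg.M]:
            candidates.append((float(mass[n_idx, p_idx]), L, int(n_idx),
                               int(p_idx)))
    candidates.sort(key=lambda t: -t[0])
    D = D.copy()
    ci = 0
    for m in np.nonzero(dead)[0]:
        if ci >= len(candidates):
            break
        _, L, n_idx, p_idx = candidates[ci]
        ci += 1
        win = stacks[L][n_idx][:, p_idx:p_idx + cfg.filter_len]
        new = 0.1 * (1.0 - win) + 0.7 * win
        D[m] = new / new.sum(axis=0, keepdims=True)
    return D


def _objective_value(states, stacks, D, F, cfg) -> dict:
    terms = {"data": 0.0, "image": 0.0, "code_l1": 0.0}
    for L, S in stacks.items():
        st = states[L]
        X, Y = st.X, st.Y
        r = B.conv_codes(X, D) + B.conv_codes(Y, D[:, ::-1, ::-1]) - S
        C = cfg.beta * np.concatenate([X, Y], axis=2)
        ri = B.conv_image(st.Z, F) - C
        terms["data"] += 0.5 * float((r ** 2).sum())
        terms["image"] += 0.5 * float((ri ** 2).sum())
        terms["code_l1"] += cfg.lam * float(X.sum() + Y.sum())
    terms["filter_l1"] = cfg.mu * float(np.abs(F).sum())
    terms["total"] = sum(terms.values())
    return terms


def _collect_codes(states, groups, cfg):
    """Per-sequence (CodePair, ImageCode) in the original input order."""
    n_seqs = sum(len(idx) for idx in groups.values())
    codes = [None] * n_seqs
    for L, idx in groups.items():
        st = states[L]
        X, Y = st.X, st.Y
        for j, i in enumerate(idx):
            codes[i] = (CodePair(X[j], Y[j]),
                        ImageCode(st.Z[j], cfg.alpha))
    return codes
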