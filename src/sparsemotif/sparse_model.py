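"""The two-level convolutional sparse representation of DNA.

Level one approximates each one-hot sequence s_n (4 x L) as a sum of
placements of M short PFM filters d_m on both strands:

    s_n ~ sum_m d_m * x_mn + rc(d_m) * y_mn

where x_mn, y_mn >= 0 are sparse codes over the P = L - l + 1 valid offsets.
The horizontal concatenation of all code columns forms the "code image"
(P x 2M).  Level two represents the (scaled) code image as a sum of
placements of K non-negative, unit-Frobenius image filters F_k (h x 2M)
indicated by an alpha-sparse code Z_n (Q x K, Q = P - h + 1):

    sum_k F_k * z_kn ~ beta * (X_n, Y_n)

The scaling beta keeps the image-matching residual on a numerically
comfortable scale.  Spatial arrangements of the non-zeros of Z are what the
enumeration stage turns into motifs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad

PFM_TOL = 1e-9
FRO_TOL = 1e-6


@dataclasses.dataclass
class Pfm:
    """4 x l position frequency matrix; every column on the simplex."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PFM must be 4 x l")
        if np.any(self.matrix < -PFM_TOL):
            raise ValueError("PFM entries must be non-negative")
        if np.any(np.abs(self.matrix.sum(axis=0) - 1.0) > 1e-6):
            raise ValueError("PFM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def reverse_complement_filter(p: Pfm) -> Pfm:
    """Column reverse + complement row swap (A<->T, C<->G); an involution.

    With rows ordered (A, C, G, T) the complement swap is a row reversal.
    """
    return Pfm(p.matrix[::-1, ::-1].copy())


@dataclasses.dataclass
class SeqFilterBank:
    """M sequence filters stored stacked as [M, 4, l]."""

    filters: np.ndarray

    def __post_init__(self):
        self.filters = np.asarray(self.filters, dtype=float)
        if self.filters.ndim != 3 or self.filters.shape[1] != 4:
            raise ValueError("filter bank must be [M, 4, l]")

    @property
    def M(self) -> int:
        return self.filters.shape[0]

    @property
    def width(self) -> int:
        return self.filters.shape[2]

    @property
    def rc_filters(self) -> np.ndarray:
        """Reverse-complement bank, recomputed so it can never go stale."""
        return self.filters[:, ::-1, ::-1]

    def pfm(self, m: int) -> Pfm:
        return Pfm(self.filters[m])

    def validate(self, tol: float = PFM_TOL):
        sums = self.filters.sum(axis=1)
        if np.any(self.filters < -tol) or np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("sequence filters left the PFM simplex")


@dataclasses.dataclass
class ImageFilterBank:
    """K image filters [K, h, 2M]; non-negative, unit Frobenius norm."""

    filters: np.ndarray

    def __post_init__(self):
        self.filters = np.asarray(self.filters, dtype=float)
        if self.filters.ndim != 3:
            raise ValueError("image filter bank must be [K, h, 2M]")

    @property
    def K(self) -> int:
        return self.filters.shape[0]

    @property
    def height(self) -> int:
        return self.filters.shape[1]

    def validate(self, tol: float = FRO_TOL):
        if np.any(self.filters < -tol):
            raise ValueError("image filters must be non-negative")
        norms = np.sqrt((self.filters ** 2).sum(axis=(1, 2)))
        live = norms > 1e-12
        if np.any(np.abs(norms[live] - 1.0) > tol):
            raise ValueError("image filters must have unit Frobenius norm")


@dataclasses.dataclass
class CodePair:
    """Forward (X) and reverse-complement (Y) codes of one sequence, P x M."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must share a shape")

    @property
    def P(self) -> int:
        return self.X.shape[0]

    @property
    def M(self) -> int:
        return self.X.shape[1]

    def image(self, beta: float = 1.0) -> np.ndarray:
        """The code image: columns 1..M from X, M+1..2M from Y, scaled."""
        return beta * np.concatenate([self.X, self.Y], axis=1)


@dataclasses.dataclass
class ImageCode:
    """Alpha-sparse code of the code image; Q x K."""

    Z: np.ndarray
    alpha: int

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.Z))

    def validate(self):
        if self.nnz > self.alpha:
            raise ValueError(f"Z has {self.nnz} non-zeros > alpha={self.alpha}")


# ----------------------------------------------------------------------
# reconstruction arithmetic (single-sequence views over the batched kernels)
# ----------------------------------------------------------------------

def reconstruct_sequence(bank: SeqFilterBank, codes: CodePair) -> np.ndarray:
    """Stamp every filter at every coded offset: the 4 x L approximation.

    The code indexes valid placement offsets 1..L-l+1; forward placements use
    d_m, reverse placements the reverse-complement filter.  Linear in codes.
    """
    if codes.M != bank.M:
        raise ValueError(f"codes have M={codes.M}, bank has M={bank.M}")
    X = codes.X[None]  # [1, P, M]
    Y = codes.Y[None]
    recon = ad._np_conv_codes(X, bank.filters) + ad._np_conv_codes(
        Y, np.ascontiguousarray(bank.rc_filters)
    )
    return recon[0]


def reconstruct_image(bank: ImageFilterBank, z: ImageCode) -> np.ndarray:
    """Stamp image filters at coded row offsets: the P x 2M approximation."""
    Q = z.Z.shape[0]
    if z.Z.shape[1] != bank.K:
        raise ValueError(f"Z has K={z.Z.shape[1]}, bank has K={bank.K}")
    return ad._np_conv_image(z.Z[None], bank.filters)[0]


def objective(
    bank: SeqFilterBank,
    ibank: ImageFilterBank,
    codes: list[CodePair],
    zs: list[ImageCode],
    seqs,
    lam: float,
    mu: float,
    beta: float,
) -> dict:
    """Labelled terms of the representation objective.

    Returns the sequence data term 1/2 sum ||recon - s||^2, the l1 penalties
    on codes and image filters, the image residual
    1/2 sum ||sum_k F_k * z - beta (X, Y)||_F^2, and their sum.
    """
    data = 0.0
    image = 0.0
    code_l1 = 0.0
    for cp, z, s in zip(codes, zs, seqs):
        mat = s.matrix if hasattr(s, "matrix") else np.asarray(s)
        r = reconstruct_sequence(bank, cp) - mat
        data += 0.5 * float((r ** 2).sum())
        ri = reconstruct_image(ibank, z) - cp.image(beta)
        image += 0.5 * float((ri ** 2).sum())
        code_l1 += float(cp.X.sum() + cp.Y.sum())
    filter_l1 = float(np.abs(ibank.filters).sum())
    terms = {
        "data": data,
        "image": image,
        "code_l1": lam * code_l1,
        "filter_l1": mu * filter_l1,
    }
    terms["total"] = sum(terms.values())
    return terms
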