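"""Planted-motif synthetic datasets with ground truth.

Emulates the statistical structure the model assumes: near-random background
(i.i.d. uniform or first-order Markov) carrying sparse, localized conserved
sites — a short primary site, a pair of boxes with a fixed or variable
spacer (gapped), or a primary site embedded in a longer conserved element.
It does not emulate ChIP-seq peak shape, positional soft-masking, or
repeat-family sequence models; recovery results on these fixtures show that
the pipeline works under its own assumptions, not that it handles every
artefact of real peak sets.

Ground truth is a BED-like table with 1-based closed coordinates and strand.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .seq_io import BASES, DnaRecord, reverse_complement
from .sparse_model import Pfm


@dataclasses.dataclass
class PlantSpec:
    """What to plant and at what rate.

    mode "primary" plants a site from the single PFM; "gapped" joins one
    site per PFM with uniform spacers from ``spacer_range`` (inclusive);
    "embedded" wraps the primary site in fixed flanks of ``flank_len``
    consensus nucleotides drawn once from the seed (a stand-in for a
    conserved long element).
    """

    pfms: list
    mode: str = "primary"
    spacer_range: tuple[int, int] = (0, 0)
    occurrence_rate: float = 1.0
    strand_prob: float = 0.0
    n_seqs: int = 100
    seq_len: int = 100
    markov_order: int = 0
    seed: int = 0
    flank_len: int = 10

    def __post_init__(self):
        if not 0.0 <= self.occurrence_rate <= 1.0:
            raise ValueError("occurrence_rate must be in [0, 1]")
        if not 0.0 <= self.strand_prob <= 1.0:
            raise ValueError("strand_prob must be in [0, 1]")
        if self.mode not in ("primary", "gapped", "embedded"):
            raise ValueError(f"unknown mode {self.mode!r}")


def sample_background(n: int, L: int, markov_order: int = 0,
                      seed: int = 0, transition: np.ndarray | None = None,
                      initial: np.ndarray | None = None) -> list[DnaRecord]:
    """i.i.d. uniform (order 0) or first-order Markov background strings."""
    if n < 1 or L < 1:
        raise ValueError("n and L must be >= 1")
    rng = np.random.default_rng(seed)
    if markov_order == 0:
        mats = rng.integers(0, 4, size=(n, L))
        return [DnaRecord(f"bg_{i}", "".join(BASES[b] for b in mats[i]))
                for i in range(n)]
    if markov_order != 1:
        raise ValueError("markov_order must be 0 or 1")
    if transition is None:
        transition = np.full((4, 4), 0.25)
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (4, 4) or np.any(transition < 0) or np.any(
            np.abs(transition.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition must be 4x4 row-stochastic")
    init = np.full(4, 0.25) if initial is None else np.asarray(initial)
    cum = np.cumsum(transition, axis=1)
    records = []
    for i in range(n):
        out = np.empty(L, dtype=np.int64)
        out[0] = rng.choice(4, p=init)
        u = rng.random(L - 1)
        for j in range(1, L):
            out[j] = np.searchsorted(cum[out[j - 1]], u[j - 1])
        records.append(DnaRecord(f"bg_{i}", "".join(BASES[b] for b in out)))
    return records


def _sample_site(pfm: Pfm, rng) -> str:
    cols = pfm.matrix.T
    return "".join(BASES[rng.choice(4, p=c / c.sum())] for c in cols)


def _uniform_string(length: int, rng) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


def plant(records: list[DnaRecord], spec: PlantSpec
          ) -> tuple[list[DnaRecord], pd.DataFrame]:
    """Overwrite a planted insert into each record with the given rate.

    Per record, with probability ``occurrence_rate``: sample one site per
    PFM, assemble the insert per mode, optionally reverse-complement the
    whole insert, and overwrite it at a uniform random valid offset.  At
    most one insert per record, so truth coordinates are unambiguous.

    Returns new records plus the truth table
    (id, start, end, strand, motif, spacer); coordinates 1-based closed.
    """
    rng = np.random.default_rng(spec.seed)
    pfms = [p if isinstance(p, Pfm) else Pfm(p) for p in spec.pfms]
    if spec.mode == "primary" and len(pfms) != 1:
        raise ValueError("primary mode takes exactly one PFM")
    # fixed consensus flanks for embedded mode, drawn once
    flank_rng = np.random.default_rng(spec.seed + 104729)
    left_flank = _uniform_string(spec.flank_len, flank_rng)
    right_flank = _uniform_string(spec.flank_len, flank_rng)

    out_records = []
    truth_rows = []
    for rec in records:
        if rng.random() >= spec.occurrence_rate:
            out_records.append(rec)
            continue
        sites = [_sample_site(p, rng) for p in pfms]
        spacers = []
        if spec.mode == "primary":
            insert = sites[0]
        elif spec.mode == "gapped":
            lo, hi = spec.spacer_range
            pieces = [sites[0]]
            for s in sites[1:]:
                gap = int(rng.integers(lo, hi + 1))
                spacers.append(gap)
                pieces.append(_uniform_string(gap, rng))
                pieces.append(s)
            insert = "".join(pieces)
        else:  # embedded
            insert = left_flank + sites[0] + right_flank
        if len(insert) > len(rec.seq):
            raise ValueError(
                f"insert of length {len(insert)} exceeds sequence length "
                f"{len(rec.seq)}")
        strand = "-" if rng.random() < spec.strand_prob else "+"
        if strand == "-":
            insert = reverse_complement(insert)
        start0 = int(rng.integers(0, len(rec.seq) - len(insert) + 1))
        seq = rec.seq[:start0] + insert + rec.seq[start0 + len(insert):]
        out_records.append(DnaRecord(rec.id, seq))
        truth_rows.append({
            "id": rec.id,
            "start": start0 + 1,
            "end": start0 + len(insert),
            "strand": strand,
            "motif": spec.mode,
            "spacer": ",".join(str(s) for s in spacers),
        })
    truth = pd.DataFrame(
        truth_rows,
        columns=["id", "start", "end", "strand", "motif", "spacer"])
    return out_records, truth


def planted_dataset(spec: PlantSpec) -> tuple[list[DnaRecord], pd.DataFrame]:
    """Background + plants in one call."""
    bg = sample_background(spec.n_seqs, spec.seq_len, spec.markov_order,
                           spec.seed)
    return plant(bg, spec)


def consensus_pfm(consensus: str, conservation: float = 1.0) -> Pfm:
    """PFM with ``conservation`` mass on the consensus base per column."""
    idx = {b: i for i, b in enumerate(BASES)}
    w = len(consensus)
    mat = np.full((4, w), (1.0 - conservation) / 3.0)
    for j, ch in enumerate(consensus):
        mat[:, j] = (1.0 - conservation) / 3.0
        mat[idx[ch], j] = conservation
    return Pfm(mat)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
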