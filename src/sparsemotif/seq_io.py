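"""DNA sequence I/O and elementary sequence operations.

All coordinates in this package are 1-based, closed intervals on the forward
strand.  Sequences are uppercase strings over {A, C, G, T, N}; IUPAC
ambiguity codes are accepted on input and collapse to N.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_IUPAC = set("ACGTNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised for files that are not well-formed DNA FASTA."""


@dataclasses.dataclass(frozen=True)
class DnaRecord:
    """A named DNA string over {A,C,G,T,N} (post-sanitation)."""

    id: str
    seq: str

    def __post_init__(self):
        if len(self.seq) == 0:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self):
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class OneHotSequence:
    """4 x L indicator matrix of a DNA string, rows ordered A, C, G, T.

    Ambiguous bases (N) encode as uniform 0.25 columns so every column sums
    to one and reconstruction losses stay well defined.
    """

    matrix: np.ndarray

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


def sanitize(seq: str, *, record_id: str = "?", line: int | None = None) -> str:
    """Uppercase and collapse IUPAC ambiguity codes to N; reject non-DNA."""
    up = seq.upper()
    out = []
    for ch in up:
        if ch in "ACGT":
            out.append(ch)
        elif ch in _IUPAC:
            out.append("N")
        else:
            where = f" (line {line})" if line is not None else ""
            raise FastaParseError(
                f"record {record_id!r}{where}: non-DNA character {ch!r}"
            )
    return "".join(out)


def read_fasta(path) -> list[DnaRecord]:
    """Read a DNA FASTA file into sanitized records, order preserved."""
    with open(path) as fh:
        first = None
        for lineno, raw in enumerate(fh, start=1):
            if raw.strip():
                first = (lineno, raw)
                break
        if first is None:
            raise FastaParseError(f"{path}: empty FASTA file")
        if not first[1].lstrip().startswith(">"):
            raise FastaParseError(
                f"{path}: line {first[0]}: expected '>' header, "
                f"got {first[1].strip()[:30]!r}"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(DnaRecord(rec.id, sanitize(str(rec.seq), record_id=rec.id)))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: Iterable[DnaRecord]) -> None:
    """Write records as FASTA wrapped at 80 columns."""
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(seq_records)


def one_hot(record: DnaRecord) -> OneHotSequence:
    """One-hot encode; N becomes a uniform 0.25 column."""
    L = len(record.seq)
    mat = np.zeros((4, L))
    for j, ch in enumerate(record.seq):
        i = _BASE_INDEX.get(ch)
        if i is None:
            mat[:, j] = 0.25
        else:
            mat[i, j] = 1.0
    return OneHotSequence(mat)


def decode_one_hot(mat: np.ndarray) -> str:
    """Column-argmax decoding (inverse of one_hot on unambiguous strings)."""
    return "".join(BASES[i] for i in np.argmax(mat, axis=0))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Shuffle preserving the exact dinucleotide multiset (Euler-tour method).

    Builds the multigraph whose edges are the observed 2-mers and samples a
    uniform-ish Eulerian path with the original first and last nucleotide
    fixed (Altschul-Erickson construction).  Deterministic given ``seed``.
    """
    if len(seq) < 2:
        raise ValueError("dinucleotide shuffle requires length >= 2")
    rng = np.random.default_rng(seed)
    chars = sorted(set(seq))
    edges: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    first, last = seq[0], seq[-1]

    def pick_last_edges():
        """Choose, for each non-terminal vertex, the edge to traverse last."""
        last_edge = {}
        for c in chars:
            if c == last or not edges[c]:
                continue
            last_edge[c] = edges[c][rng.integers(len(edges[c]))]
        return last_edge

    def connects_ok(last_edge):
        # following designated last-edges from every vertex must reach `last`
        for c in last_edge:
            cur, seen = c, set()
            while True:
                if cur == last:
                    break
                if cur in seen:
                    return False
                seen.add(cur)
                if cur not in last_edge:
                    return False
                cur = last_edge[cur]
        return True

    for _ in range(10000):
        last_edge = pick_last_edges()
        if connects_ok(last_edge):
            break
    else:  # pragma: no cover - cannot happen for valid Euler paths
        raise RuntimeError("failed to sample an Eulerian arborescence")

    # shuffle the remaining edges of each vertex, designated edge goes last
    ordered: dict[str, list[str]] = {}
    for c in chars:
        pool = list(edges[c])
        if c in last_edge:
            pool.remove(last_edge[c])
        rng.shuffle(pool)
        if c in last_edge:
            pool.append(last_edge[c])
        ordered[c] = pool

    out = [first]
    ptr = {c: 0 for c in chars}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def split_train_test(
    records: Sequence[DnaRecord], fraction: float, seed: int
) -> tuple[list[DnaRecord], list[DnaRecord]]:
    """Deterministic held-out split; |test| = round(fraction * N).

    The held-out fraction is excluded from model fitting and used only for
    enrichment testing.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_test = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test
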