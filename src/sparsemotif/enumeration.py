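"""Enumerating at the image level.

The non-zero components of each sequence's image code Z mark where image
filters stamp onto the code image.  Every q-subset of components, together
with the nucleotide distances between the regions they cover, is a
*configuration* — a hash-table key.  All DNA substrings covered by the same
configuration across the dataset have the same length and form a multiple
sequence alignment (MSA), the raw material of a motif.

A component at image row p (1-based) covers nucleotides [p, p + h + l - 2]:
the image filter spans h code rows and each code row indexes a placement of
an l-wide sequence filter.  The distance entries of a configuration are the
gaps in nucleotides between consecutive coverage intervals; overlapping
components yield negative distances and are retained (overlapping motifs are
real).
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import defaultdict

import numpy as np

from .seq_io import DnaRecord
from .sparse_model import ImageCode


@dataclasses.dataclass(frozen=True)
class Component:
    """One non-zero of Z: image-filter index k, image row p (both 1-based)."""

    k: int
    p: int
    value: float


@dataclasses.dataclass(frozen=True)
class Configuration:
    """q filter indices in spatial order + q-1 inter-component distances."""

    f: tuple
    d: tuple

    def __post_init__(self):
        if len(self.f) != len(self.d) + 1:
            raise ValueError("need exactly q-1 distances for q filters")

    def span(self, h: int, ell: int) -> int:
        """Total covered nucleotides: q*(h+l-1) + sum(d)."""
        unit = h + ell - 1
        return len(self.f) * unit + sum(self.d)

    def key(self) -> tuple:
        """Interleaved (f1, d1, f2, ..., d_{q-1}, fq) for ordering/output."""
        out = []
        for i, fi in enumerate(self.f):
            out.append(fi)
            if i < len(self.d):
                out.append(self.d[i])
        return tuple(out)


def nonzero_components(z: ImageCode) -> list[Component]:
    """All non-zeros of Z, sorted by row offset then filter index."""
    rows, cols = np.nonzero(z.Z)
    comps = [Component(k=int(k) + 1, p=int(p) + 1, value=float(z.Z[p, k]))
             for p, k in zip(rows, cols)]
    comps.sort(key=lambda c: (c.p, c.k))
    return comps


def enumerate_configurations(z: ImageCode, q: int, h: int, ell: int
                             ) -> list[tuple[Configuration, int]]:
    """Every q-subset of non-zero components as (configuration, nt start).

    Components are ordered by occurrence; distances are coverage gaps
    d_i = p_{i+1} - p_i - (h + l - 1).  Fewer than q components yields an
    empty list.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    comps = nonzero_components(z)
    if len(comps) < q:
        return []
    unit = h + ell - 1
    out = []
    for subset in itertools.combinations(comps, q):
        f = tuple(c.k for c in subset)
        d = tuple(subset[i + 1].p - subset[i].p - unit
                  for i in range(q - 1))
        out.append((Configuration(f, d), subset[0].p))
    return out


def _iter_key_tuples(Z: np.ndarray, q: int, unit: int):
    """Fast path over interleaved key tuples (f1, d1, ..., fq) + nt starts.

    Semantically identical to :func:`enumerate_configurations` (tested for
    equality) but avoids building Component/Configuration objects in the
    innermost loop.
    """
    rows, cols = np.nonzero(Z)
    order = np.lexsort((cols, rows))
    ps = rows[order] + 1
    ks = cols[order] + 1
    n = ps.size
    if n < q:
        return
    for subset in itertools.combinations(range(n), q):
        key = []
        for i, si in enumerate(subset):
            key.append(int(ks[si]))
            if i + 1 < q:
                key.append(int(ps[subset[i + 1]] - ps[si] - unit))
        yield tuple(key), int(ps[subset[0]])


def key_to_configuration(key: tuple) -> Configuration:
    return Configuration(tuple(key[::2]), tuple(key[1::2]))


def build_motif_table(codes, records, q: int, h: int, ell: int,
                      drop_n: bool = True) -> dict:
    """Hash table: interleaved key tuple -> list of (record id, start, sub).

    ``codes`` holds per-sequence (CodePair, ImageCode) aligned with
    ``records``.  Keys are the interleaved configuration tuples
    (f1, d1, ..., fq); use :func:`key_to_configuration` for the structured
    view.  Configurations whose nucleotide span overruns either sequence end
    are skipped; substrings containing N are dropped so MSA counts stay
    integral over {A,C,G,T}.
    """
    unit = h + ell - 1
    span_base = q * unit
    table: dict[tuple, list] = defaultdict(list)
    for (_, z), rec in zip(codes, records):
        L = len(rec.seq)
        seq = rec.seq
        for key, start in _iter_key_tuples(z.Z, q, unit):
            span = span_base + sum(key[1::2])
            end = start + span - 1
            if start < 1 or end > L:
                continue
            sub = seq[start - 1:end]
            if drop_n and "N" in sub:
                continue
            table[key].append((rec.id, start, sub))
    return dict(table)


def msa_to_counts(strings) -> np.ndarray:
    """4 x w base counts of an equal-length alignment (N rows excluded)."""
    strings = [s for s in strings]
    if not strings:
        raise ValueError("empty alignment")
    w = len(strings[0])
    if any(len(s) != w for s in strings):
        raise ValueError("alignment strings must have equal length")
    kept = [s for s in strings if "N" not in s]
    counts = np.zeros((4, w), dtype=np.int64)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for s in kept:
        for j, ch in enumerate(s):
            counts[idx[ch], j] += 1
    return counts


def _key_of(k) -> tuple:
    return k.key() if isinstance(k, Configuration) else k


def select_top(table: dict, J: int = 1000) -> list:
    """Up to J keys ranked by bucket occupancy, ties lexicographic on key.

    Accepts either interleaved tuple keys or Configuration keys.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    ranked = sorted(table.items(), key=lambda kv: (-len(kv[1]), _key_of(kv[0])))
    return ranked[:J]


def table_to_tsv(table: dict, path, h: int, ell: int) -> None:
    """Optional dump: key, bucket size, span, example substring."""
    with open(path, "w") as fh:
        fh.write("configuration\tbucket_size\tspan_nt\texample\n")
        for k, bucket in sorted(
                table.items(), key=lambda kv: (-len(kv[1]), _key_of(kv[0]))):
            config = k if isinstance(k, Configuration) \
                else key_to_configuration(k)
            key = ",".join(str(x) for x in config.key())
            example = bucket[0][2] if bucket else ""
            fh.write(f"{key}\t{len(bucket)}\t{config.span(h, ell)}\t"
                     f"{example}\n")
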