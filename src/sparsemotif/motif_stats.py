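"""Motif scoring and enrichment statistics.

An MSA's base counts become a log-odds PWM against a background model.  The
PWM's hit threshold is calibrated to a scanning p-value by exact dynamic
programming over the discretized score distribution under the background
(the pvalue-to-score construction).  Hits are counted on both strands of a
held-out test set and of a dinucleotide-preserving shuffled control, and
motif significance is a two-sided Fisher exact test on the resulting 2x2
hit/miss table.  Redundant PWMs are merged greedily by average
log-likelihood ratio (ALLR) column similarity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sp_stats

from .enumeration import msa_to_counts
from .seq_io import DnaRecord, dinucleotide_shuffle

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
UNIFORM_BG = np.full(4, 0.25)


@dataclasses.dataclass
class Pwm:
    """Count matrix + base-2 log-odds with background-distributed pseudocount.

    log_odds[b, j] = log2( (counts[b,j] + pc*bg[b]) / (n_j + pc) / bg[b] ).
    """

    counts: np.ndarray
    background: np.ndarray = dataclasses.field(
        default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 1.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be 4 x w")
        if np.any(self.counts.sum(axis=0) <= 0) and self.pseudocount <= 0:
            raise ValueError("zero total column with zero pseudocount")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        pc = self.pseudocount * self.background[:, None]
        num = self.counts + pc
        freqs = num / num.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore"):
            return np.log2(freqs / self.background[:, None])

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.counts[::-1, ::-1].copy(), self.background[::-1].copy(),
                   self.pseudocount)

    def probabilities(self) -> np.ndarray:
        pc = self.pseudocount * self.background[:, None]
        num = self.counts + pc
        return num / num.sum(axis=0, keepdims=True)


def pwm_from_counts(counts, background=None, pseudocount: float = 1.0) -> Pwm:
    bg = UNIFORM_BG.copy() if background is None else np.asarray(background,
                                                                 dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.all(counts.sum(axis=0) == 0):
        raise ValueError("all-zero count matrix")
    return Pwm(counts, bg, pseudocount)


# ----------------------------------------------------------------------
# p-value -> score threshold by exact DP on the discretized distribution
# ----------------------------------------------------------------------

def _int_scores(pwm: Pwm, granularity: float) -> np.ndarray:
    return np.round(pwm.log_odds / granularity).astype(np.int64)


def pvalue_to_score(pwm: Pwm, pvalue: float,
                    granularity: float = 1e-3) -> float:
    """Smallest discretized threshold t with P_bg(score >= t) <= pvalue.

    Scores are discretized to integer multiples of ``granularity``; the
    distribution of the word score under the (mononucleotide) background is
    the column-wise convolution of the per-column score distributions.
    """
    s = _int_scores(pwm, granularity)        # [4, w]
    t_int = _int_threshold(s, pwm.background, pvalue)
    return t_int * granularity


def score_threshold(scores: np.ndarray, background, pvalue: float,
                    granularity: float = 1e-3) -> float:
    """Threshold for an arbitrary 4 x w score matrix (same DP as above)."""
    s = np.round(np.asarray(scores, dtype=float) / granularity
                 ).astype(np.int64)
    return _int_threshold(s, np.asarray(background, dtype=float),
                          pvalue) * granularity


def _int_threshold(s: np.ndarray, bg: np.ndarray, pvalue: float) -> int:
    if not 0.0 < pvalue < 1.0:
        raise ValueError("pvalue must be in (0, 1)")
    width = s.shape[1]
    lo = int(s.min(axis=0).sum())
    hi = int(s.max(axis=0).sum())
    # dist[i] = P(score == lo + i)
    dist = np.zeros(hi - lo + 1)
    dist[0] = 1.0
    cur_lo = 0
    for j in range(width):
        col = s[:, j]
        cmin = int(col.min())
        # scores tracked relative to the accumulated minimum
        tmp = np.zeros(dist.size)
        for b in range(4):
            shift = int(col[b]) - cmin
            if bg[b] == 0:
                continue
            tmp[shift:] += bg[b] * dist[:dist.size - shift]
        dist = tmp
        cur_lo += cmin
    assert cur_lo == lo
    tail = np.cumsum(dist[::-1])[::-1]
    # the threshold is the smallest *achievable* score whose tail <= pvalue
    ok = np.nonzero((tail <= pvalue + 1e-15) & (dist > 0))[0]
    if ok.size == 0:
        return hi + 1  # no achievable score has tail <= pvalue
    return lo + int(ok[0])


# ----------------------------------------------------------------------
# scanning
# ----------------------------------------------------------------------

def _scan_scores(int_lo: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Window scores of an index-encoded sequence; N windows -> -inf."""
    w = int_lo.shape[1]
    L = idx.size
    if L < w:
        return np.zeros(0)
    from numpy.lib.stride_tricks import sliding_window_view
    wins = sliding_window_view(idx, w)                 # [P, w]
    padded = np.vstack([int_lo, np.full((1, w), np.iinfo(np.int64).min // 2)])
    scores = padded[wins, np.arange(w)].sum(axis=1)
    return scores


def scan_hits(pwm: Pwm, threshold: float, records,
              granularity: float = 1e-3):
    """Hit positions of a PWM over both strands of a record set.

    A window hits when its (discretized) score is >= the threshold; the
    reverse strand is scanned via the reverse-complement PWM on the forward
    text, and a placement counts once even if both strands pass.  Windows
    containing N never hit.  Returns the hit count (number of hit
    placements) and their 1-based window start offsets.
    """
    t_int = int(round(threshold / granularity))
    s_f = _int_scores(pwm, granularity)
    s_r = _int_scores(pwm.reverse_complement(), granularity)
    n_hits = 0
    positions = []
    for rec in records:
        idx = np.fromiter((_BASE_IDX[c] for c in rec.seq), dtype=np.int64,
                          count=len(rec.seq))
        sc_f = _scan_scores(s_f, idx)
        sc_r = _scan_scores(s_r, idx)
        hit = (sc_f >= t_int) | (sc_r >= t_int)
        where = np.nonzero(hit)[0]
        n_hits += int(where.size)
        positions.extend((rec.id, int(p) + 1) for p in where)
    return n_hits, positions


def refine_pwm(pwm: Pwm, records, n_iter: int = 2,
               scan_pvalue: float = 1e-3, granularity: float = 1e-3,
               min_sites: int = 5, anneal: bool = True) -> Pwm:
    """Sharpen a candidate PWM on its own hit windows.

    Each iteration scans ``records`` (both strands) at the p-value-calibrated
    threshold and rebuilds the count matrix from the hit windows
    (reverse-strand hits contribute their reverse complement).  This is the
    standard seed-polishing step of enumerative motif finders: the MSA that
    seeded the candidate is a biased sample of the site population, and one
    or two scan-and-recount rounds converge the PWM onto the sites actually
    present.  Falls back to the input PWM when fewer than ``min_sites``
    windows hit.  With ``anneal`` the first scan runs at a 10x more
    permissive p-value so a biased seed can first gather the site
    population before the strict threshold sharpens it.
    """
    from .seq_io import reverse_complement

    current = pwm
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    schedule = [min(10 * scan_pvalue, 0.5)] + [scan_pvalue] * (n_iter - 1) \
        if anneal and n_iter > 1 else [scan_pvalue] * n_iter
    for it_pvalue in schedule:
        threshold = pvalue_to_score(current, it_pvalue, granularity)
        t_int = int(round(threshold / granularity))
        s_f = _int_scores(current, granularity)
        s_r = _int_scores(current.reverse_complement(), granularity)
        w = current.width
        counts = np.zeros((4, w))
        n_sites = 0
        for rec in records:
            arr = np.fromiter((_BASE_IDX[c] for c in rec.seq),
                              dtype=np.int64, count=len(rec.seq))
            sc_f = _scan_scores(s_f, arr)
            sc_r = _scan_scores(s_r, arr)
            for p in np.nonzero((sc_f >= t_int) | (sc_r >= t_int))[0]:
                window = rec.seq[p:p + w]
                if "N" in window:
                    continue
                if sc_f[p] < sc_r[p]:
                    window = reverse_complement(window)
                for j, ch in enumerate(window):
                    counts[idx[ch], j] += 1
                n_sites += 1
        if n_sites < min_sites:
            break
        current = Pwm(counts, current.background.copy(), current.pseudocount)
    return current


# ----------------------------------------------------------------------
# significance
# ----------------------------------------------------------------------

@dataclasses.dataclass
class MotifStats:
    tau_h: int
    tau_m: int
    c_h: int
    c_m: int
    odds_ratio: float
    p_value: float
    n_instances: int


def evaluate_significance(pwm: Pwm, test_records, seed: int,
                          scan_pvalue: float = 1e-3,
                          granularity: float = 1e-3,
                          threshold: float | None = None) -> MotifStats:
    """Fisher exact enrichment of PWM hits versus shuffled controls.

    N_T = sum of test-record lengths; misses are N_T minus hits.  Controls
    are per-record dinucleotide-preserving shuffles (seeded).  The p-value is
    the two-sided Fisher exact test of unit odds ratio.
    """
    if not test_records:
        raise ValueError("empty test set")
    if threshold is None:
        threshold = pvalue_to_score(pwm, scan_pvalue, granularity)
    n_t = sum(len(r.seq) for r in test_records)
    tau_h, _ = scan_hits(pwm, threshold, test_records, granularity)
    controls = [DnaRecord(r.id + "_shuf",
                          dinucleotide_shuffle(r.seq, seed + 7919 * i))
                for i, r in enumerate(test_records)]
    c_h, _ = scan_hits(pwm, threshold, controls, granularity)
    tau_m = n_t - tau_h
    c_m = n_t - c_h
    if (tau_h + c_h) == 0 or (tau_m + c_m) == 0:
        return MotifStats(tau_h, tau_m, c_h, c_m, float("nan"), 1.0, tau_h)
    oddsr, p = sp_stats.fisher_exact([[tau_h, tau_m], [c_h, c_m]],
                                     alternative="two-sided")
    if c_h == 0 or tau_m == 0:
        odds = float("inf")
    else:
        odds = (tau_h / tau_m) / (c_h / c_m)
    return MotifStats(tau_h, tau_m, c_h, c_m, odds, float(p), tau_h)


# ----------------------------------------------------------------------
# ALLR merging
# ----------------------------------------------------------------------

def allr(counts_a, counts_b, background=None, pseudocount: float = 1.0
         ) -> float:
    """Average log-likelihood ratio between two alignment columns.

    ALLR = [ sum_b n^a_b log2(f^B_b / bg_b) + sum_b n^b_b log2(f^A_b / bg_b) ]
           / (n^a + n^b),
    with f the pseudocounted frequencies of the opposite column.  Symmetric.
    """
    bg = UNIFORM_BG.copy() if background is None else np.asarray(background,
                                                                 dtype=float)
    na = np.asarray(counts_a, dtype=float)
    nb = np.asarray(counts_b, dtype=float)
    if na.sum() <= 0 or nb.sum() <= 0:
        raise ValueError("columns must have positive totals")
    fa = (na + pseudocount * bg) / (na.sum() + pseudocount)
    fb = (nb + pseudocount * bg) / (nb.sum() + pseudocount)
    num = (na * np.log2(fb / bg)).sum() + (nb * np.log2(fa / bg)).sum()
    return float(num / (na.sum() + nb.sum()))


def _allr_matrix(ca: np.ndarray, cb: np.ndarray, background,
                 pseudocount: float) -> np.ndarray:
    """Pairwise column ALLR, shape [wa, wb] (vectorized form of allr)."""
    bg = UNIFORM_BG if background is None else np.asarray(background,
                                                          dtype=float)
    na = ca.sum(axis=0)                              # [wa]
    nb = cb.sum(axis=0)                              # [wb]
    fa = (ca + pseudocount * bg[:, None]) / (na + pseudocount)
    fb = (cb + pseudocount * bg[:, None]) / (nb + pseudocount)
    la = np.log2(fa / bg[:, None])
    lb = np.log2(fb / bg[:, None])
    num = ca.T @ lb + (cb.T @ la).T                  # [wa, wb]
    return num / (na[:, None] + nb[None, :])


def _best_offset(ca: np.ndarray, cb: np.ndarray, min_overlap: int,
                 background, pseudocount) -> tuple[float, int]:
    """Best (mean ALLR, offset) of cb against ca over all overlaps."""
    wa, wb = ca.shape[1], cb.shape[1]
    mat = _allr_matrix(ca, cb, background, pseudocount)
    best, best_off = -np.inf, 0
    for offset in range(-wb + 1, wa):
        start_a = max(0, offset)
        end_a = min(wa, offset + wb)
        n_ov = end_a - start_a
        if n_ov < min_overlap:
            continue
        idx = np.arange(start_a, end_a)
        val = float(mat[idx, idx - offset].mean())
        if val > best:
            best, best_off = val, offset
    return best, best_off


@dataclasses.dataclass
class MergedMotif:
    counts: np.ndarray
    n_instances: int
    members: list          # configuration keys or candidate ids merged in


def merge_similar(candidates, min_overlap: int | None = None,
                  allr_threshold: float = 0.0, background=None,
                  pseudocount: float = 1.0,
                  max_retained: int | None = None) -> list[MergedMotif]:
    """Greedy redundancy reduction over an enrichment-ranked candidate list.

    ``candidates`` is a list of (label, counts, n_instances) in rank order.
    Each candidate is aligned against every retained motif at all overlap
    offsets on both strands; if the best mean ALLR over an overlap of at
    least ``min_overlap`` columns exceeds ``allr_threshold``, its aligned
    counts are added into the retained motif, else it starts a new motif.
    Total instance mass is conserved.  When ``max_retained`` is set,
    candidates that would open a motif beyond the cap are dropped (the
    ranking puts the strongest first).
    """
    retained: list[MergedMotif] = []
    for label, counts, n_inst in candidates:
        counts = np.asarray(counts, dtype=float)
        best = (-np.inf, None, None, None)  # allr, motif idx, offset, strand
        for i, mot in enumerate(retained):
            wa, wb = mot.counts.shape[1], counts.shape[1]
            mo = min_overlap if min_overlap is not None else max(
                6, int(np.ceil(min(wa, wb) / 2)))
            for strand, cb in (("+", counts), ("-", counts[::-1, ::-1])):
                val, off = _best_offset(mot.counts, cb, mo, background,
                                        pseudocount)
                if val > best[0]:
                    best = (val, i, off, strand)
        if best[1] is not None and best[0] > allr_threshold:
            _, i, offset, strand = best
            mot = retained[i]
            cb = counts if strand == "+" else counts[::-1, ::-1]
            wa, wb = mot.counts.shape[1], cb.shape[1]
            start_a = max(0, offset)
            end_a = min(wa, offset + wb)
            mot.counts[:, start_a:end_a] += cb[:, start_a - offset:
                                               end_a - offset]
            mot.n_instances += n_inst
            mot.members.append(label)
        elif max_retained is None or len(retained) < max_retained:
            retained.append(MergedMotif(counts.copy(), n_inst, [label]))
    return retained


# ----------------------------------------------------------------------
# MEME minimal format
# ----------------------------------------------------------------------

def write_meme(path, motifs, background=None) -> None:
    """Write motifs in MEME minimal format.

    ``motifs`` is a list of (name, Pwm, nsites, evalue-like p).
    """
    bg = UNIFORM_BG.copy() if background is None else np.asarray(background,
                                                                 dtype=float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for name, pwm, nsites, pval in motifs:
            probs = pwm.probabilities()
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {nsites} E= {pval:.3g}\n")
            for j in range(pwm.width):
                fh.write(" ".join(f"{probs[b, j]:.6f}" for b in range(4))
                         + "\n")
            fh.write("\n")


def read_meme(path):
    """Read back a MEME minimal file as (name, probability matrix) pairs."""
    out = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    out.append((name, np.array(rows).T))
                name, rows = line.split()[1], []
            elif name is not None:
                parts = line.split()
                if len(parts) == 4:
                    try:
                        rows.append([float(p) for p in parts])
                    except ValueError:
                        pass
    if name is not None and rows:
        out.append((name, np.array(rows).T))
    return out
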