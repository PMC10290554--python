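"""scikit-learn style estimators over the sparse-representation machinery.

``ConvolutionalSparseCoder`` learns the two filter banks from unaligned DNA
strings (fit) and produces per-sequence sparse codes (transform).
``MotifDiscovery`` runs the whole pipeline: held-out split, coder fit,
image-level enumeration, candidate ranking, ALLR merging and Fisher
enrichment — exposing the discovered motifs as fitted attributes.

Both follow the estimator contract (get_params/set_params, trailing
underscore on fitted attributes) and accept either DnaRecord lists or plain
strings as X.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import enumeration, motif_stats, seq_io, solvers, unfolded
from .seq_io import DnaRecord
from .solvers import SolverConfig
from .unfolded import NetHyper


def _as_records(X) -> list[DnaRecord]:
    records = []
    for i, x in enumerate(X):
        if isinstance(x, DnaRecord):
            records.append(x)
        elif isinstance(x, str):
            records.append(DnaRecord(f"seq_{i}", seq_io.sanitize(x)))
        else:
            raise TypeError("X must contain DNA strings or DnaRecords")
    return records


class ConvolutionalSparseCoder(BaseEstimator, TransformerMixin):
    """Two-level convolutional sparse coder for one-hot DNA.

    Parameters mirror the representation: M PFM filters of width
    ``filter_len`` at the sequence level, K non-negative unit-Frobenius
    filters of height ``filter_height`` at the image level, an alpha-sparse
    image code, and the image scaling beta.  ``mode`` selects the classical
    alternating solver or the trained unfolded network.

    Attributes
    ----------
    seq_filters_ : SeqFilterBank
    image_filters_ : ImageFilterBank
    net_params_ : NetParams (unfolded mode only)
    """

    def __init__(self, M=12, filter_len=8, K=8, filter_height=6, alpha=32,
                 beta=100.0, mode="classical", lam=2.0, eta=0.9,
                 outer_rounds=8, admm_iters=10, K1=6, K2=3, batch_size=6,
                 epochs=10, learning_rate=1e-3, random_state=0):
        self.M = M
        self.filter_len = filter_len
        self.K = K
        self.filter_height = filter_height
        self.alpha = alpha
        self.beta = beta
        self.mode = mode
        self.lam = lam
        self.eta = eta
        self.outer_rounds = outer_rounds
        self.admm_iters = admm_iters
        self.K1 = K1
        self.K2 = K2
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _solver_config(self) -> SolverConfig:
        return SolverConfig(
            M=self.M, filter_len=self.filter_len, K=self.K,
            filter_height=self.filter_height, alpha=self.alpha,
            beta=self.beta, lam=self.lam, eta=self.eta,
            outer_rounds=self.outer_rounds, admm_iters=self.admm_iters)

    def _hyper(self) -> NetHyper:
        return NetHyper(
            M=self.M, filter_len=self.filter_len, K=self.K,
            filter_height=self.filter_height, alpha=self.alpha,
            beta=self.beta, K1=self.K1, K2=self.K2,
            batch_size=self.batch_size, epochs=self.epochs,
            learning_rate=self.learning_rate, seed=self.random_state)

    def fit(self, X, y=None):
        records = _as_records(X)
        mats = [seq_io.one_hot(r).matrix for r in records]
        if self.mode == "classical":
            cfg = self._solver_config()
            bank, ibank, _ = solvers.fit_classical(
                mats, cfg, seed=self.random_state)
            self.seq_filters_ = bank
            self.image_filters_ = ibank
            self.net_params_ = None
        elif self.mode == "unfolded":
            hyper = self._hyper()
            params, trace = unfolded.train(mats, hyper)
            self.net_params_ = params
            from .sparse_model import ImageFilterBank, SeqFilterBank
            self.seq_filters_ = SeqFilterBank(params.seq_filters.copy())
            self.image_filters_ = ImageFilterBank(
                params.image_filters.copy())
            self.loss_trace_ = trace
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.n_sequences_ = len(records)
        return self

    def transform(self, X):
        """Per-sequence (CodePair, ImageCode), zero-start forward solve."""
        records = _as_records(X)
        mats = [seq_io.one_hot(r).matrix for r in records]
        if self.mode == "unfolded":
            return unfolded.infer_codes(self.net_params_, mats,
                                        self._hyper())
        cfg = self._solver_config()
        groups: dict[int, list[int]] = {}
        for i, m in enumerate(mats):
            groups.setdefault(m.shape[1], []).append(i)
        codes = [None] * len(mats)
        for L, idx in groups.items():
            S = np.stack([mats[i] for i in idx])
            st = solvers.init_state(len(idx), L, cfg)
            solvers.admm_solve_codes(
                st, self.seq_filters_.filters, self.image_filters_.filters,
                S, cfg, cfg.admm_iters)
            from .sparse_model import CodePair, ImageCode
            for j, i in enumerate(idx):
                codes[i] = (CodePair(st.X[j], st.Y[j]),
                            ImageCode(st.Z[j], cfg.alpha))
        return codes


class MotifDiscovery(BaseEstimator):
    """End-to-end motif discovery from unaligned DNA strings.

    fit(X) splits off a held-out test fraction, fits the coder on the
    training part, infers codes for all records, enumerates q-component
    image configurations into MSAs, ranks and merges candidates, and
    evaluates Fisher enrichment of every reported motif on the held-out
    records against dinucleotide-shuffled controls.

    Attributes
    ----------
    motifs_ : list of dict with counts, Pwm, MotifStats, configuration
    report_ : DataFrame, one row per reported motif
    coder_ : the fitted ConvolutionalSparseCoder
    """

    def __init__(self, M=12, filter_len=8, K=8, filter_height=6, alpha=32,
                 beta=100.0, q=3, mode="classical", top_j=1000,
                 test_fraction=0.15, scan_pvalue=1e-3,
                 significance_pvalue=1e-6, min_count=3, max_report=50,
                 allr_threshold=0.0, refine_iters=3, outer_rounds=8,
                 admm_iters=10, epochs=10, random_state=0):
        self.M = M
        self.filter_len = filter_len
        self.K = K
        self.filter_height = filter_height
        self.alpha = alpha
        self.beta = beta
        self.q = q
        self.mode = mode
        self.top_j = top_j
        self.test_fraction = test_fraction
        self.scan_pvalue = scan_pvalue
        self.significance_pvalue = significance_pvalue
        self.min_count = min_count
        self.max_report = max_report
        self.allr_threshold = allr_threshold
        self.refine_iters = refine_iters
        self.outer_rounds = outer_rounds
        self.admm_iters = admm_iters
        self.epochs = epochs
        self.random_state = random_state

    def fit(self, X, y=None):
        records = _as_records(X)
        if len(records) < 20:
            raise ValueError("need at least 20 sequences")
        train, test = seq_io.split_train_test(
            records, self.test_fraction, self.random_state)
        coder = ConvolutionalSparseCoder(
            M=self.M, filter_len=self.filter_len, K=self.K,
            filter_height=self.filter_height, alpha=self.alpha,
            beta=self.beta, mode=self.mode, outer_rounds=self.outer_rounds,
            admm_iters=self.admm_iters, epochs=self.epochs,
            random_state=self.random_state)
        coder.fit(train)
        # MSAs are built from the training records only: the held-out set
        # must stay untouched by fitting AND motif construction, or the
        # enrichment test conditions on its own sequences
        codes = coder.transform(train)

        table = enumeration.build_motif_table(
            codes, train, self.q, self.filter_height, self.filter_len)
        ranked = enumeration.select_top(table, self.top_j)
        candidates = []
        for config, bucket in ranked:
            if len(bucket) < self.min_count:
                continue
            counts = enumeration.msa_to_counts([b[2] for b in bucket])
            if counts.sum() == 0:
                continue
            candidates.append((config, counts, len(bucket)))
        merged = motif_stats.merge_similar(
            candidates, allr_threshold=self.allr_threshold,
            max_retained=self.max_report)
        merged = merged[:self.max_report]

        motifs = []
        for i, mot in enumerate(merged):
            pwm = motif_stats.pwm_from_counts(mot.counts)
            if self.refine_iters:
                # polish the candidate on its own training-set hit windows;
                # the held-out records never enter this step
                pwm = motif_stats.refine_pwm(
                    pwm, train, n_iter=self.refine_iters,
                    scan_pvalue=self.scan_pvalue)
            threshold = motif_stats.pvalue_to_score(pwm, self.scan_pvalue)
            stats = motif_stats.evaluate_significance(
                pwm, test, seed=self.random_state + 31 * i,
                scan_pvalue=self.scan_pvalue, threshold=threshold)
            # instances = hits across the whole dataset
            n_inst, _ = motif_stats.scan_hits(pwm, threshold, records)
            motifs.append({
                "configuration": mot.members[0],
                "member_keys": mot.members,
                "counts": mot.counts,
                "pwm": pwm,
                "stats": stats,
                "threshold": threshold,
                "n_instances": n_inst,
                "msa_size": mot.n_instances,
                "significant": stats.p_value < self.significance_pvalue,
            })
        # report the most significant motifs first (enrichment on held-out
        # data is what distinguishes a real motif from a recurring pattern
        # of the representation)
        motifs.sort(key=lambda m: (m["stats"].p_value, -m["msa_size"]))
        rows = []
        for i, m in enumerate(motifs):
            m["name"] = f"motif_{i + 1}"
            rows.append({
                "motif": m["name"],
                "configuration": ",".join(str(v) for v in
                                          m["configuration"]),
                "width": m["pwm"].width,
                "n_instances": m["n_instances"],
                "msa_size": m["msa_size"],
                "tau_h": m["stats"].tau_h,
                "c_h": m["stats"].c_h,
                "odds_ratio": m["stats"].odds_ratio,
                "p_value": m["stats"].p_value,
                "significant": m["significant"],
            })
        self.coder_ = coder
        self.motifs_ = motifs
        self.report_ = pd.DataFrame(rows)
        self.train_records_ = train
        self.test_records_ = test
        self.table_size_ = len(table)
        return self

    def significant_motifs_(self):
        return [m for m in self.motifs_ if m["significant"]]

    def to_meme(self, path):
        motif_stats.write_meme(
            path,
            [(m["name"], m["pwm"], m["n_instances"], m["stats"].p_value)
             for m in self.motifs_])
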