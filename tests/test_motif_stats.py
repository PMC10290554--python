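import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats as sp_stats

from sparsemotif import motif_stats as ms
from sparsemotif.seq_io import DnaRecord
from sparsemotif.synthetic import sample_background


class TestPwm:
    def test_uniform_counts_zero_log_odds(self):
        pwm = ms.pwm_from_counts(np.full((4, 3), 5))
        assert np.allclose(pwm.log_odds, 0)

    def test_single_base_column(self):
        pwm = ms.pwm_from_counts(np.array([[10], [0], [0], [0]]))
        # (10 + 0.25) / 11 / 0.25
        assert np.isclose(pwm.log_odds[0, 0], np.log2((10.25 / 11) / 0.25))
        assert np.isclose(pwm.log_odds[0, 0], 1.898, atol=1e-3)

    def test_scale_invariance_without_pseudocount(self):
        c = np.array([[3, 1], [2, 0], [4, 4], [1, 5]], dtype=float)
        p1 = ms.Pwm(c, pseudocount=0.0)
        p2 = ms.Pwm(2 * c, pseudocount=0.0)
        assert np.allclose(p1.log_odds, p2.log_odds)

    def test_reverse_complement(self):
        c = np.array([[4, 0], [0, 0], [0, 0], [0, 4]], dtype=float)
        rc = ms.pwm_from_counts(c).reverse_complement()
        assert np.array_equal(rc.counts, [[4, 0], [0, 0], [0, 0], [0, 4]])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ms.pwm_from_counts(np.zeros((4, 2)))


class TestPvalueToScore:
    def test_one_column_enumeration(self):
        scores = np.array([[2.0], [1.0], [0.0], [-1.0]])
        bg = [0.25] * 4
        assert ms.score_threshold(scores, bg, 0.25) == 2.0
        assert ms.score_threshold(scores, bg, 0.5) == 1.0

    def test_exhaustive_word_oracle(self, rng):
        """Threshold equals brute force over all 4^w words, 50 random PWMs
        of width <= 6."""
        g = 1e-3
        for trial in range(50):
            w = int(rng.integers(1, 7))
            counts = rng.integers(0, 25, size=(4, w)) + 1
            pwm = ms.pwm_from_counts(counts)
            p = float(rng.uniform(0.002, 0.6))
            s_int = np.round(pwm.log_odds / g).astype(np.int64)
            cnt = Counter(
                int(s_int[list(word), range(w)].sum())
                for word in itertools.product(range(4), repeat=w))
            best = None
            for t in sorted(cnt):
                tail = sum(c for u, c in cnt.items() if u >= t) / 4 ** w
                if tail <= p + 1e-15:
                    best = t
                    break
            expect = (max(cnt) + 1) * g if best is None else best * g
            assert np.isclose(ms.pvalue_to_score(pwm, p, g), expect,
                              atol=1e-12)

    def test_monotone_in_pvalue(self, rng):
        counts = rng.integers(0, 30, size=(4, 5)) + 1
        pwm = ms.pwm_from_counts(counts)
        ts = [ms.pvalue_to_score(pwm, p)
              for p in [0.5, 0.1, 0.01, 1e-3, 1e-4]]
        assert all(t2 >= t1 for t1, t2 in zip(ts, ts[1:]))

    def test_invalid_pvalue(self):
        pwm = ms.pwm_from_counts(np.ones((4, 2)))
        with pytest.raises(ValueError):
            ms.pvalue_to_score(pwm, 1.5)


class TestScan:
    def _ac_pwm(self):
        return ms.pwm_from_counts(np.array([[20, 0], [0, 20],
                                            [0, 0], [0, 0]]))

    def test_exact_match_offsets(self):
        pwm = self._ac_pwm()
        thr = ms.pvalue_to_score(pwm, 0.1)
        n, pos = ms.scan_hits(pwm, thr, [DnaRecord("r", "ACGACT")])
        assert n == 2
        assert [p for _, p in pos] == [1, 4]

    def test_empty_record_set(self):
        pwm = self._ac_pwm()
        assert ms.scan_hits(pwm, 0.0, [])[0] == 0

    def test_n_windows_never_hit(self):
        pwm = self._ac_pwm()
        thr = ms.pvalue_to_score(pwm, 0.1)
        n, _ = ms.scan_hits(pwm, thr, [DnaRecord("r", "ANCAC")])
        assert n == 1  # only the terminal AC

    def test_strand_symmetry(self, rng):
        from sparsemotif.seq_io import reverse_complement

        for _ in range(20):
            counts = rng.integers(0, 15, size=(4, 4)) + 1
            pwm = ms.pwm_from_counts(counts)
            thr = ms.pvalue_to_score(pwm, 0.05)
            s = "".join(rng.choice(list("ACGT"), size=30))
            n1, _ = ms.scan_hits(pwm, thr, [DnaRecord("r", s)])
            n2, _ = ms.scan_hits(pwm, thr,
                                 [DnaRecord("r", reverse_complement(s))])
            assert n1 == n2

    def test_control_hit_rate_tracks_scan_pvalue(self):
        """On pure background the per-strand hit rate approximates the
        calibrated p-value (binomial tolerance at ~1e5 positions)."""
        g = np.random.default_rng(0)
        counts = g.integers(0, 40, size=(4, 8)) + 1
        pwm = ms.pwm_from_counts(counts)
        p = 1e-3
        thr = ms.pvalue_to_score(pwm, p)
        records = sample_background(1000, 108, seed=5)  # ~1e5 windows
        n, _ = ms.scan_hits(pwm, thr, records)
        n_windows = sum(len(r.seq) - pwm.width + 1 for r in records)
        # both strands scanned: the deduplicated rate lies in [p, 2p];
        # allow the spec's binomial band around that
        rate = n / n_windows
        assert 0.5 * p <= rate <= 2.0 * p * 1.1


class TestFisher:
    def hypergeom_two_sided(self, a, b, c, d):
        """Independent oracle: sum of table probabilities <= P(observed)."""
        n = a + b + c + d
        row1, col1 = a + b, a + c
        lo = max(0, col1 - (c + d))
        hi = min(row1, col1)
        probs = {x: sp_stats.hypergeom.pmf(x, n, row1, col1)
                 for x in range(lo, hi + 1)}
        p_obs = probs[a]
        return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))

    def test_worked_example(self):
        """tau=(3,1), c=(1,3): odds ratio 9, two-sided p = 34/70."""
        st = ms.MotifStats(3, 1, 1, 3, 9.0, 0.0, 3)
        _, p = sp_stats.fisher_exact([[3, 1], [1, 3]])
        assert np.isclose(p, 34 / 70)
        assert np.isclose(self.hypergeom_two_sided(3, 1, 1, 3), 34 / 70)

    def test_matches_hypergeometric_oracle(self, rng):
        """500 random tables against the hypergeometric-sum oracle."""
        for _ in range(500):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = sp_stats.fisher_exact([[a, b], [c, d]])
            oracle = self.hypergeom_two_sided(a, b, c, d)
            assert np.isclose(p, oracle, rtol=1e-10)


class TestEvaluateSignificance:
    def test_null_case_identical_sets(self):
        """Scanning a set against itself as control: odds ratio 1, p 1."""
        g = np.random.default_rng(3)
        counts = g.integers(0, 20, size=(4, 6)) + 1
        pwm = ms.pwm_from_counts(counts)
        recs = sample_background(10, 60, seed=8)
        thr = ms.pvalue_to_score(pwm, 1e-2)
        th, _ = ms.scan_hits(pwm, thr, recs)
        n_t = sum(len(r.seq) for r in recs)
        odds, p = sp_stats.fisher_exact([[th, n_t - th], [th, n_t - th]])
        assert p == 1.0

    def test_stats_fields_consistent(self):
        recs = sample_background(15, 80, seed=2)
        g = np.random.default_rng(3)
        pwm = ms.pwm_from_counts(g.integers(0, 20, size=(4, 6)) + 1)
        st = ms.evaluate_significance(pwm, recs, seed=4)
        n_t = sum(len(r.seq) for r in recs)
        assert st.tau_h + st.tau_m == n_t
        assert st.c_h + st.c_m == n_t
        assert 0 <= st.p_value <= 1
        assert st.n_instances == st.tau_h

    def test_deterministic_given_seed(self):
        recs = sample_background(10, 60, seed=2)
        g = np.random.default_rng(3)
        pwm = ms.pwm_from_counts(g.integers(0, 20, size=(4, 5)) + 1)
        s1 = ms.evaluate_significance(pwm, recs, seed=7)
        s2 = ms.evaluate_significance(pwm, recs, seed=7)
        assert (s1.tau_h, s1.c_h, s1.p_value) == (s2.tau_h, s2.c_h,
                                                  s2.p_value)
        assert np.isclose(s1.odds_ratio, s2.odds_ratio, equal_nan=True)

    def test_empty_test_set_rejected(self):
        pwm = ms.pwm_from_counts(np.ones((4, 2)))
        with pytest.raises(ValueError):
            ms.evaluate_significance(pwm, [], seed=0)


class TestAllr:
    def test_identical_conserved_columns_positive(self):
        a = np.array([20, 0, 0, 0])
        assert ms.allr(a, a) > 0

    def test_opposed_columns_negative(self):
        a = np.array([20, 0, 0, 0])
        b = np.array([0, 0, 0, 20])
        assert ms.allr(a, b) < 0

    def test_symmetry(self, rng):
        for _ in range(20):
            a = rng.integers(0, 30, size=4) + 1
            b = rng.integers(0, 30, size=4) + 1
            assert np.isclose(ms.allr(a, b), ms.allr(b, a))

    def test_vectorized_matrix_matches_scalar(self, rng):
        ca = rng.integers(0, 20, size=(4, 3)) + 1.0
        cb = rng.integers(0, 20, size=(4, 4)) + 1.0
        mat = ms._allr_matrix(ca, cb, None, 1.0)
        for i in range(3):
            for j in range(4):
                assert np.isclose(mat[i, j], ms.allr(ca[:, i], cb[:, j]))


class TestMerge:
    def test_self_merge_doubles_counts(self):
        c = np.array([[9, 0, 0], [1, 10, 0], [0, 0, 10], [0, 0, 0]],
                     dtype=float)
        merged = ms.merge_similar([("a", c, 5), ("b", c, 5)], min_overlap=3)
        assert len(merged) == 1
        assert np.array_equal(merged[0].counts, 2 * c)
        assert merged[0].n_instances == 10

    def test_dissimilar_retained_separately(self):
        a = np.zeros((4, 6)); a[0] = 10            # poly-A
        b = np.zeros((4, 6)); b[1] = 10            # poly-C (not rc of A)
        merged = ms.merge_similar([("a", a, 3), ("b", b, 3)], min_overlap=4)
        assert len(merged) == 2

    def test_reverse_complement_merge(self):
        a = np.zeros((4, 6)); a[0] = 10            # poly-A
        t = np.zeros((4, 6)); t[3] = 10            # poly-T = rc(poly-A)
        merged = ms.merge_similar([("a", a, 3), ("t", t, 3)], min_overlap=4)
        assert len(merged) == 1

    def test_instance_mass_conserved_and_deterministic(self, rng):
        cands = []
        for i in range(8):
            c = rng.integers(0, 12, size=(4, int(rng.integers(5, 9)))) + 1.0
            cands.append((f"c{i}", c, int(rng.integers(1, 20))))
        m1 = ms.merge_similar(cands)
        m2 = ms.merge_similar(cands)
        assert sum(m.n_instances for m in m1) == sum(n for _, _, n in cands)
        assert len(m1) == len(m2)
        for x, y in zip(m1, m2):
            assert np.array_equal(x.counts, y.counts)


class TestMeme:
    def test_roundtrip(self, tmp_path):
        g = np.random.default_rng(0)
        motifs = []
        for i in range(3):
            counts = g.integers(0, 30, size=(4, 5 + i))
            pwm = ms.pwm_from_counts(counts)
            motifs.append((f"motif_{i+1}", pwm, 10 + i, 1e-8))
        path = tmp_path / "motifs.meme"
        ms.write_meme(path, motifs)
        back = ms.read_meme(path)
        assert [name for name, _ in back] == ["motif_1", "motif_2",
                                              "motif_3"]
        for (name, mat), (_, pwm, _, _) in zip(back, motifs):
            assert mat.shape == (4, pwm.width)
            assert np.allclose(mat, pwm.probabilities(), atol=1e-5)
            assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-4)
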