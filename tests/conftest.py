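import numpy as np
import pytest

from sparsemotif import synthetic
from sparsemotif.seq_io import one_hot


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planted_primary():
    """Small planted-motif dataset used by several module tests."""
    spec = synthetic.PlantSpec(
        pfms=[synthetic.consensus_pfm("TGACTCAG", 0.92)],
        occurrence_rate=1.0, n_seqs=40, seq_len=80, seed=11)
    records, truth = synthetic.planted_dataset(spec)
    return records, truth, spec


@pytest.fixture(scope="session")
def exact_instance():
    """Sequences synthesized exactly from known filters and 1-sparse codes."""
    from sparsemotif.sparse_model import CodePair, SeqFilterBank
    from sparsemotif.sparse_model import reconstruct_sequence

    g = np.random.default_rng(7)
    M_true, ell, L, n = 3, 8, 50, 30
    D = g.dirichlet(np.ones(4) * 0.2, size=(M_true, ell)).transpose(0, 2, 1)
    bank = SeqFilterBank(D)
    seqs, codes = [], []
    for _ in range(n):
        X = np.zeros((L - ell + 1, M_true))
        X[g.integers(L - ell + 1), g.integers(M_true)] = 1.0
        cp = CodePair(X, np.zeros_like(X))
        seqs.append(reconstruct_sequence(bank, cp))
        codes.append(cp)
    return bank, codes, seqs
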