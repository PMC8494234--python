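"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from math import lgamma

import numpy as np
import pandas as pd
import pytest

from scitopic.preprocess import GenomeTable


# ---------------------------------------------------------------------------
# independent oracles (never call the implementation under test)
# ---------------------------------------------------------------------------

def collapsed_posterior_enumeration(doc_ids, word_ids, n_docs, vocab, n_topics,
                                    alpha_total, beta_total):
    """Exhaustively enumerate p(z | w) of collapsed LDA on a tiny corpus.

    Returns (per-token marginals [T x K], co-assignment matrix [T x T] with
    P(z_i == z_j)). Brute force over K^T assignment vectors using the
    Dirichlet-multinomial collapsed joint.
    """
    a = alpha_total / n_topics
    b = beta_total / vocab
    T = len(doc_ids)

    def log_joint(z):
        lj = 0.0
        for d in range(n_docs):
            nd = np.bincount([z[i] for i in range(T) if doc_ids[i] == d],
                             minlength=n_topics)
            lj += lgamma(alpha_total) - lgamma(alpha_total + nd.sum())
            for k in range(n_topics):
                lj += lgamma(a + nd[k]) - lgamma(a)
        for k in range(n_topics):
            nw = np.bincount([word_ids[i] for i in range(T) if z[i] == k],
                             minlength=vocab)
            lj += lgamma(beta_total) - lgamma(beta_total + nw.sum())
            for w in range(vocab):
                lj += lgamma(b + nw[w]) - lgamma(b)
        return lj

    states = list(itertools.product(range(n_topics), repeat=T))
    ljs = np.array([log_joint(z) for z in states])
    p = np.exp(ljs - ljs.max())
    p /= p.sum()
    marg = np.zeros((T, n_topics))
    co = np.zeros((T, T))
    for z, pi in zip(states, p):
        for i in range(T):
            marg[i, z[i]] += pi
            for j in range(T):
                if z[i] == z[j]:
                    co[i, j] += pi
    return marg, co


def doc_marginal_enumeration(tokens, phi, alpha_total):
    """Exact p(w | phi, alpha) of one document by enumeration over z."""
    n_topics = phi.shape[0]
    a = alpha_total / n_topics
    total = 0.0
    for z in itertools.product(range(n_topics), repeat=len(tokens)):
        nk = np.bincount(z, minlength=n_topics)
        lj = lgamma(alpha_total) - lgamma(alpha_total + len(tokens))
        for k in range(n_topics):
            lj += lgamma(a + nk[k]) - lgamma(a)
        total += np.exp(lj) * np.prod([phi[z[i], tokens[i]] for i in range(len(tokens))])
    return total


def slope_jump_outliers(values, side):
    """Direct slope-jump oracle: items beyond the largest gap on a side."""
    order = np.argsort(values, kind="stable")
    sv = np.asarray(values)[order]
    n = sv.size
    half = n // 2
    mask = np.zeros(n, dtype=bool)
    if side in ("high", "both"):
        j = half + int(np.argmax(np.diff(sv[half:])))
        mask_sorted = np.zeros(n, dtype=bool)
        mask_sorted[j + 1:] = True
        mask[order] |= mask_sorted
    if side in ("low", "both"):
        j = int(np.argmax(np.diff(sv[: half + 1])))
        mask_sorted = np.zeros(n, dtype=bool)
        mask_sorted[: j + 1] = True
        mask[order] |= mask_sorted
    return mask


def valley_split_oracle(signal):
    """Brute-force valley search: boundaries at minima between local maxima."""
    sig = np.asarray(signal, dtype=float)
    summits = [
        i for i in range(len(sig))
        if (i == 0 or sig[i] > sig[i - 1]) and (i == len(sig) - 1 or sig[i] > sig[i + 1])
    ]
    # keep clear local maxima only (strictly above both neighbors where defined)
    summits = [i for i in summits if 0 < i < len(sig) - 1] or [int(np.argmax(sig))]
    boundaries = [0]
    for s1, s2 in zip(summits[:-1], summits[1:]):
        valley = sig[s1 + 1: s2]
        vmin = valley.min()
        cands = [s1 + 1 + k for k, v in enumerate(valley) if v == vmin]
        mid = (s1 + s2) / 2
        v = min(cands, key=lambda c: (abs(c - mid), c))
        boundaries.append(v + 1)
    boundaries.append(len(sig))
    return list(zip(boundaries[:-1], boundaries[1:]))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_genome():
    return GenomeTable([("chr1", 10_000), ("chr2", 5_000)])


@pytest.fixture
def fragments_df():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "start": [100, 100, 500, 40],
            "end": [200, 200, 700, 90],
            "barcode": ["AAA", "AAA", "AAA", "CCC"],
        }
    )


@pytest.fixture
def tiny_corpus():
    """2 cells x 4 peaks: cell1={p1,p2}, cell2={p3,p4}."""
    import scipy.sparse as sp

    from scitopic.matrix import CellsByPeaksMatrix

    dense = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
    return CellsByPeaksMatrix(
        sp.csr_matrix(dense), pd.Index(["c1", "c2"]), pd.Index(["p1", "p2", "p3", "p4"])
    )
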