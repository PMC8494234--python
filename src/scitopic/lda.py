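"""Collapsed-Gibbs latent Dirichlet allocation over binary scATAC corpora.

Cells are documents, peaks are words, and every (cell, present-peak) entry of
the binary matrix is one token. Symmetric Dirichlet priors are parameterized
by their *total* weights ``alpha`` (cell-topic) and ``beta`` (topic-peak):
the per-component hyperparameters are ``alpha / K`` and ``beta / V``. Under
this convention a large beta (default 2000) pulls each topic's peak
distribution toward uniform, spreading probability across many peaks, while
the modest alpha (default 3) keeps each cell concentrated on few topics.
Set ``prior_style="per_component"`` to treat alpha and beta as the
per-component values directly.

The sampler integrates out theta and phi and samples only the per-token topic
assignments; point estimates are read off post-burn-in samples taken every
``sample_stride`` sweeps, either by averaging the sampled count matrices
("mean", the default) or by taking each token's most frequent sampled
assignment ("mode").
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from ._gibbs import gibbs_train, gibbs_predict_doc
from .matrix import CellsByPeaksMatrix

logger = logging.getLogger(__name__)


@dataclass
class LDAConfig:
    """Training configuration for the collapsed Gibbs sampler."""

    n_topics: int
    alpha: float = 3.0
    beta: float = 2000.0
    iterations: int = 4000
    burn_in: int | None = None  # default: iterations // 2
    sample_stride: int = 40
    seed: int = 0
    n_workers: int = 1
    estimator: str = "mean"  # "mean" | "mode"
    prior_style: str = "total"  # "total" | "per_component"

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")
        if self.estimator not in ("mean", "mode"):
            raise ValueError("estimator must be 'mean' or 'mode'")
        if self.prior_style not in ("total", "per_component"):
            raise ValueError("prior_style must be 'total' or 'per_component'")

    def resolved_burn_in(self) -> int:
        b = self.iterations // 2 if self.burn_in is None else self.burn_in
        if b >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        return b

    def per_component(self, vocab_size: int) -> tuple[float, float, float, float]:
        """(a, b_v, alpha_total, beta_total) given the vocabulary size."""
        if self.prior_style == "total":
            return (
                self.alpha / self.n_topics,
                self.beta / vocab_size,
                self.alpha,
                self.beta,
            )
        return (
            self.alpha,
            self.beta,
            self.alpha * self.n_topics,
            self.beta * vocab_size,
        )


@dataclass
class LDAModel:
    """Fitted model: count matrices, probability matrices, and assignments."""

    config: LDAConfig
    cells: pd.Index
    peaks: pd.Index
    doc_topic: np.ndarray    # D x K integer counts
    word_topic: np.ndarray   # V x K integer counts
    theta: np.ndarray        # D x K prior-smoothed probabilities
    phi: np.ndarray          # K x V prior-smoothed probabilities
    assignments: np.ndarray  # one topic label per (cell, present-peak) token
    token_doc: np.ndarray
    token_word: np.ndarray
    assignment_freq: np.ndarray | None = None

    @property
    def n_topics(self) -> int:
        return self.config.n_topics

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "docTopic.tsv", self.doc_topic, fmt="%d", delimiter="\t")
        np.savetxt(d / "wordTopic.tsv", self.word_topic, fmt="%d", delimiter="\t")
        np.savetxt(d / "theta.tsv", self.theta, delimiter="\t")
        np.savetxt(d / "phi.tsv", self.phi, delimiter="\t")
        (d / "cells.txt").write_text("\n".join(map(str, self.cells)) + "\n")
        (d / "peaks.txt").write_text("\n".join(map(str, self.peaks)) + "\n")
        (d / "config.json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, directory) -> "LDAModel":
        d = Path(directory)
        config = LDAConfig(**json.loads((d / "config.json").read_text()))
        theta = np.atleast_2d(np.loadtxt(d / "theta.tsv", delimiter="\t"))
        phi = np.atleast_2d(np.loadtxt(d / "phi.tsv", delimiter="\t"))
        doc_topic = np.atleast_2d(np.loadtxt(d / "docTopic.tsv", delimiter="\t", dtype=np.int64))
        word_topic = np.atleast_2d(np.loadtxt(d / "wordTopic.tsv", delimiter="\t", dtype=np.int64))
        cells = pd.Index((d / "cells.txt").read_text().splitlines())
        peaks = pd.Index((d / "peaks.txt").read_text().splitlines())
        return cls(
            config, cells, peaks, doc_topic, word_topic, theta, phi,
            assignments=np.zeros(0, dtype=np.int64),
            token_doc=np.zeros(0, dtype=np.int64),
            token_word=np.zeros(0, dtype=np.int64),
        )


def _tokens_from_matrix(m) -> tuple[np.ndarray, np.ndarray, int, int]:
    """(doc_ids, word_ids, D, V) from a binary sparse matrix, row-major order."""
    x = m.matrix if isinstance(m, CellsByPeaksMatrix) else sp.csr_matrix(m)
    x = sp.csr_matrix(x)
    coo = x.tocoo()
    order = np.lexsort((coo.col, coo.row))
    return (
        coo.row[order].astype(np.int64),
        coo.col[order].astype(np.int64),
        x.shape[0],
        x.shape[1],
    )


def _match_topics(ref_nwk: np.ndarray, cur_nwk: np.ndarray) -> np.ndarray:
    """Permutation aligning current topic columns to the reference sample.

    Maximizes the summed cosine similarity between matched word-topic count
    columns (Hungarian assignment), undoing label switching between
    posterior samples.
    """
    ref = ref_nwk / np.maximum(np.linalg.norm(ref_nwk, axis=0), 1e-12)
    cur = cur_nwk / np.maximum(np.linalg.norm(cur_nwk, axis=0), 1e-12)
    cost = -(ref.T @ cur)
    from scipy.optimize import linear_sum_assignment

    row, col = linear_sum_assignment(cost)
    perm = np.empty(ref_nwk.shape[1], dtype=np.int64)
    perm[row] = col
    return perm


def _derive_seed(*parts) -> int:
    """Stable 31-bit seed from arbitrary string-able parts."""
    key = ":".join(str(p) for p in parts)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


class LatentDirichletAllocationGibbs(TransformerMixin, BaseEstimator):
    """Collapsed-Gibbs LDA with symmetric Dirichlet priors.

    Parameters mirror :class:`LDAConfig`. After :meth:`fit`, the model exposes
    ``theta_`` (cells x topics), ``phi_`` / ``components_`` (topics x peaks),
    the raw count matrices ``doc_topic_`` and ``word_topic_``, and the final
    token assignments ``z_``. :meth:`transform` infers theta rows for new
    cells with phi held fixed.

    With ``n_workers > 1`` training uses an approximate-distributed scheme:
    documents are partitioned into shards, each shard sweeps against a
    snapshot of the global word-topic counts, and the count deltas are merged
    after every sweep. The factorization is approximate but converges to the
    same posterior summaries in practice; single-worker runs are
    bit-reproducible given ``seed``.
    """

    def __init__(
        self,
        n_topics: int = 10,
        alpha: float = 3.0,
        beta: float = 2000.0,
        iterations: int = 4000,
        burn_in: int | None = None,
        sample_stride: int = 40,
        seed: int = 0,
        n_workers: int = 1,
        estimator: str = "mean",
        prior_style: str = "total",
        track_assignments: bool = False,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.iterations = iterations
        self.burn_in = burn_in
        self.sample_stride = sample_stride
        self.seed = seed
        self.n_workers = n_workers
        self.estimator = estimator
        self.prior_style = prior_style
        self.track_assignments = track_assignments

    def _config(self) -> LDAConfig:
        return LDAConfig(
            n_topics=self.n_topics, alpha=self.alpha, beta=self.beta,
            iterations=self.iterations, burn_in=self.burn_in,
            sample_stride=self.sample_stride, seed=self.seed,
            n_workers=self.n_workers, estimator=self.estimator,
            prior_style=self.prior_style,
        )

    def fit(self, X, y=None) -> "LatentDirichletAllocationGibbs":
        cfg = self._config()
        doc_ids, word_ids, n_docs, vocab = _tokens_from_matrix(X)
        if doc_ids.size == 0:
            raise ValueError("empty corpus: no tokens")
        doc_lens = np.bincount(doc_ids, minlength=n_docs)
        if (doc_lens == 0).any():
            bad = int(np.nonzero(doc_lens == 0)[0][0])
            raise ValueError(
                f"cell {bad} has zero tokens; filter the matrix before fitting"
            )
        if cfg.n_topics > vocab:
            warnings.warn(
                f"n_topics={cfg.n_topics} exceeds vocabulary size {vocab}",
                stacklevel=2,
            )
        a, b_v, alpha_total, beta_total = cfg.per_component(vocab)
        burn_in = cfg.resolved_burn_in()

        rng = np.random.default_rng(cfg.seed)
        z = rng.integers(0, cfg.n_topics, size=doc_ids.size).astype(np.int64)
        n_dk = np.zeros((n_docs, cfg.n_topics), dtype=np.int64)
        n_wk = np.zeros((vocab, cfg.n_topics), dtype=np.int64)
        np.add.at(n_dk, (doc_ids, z), 1)
        np.add.at(n_wk, (word_ids, z), 1)
        n_k = n_wk.sum(axis=0)

        track = self.track_assignments or cfg.estimator == "mode"
        freq = np.zeros((doc_ids.size if track else 1, cfg.n_topics), dtype=np.int64)
        sum_ndk = np.zeros(n_dk.shape, dtype=np.float64)
        sum_nwk = np.zeros(n_wk.shape, dtype=np.float64)
        ref_nwk: np.ndarray | None = None

        def take_sample(sample_idx: int) -> np.ndarray | None:
            # Align topic labels to the first sample before averaging:
            # a small chain can swap topic labels between samples (label
            # switching), which would smear the averaged counts across
            # topics. Raw per-token frequencies stay unaligned, matching
            # the exchangeable posterior.
            nonlocal ref_nwk
            perm = np.arange(cfg.n_topics)
            if ref_nwk is None:
                ref_nwk = n_wk.astype(float).copy()
            elif cfg.n_topics > 1:
                perm = _match_topics(ref_nwk, n_wk)
            sum_ndk[:] += n_dk[:, perm]
            sum_nwk[:] += n_wk[:, perm]
            if track:
                np.add.at(freq, (np.arange(z.size), z), 1)
            return perm

        n_samples = 0
        if cfg.n_workers <= 1:
            dummy = np.zeros((1, cfg.n_topics), dtype=np.int64)
            chunk_seeds = iter(range(1_000_000))

            def run_sweeps(n: int) -> None:
                if n > 0:
                    gibbs_train(
                        doc_ids, word_ids, z, n_dk, n_wk, n_k,
                        a, b_v, float(beta_total),
                        n, n + 1, 1,  # no internal sampling
                        _derive_seed(cfg.seed, "train", next(chunk_seeds)),
                        dummy, dummy, dummy, False,
                    )

            run_sweeps(burn_in)
            take_sample(0)
            n_samples = 1
            done = burn_in
            while done + cfg.sample_stride <= cfg.iterations:
                run_sweeps(cfg.sample_stride)
                done += cfg.sample_stride
                take_sample(n_samples)
                n_samples += 1
            run_sweeps(cfg.iterations - done)
        else:
            n_samples = self._fit_partitioned(
                cfg, doc_ids, word_ids, z, n_dk, n_wk, n_k,
                a, b_v, float(beta_total), burn_in, take_sample,
            )

        if n_samples == 0:
            raise RuntimeError("no posterior samples collected; check burn_in/stride")

        if cfg.estimator == "mode":
            z_hat = np.argmax(freq, axis=1)
            est_ndk = np.zeros_like(n_dk)
            est_nwk = np.zeros_like(n_wk)
            np.add.at(est_ndk, (doc_ids, z_hat), 1)
            np.add.at(est_nwk, (word_ids, z_hat), 1)
            est_ndk = est_ndk.astype(float)
            est_nwk = est_nwk.astype(float)
        else:
            est_ndk = sum_ndk / n_samples
            est_nwk = sum_nwk / n_samples

        theta = (est_ndk + a) / (doc_lens[:, None] + alpha_total)
        est_nk = est_nwk.sum(axis=0)
        phi = ((est_nwk + b_v) / (est_nk + beta_total)).T

        self.n_samples_ = int(n_samples)
        self.doc_topic_ = n_dk
        self.word_topic_ = n_wk
        self.theta_ = theta
        self.phi_ = phi
        self.components_ = phi
        self.z_ = z
        self.token_doc_ = doc_ids
        self.token_word_ = word_ids
        self.assignment_freq_ = freq / n_samples if track else None
        self.vocab_size_ = vocab
        self.n_cells_ = n_docs
        return self

    def _fit_partitioned(
        self, cfg, doc_ids, word_ids, z, n_dk, n_wk, n_k,
        a, b_v, beta_total, burn_in, take_sample,
    ) -> int:
        """Approximate-distributed sweeps: shard documents, sync counts each sweep."""
        n_docs = n_dk.shape[0]
        bounds = np.linspace(0, n_docs, cfg.n_workers + 1).astype(int)
        shard_of_doc = np.searchsorted(bounds, doc_ids, side="right") - 1
        shards = [np.nonzero(shard_of_doc == s)[0] for s in range(cfg.n_workers)]
        shards = [s for s in shards if s.size]
        n_samples = 0
        dummy = np.zeros((1, cfg.n_topics), dtype=np.int64)
        for sweep in range(cfg.iterations):
            global_nwk = n_wk.copy()
            global_nk = n_k.copy()
            deltas_wk = np.zeros_like(n_wk)
            for s, tok in enumerate(shards):
                local_nwk = global_nwk.copy()
                local_nk = global_nk.copy()
                zs = z[tok].copy()
                gibbs_train(
                    doc_ids[tok], word_ids[tok], zs, n_dk,
                    local_nwk, local_nk, a, b_v, beta_total,
                    1, 2, 1,  # one sweep, no sampling inside
                    _derive_seed(cfg.seed, "shard", s, sweep),
                    dummy, dummy, dummy, False,
                )
                z[tok] = zs
                deltas_wk += local_nwk - global_nwk
            n_wk[:] = global_nwk + deltas_wk
            n_k[:] = n_wk.sum(axis=0)
            if sweep >= burn_in and (sweep - burn_in) % cfg.sample_stride == 0:
                take_sample(n_samples)
                n_samples += 1
        return n_samples

    def transform(self, X, iterations: int = 500, seed: int | None = None):
        """Infer theta rows for new cells with the fitted phi held fixed.

        Peaks outside the training vocabulary must be dropped by the caller
        (the matrix must share the model's peak axis). Each cell runs its own
        chain with an RNG stream keyed by the cell identifier, so permuting
        cells permutes the output rows identically. Cells with no
        in-vocabulary token get the prior-mean row with a warning.
        """
        cfg = self._config()
        ids, x = _cells_and_matrix(X, self.vocab_size_)
        a, _, alpha_total, _ = cfg.per_component(self.vocab_size_)
        master = self.seed if seed is None else seed
        burn = iterations // 2
        theta = np.empty((x.shape[0], cfg.n_topics))
        prior_row = np.full(cfg.n_topics, 1.0 / cfg.n_topics)
        for i in range(x.shape[0]):
            words = x.indices[x.indptr[i]: x.indptr[i + 1]].astype(np.int64)
            if words.size == 0:
                warnings.warn(
                    f"cell {ids[i]!r} has no in-vocabulary peaks; returning prior mean",
                    stacklevel=2,
                )
                theta[i] = prior_row
                continue
            theta[i] = gibbs_predict_doc(
                words, self.phi_, a, alpha_total,
                iterations, burn, max(1, cfg.sample_stride // 4),
                _derive_seed(master, "predict", ids[i]),
            )
        return theta

    def to_model(self, cells=None, peaks=None) -> LDAModel:
        """Package the fitted state as an :class:`LDAModel`."""
        cells = pd.Index(cells) if cells is not None else pd.RangeIndex(self.n_cells_)
        peaks = pd.Index(peaks) if peaks is not None else pd.RangeIndex(self.vocab_size_)
        return LDAModel(
            config=self._config(), cells=cells, peaks=peaks,
            doc_topic=self.doc_topic_, word_topic=self.word_topic_,
            theta=self.theta_, phi=self.phi_, assignments=self.z_,
            token_doc=self.token_doc_, token_word=self.token_word_,
            assignment_freq=self.assignment_freq_,
        )


def _cells_and_matrix(X, vocab_size: int) -> tuple[list, sp.csr_matrix]:
    if isinstance(X, CellsByPeaksMatrix):
        ids = list(X.cells)
        x = X.matrix
    else:
        x = sp.csr_matrix(X)
        ids = list(range(x.shape[0]))
    if x.shape[1] != vocab_size:
        raise ValueError(
            f"matrix has {x.shape[1]} peaks, model vocabulary is {vocab_size}"
        )
    return ids, sp.csr_matrix(x)


def fit_lda(matrix: CellsByPeaksMatrix, config: LDAConfig) -> LDAModel:
    """Train a collapsed-Gibbs LDA model on a filtered cells-by-peaks matrix."""
    est = LatentDirichletAllocationGibbs(**asdict(config))
    est.fit(matrix)
    cells = matrix.cells if isinstance(matrix, CellsByPeaksMatrix) else None
    peaks = matrix.peaks if isinstance(matrix, CellsByPeaksMatrix) else None
    return est.to_model(cells, peaks)


def predict_theta(
    model: LDAModel, new_cells, iterations: int = 500, seed: int | None = None
) -> np.ndarray:
    """Theta rows for new cells with the model's phi held fixed."""
    est = LatentDirichletAllocationGibbs(**asdict(model.config))
    est.phi_ = model.phi
    est.vocab_size_ = model.phi.shape[1]
    est.n_cells_ = model.theta.shape[0]
    return est.transform(new_cells, iterations=iterations, seed=seed)


# ---------------------------------------------------------------------------
# BOW corpus dialect: header lines D, V, NNZ; one line per document
# "doc_len term_id:1 term_id:1 ..." with 0-based term ids.
# ---------------------------------------------------------------------------

def export_bow(m: CellsByPeaksMatrix, path) -> None:
    """Write the sparse binary corpus in the BOW dialect (lossless)."""
    x = m.matrix.tocsr()
    if x.nnz == 0:
        raise ValueError("refusing to export an empty matrix")
    with open(path, "w") as fh:
        fh.write(f"{x.shape[0]}\n{x.shape[1]}\n{x.nnz}\n")
        for i in range(x.shape[0]):
            terms = x.indices[x.indptr[i]: x.indptr[i + 1]]
            parts = " ".join(f"{t}:1" for t in np.sort(terms))
            fh.write(f"{terms.size} {parts}".rstrip() + "\n")


def import_bow(path, cells=None, peaks=None) -> CellsByPeaksMatrix:
    """Read a BOW corpus back into a binary cells-by-peaks matrix."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        n_docs, vocab, nnz = (int(lines[i]) for i in range(3))
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed BOW header") from exc
    rows, cols = [], []
    seen_dup = False
    for d in range(n_docs):
        lineno = 3 + d
        try:
            fields = lines[lineno].split()
            doc_len = int(fields[0])
            terms = [int(f.split(":")[0]) for f in fields[1:]]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno + 1}: malformed BOW document line") from exc
        if len(terms) != doc_len:
            raise ValueError(
                f"{path}:{lineno + 1}: declared length {doc_len} != {len(terms)} terms"
            )
        uniq = sorted(set(terms))
        if len(uniq) != len(terms):
            seen_dup = True
        rows.extend([d] * len(uniq))
        cols.extend(uniq)
    if seen_dup:
        warnings.warn("duplicate (doc, term) entries collapsed to binary", stacklevel=2)
    m = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n_docs, vocab)
    ).tocsr()
    return CellsByPeaksMatrix(
        m,
        pd.Index(cells) if cells is not None else pd.RangeIndex(n_docs).astype(str),
        pd.Index(peaks) if peaks is not None else pd.RangeIndex(vocab).astype(str),
    )
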