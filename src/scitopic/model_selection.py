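"""Topic-number selection by cross-validated held-out perplexity.

Cells are split evenly and randomly into disjoint folds (default five). For
each candidate topic count K, one model is trained per fold on the remaining
folds and scored on the held-out fold: with the trained peak-topic
probabilities (phi) fixed, the marginal log-likelihood of each held-out cell
is estimated with a Chib-style estimator, and converted to per-cell
perplexity ``exp(-L / N)`` where N is the cell's token count. The
recommended K minimizes the mean held-out perplexity (ties toward smaller
K); the model actually trained downstream uses ``ceil(1.5 * recommended)``
topics, since the sampler tolerates a few surplus topics but suffers from
too few.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from ._gibbs import chib_loglik_doc
from .lda import LDAConfig, LatentDirichletAllocationGibbs, _derive_seed
from .matrix import CellsByPeaksMatrix

logger = logging.getLogger(__name__)


@dataclass
class HeldOutResult:
    """Chib-style held-out score for one cell."""

    cell: object
    loglik: float      # nats
    n_tokens: int

    @property
    def perplexity(self) -> float:
        return math.exp(-self.loglik / self.n_tokens)


def cv_split(cell_ids, folds: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Evenly and randomly split cell ids into disjoint folds (sizes differ <= 1)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ids = np.asarray(cell_ids)
    if ids.size < folds:
        raise ValueError(f"need at least {folds} cells, got {ids.size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    return [ids[np.sort(chunk)] for chunk in np.array_split(perm, folds)]


def heldout_loglik_chib(
    phi: np.ndarray,
    tokens: np.ndarray,
    alpha: float,
    iterations: int = 600,
    seed: int = 0,
    cell=None,
    prior_style: str = "total",
    n_chains: int = 4,
) -> HeldOutResult:
    """Estimate log p(tokens | phi, alpha) for one held-out cell.

    ``tokens`` are the cell's in-vocabulary word indices. A Gibbs chain is
    run over the cell's topic assignments with phi fixed; the pivot z* is the
    maximum-joint-probability state visited after burn-in, and the marginal
    likelihood is ``log p(w, z*) - log p̂(z* | w)`` with ``p̂`` estimated by
    averaging the one-sweep transition kernel from states along the chain
    (the Chib / document-completion family).
    """
    phi = np.asarray(phi, dtype=float)
    if not np.allclose(phi.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("phi rows must be proper distributions")
    tokens = np.asarray(tokens, dtype=np.int64)
    if tokens.size == 0:
        raise ValueError("held-out cell has zero tokens")
    n_topics = phi.shape[0]
    if prior_style == "total":
        a, alpha_total = alpha / n_topics, alpha
    else:
        a, alpha_total = alpha, alpha * n_topics
    burn = iterations // 2
    loglik = chib_loglik_doc(
        tokens, phi, a, alpha_total, iterations, burn, 2, seed & 0x7FFFFFFF,
        n_chains=n_chains,
    )
    return HeldOutResult(cell=cell, loglik=float(loglik), n_tokens=int(tokens.size))


@dataclass
class CVReport:
    """Cross-validation summary over a grid of topic counts."""

    k_grid: list[int]
    fold_perplexities: dict[int, list[float]]  # K -> per-fold mean perplexity
    mean_perplexity: dict[int, float]
    spread: dict[int, float]                   # std over folds
    recommended_k: int
    final_k: int
    failures: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "k_grid": self.k_grid,
            "fold_perplexities": {str(k): v for k, v in self.fold_perplexities.items()},
            "mean_perplexity": {str(k): v for k, v in self.mean_perplexity.items()},
            "spread": {str(k): v for k, v in self.spread.items()},
            "recommended_k": self.recommended_k,
            "final_k": self.final_k,
            "failures": self.failures,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def final_topic_count(recommended: int, factor: float = 1.5) -> int:
    """Surplus-topic rule: train with ceil(factor * recommended) topics."""
    return math.ceil(factor * recommended)


def select_num_topics(
    matrix: CellsByPeaksMatrix,
    k_grid,
    folds: int = 5,
    seed: int = 0,
    alpha: float = 3.0,
    beta: float = 2000.0,
    iterations: int = 400,
    sample_stride: int = 10,
    chib_iterations: int = 600,
    prior_style: str = "total",
) -> CVReport:
    """Cross-validated search over topic counts, scored by held-out perplexity."""
    k_grid = sorted(int(k) for k in k_grid)
    if not k_grid:
        raise ValueError("empty topic-count grid")
    x = matrix.matrix.tocsr() if isinstance(matrix, CellsByPeaksMatrix) else sp.csr_matrix(matrix)
    n_cells = x.shape[0]
    fold_idx = cv_split(np.arange(n_cells), folds=folds, seed=seed)

    fold_perp: dict[int, list[float]] = {k: [] for k in k_grid}
    failures: list[str] = []
    for k in k_grid:
        for f, held in enumerate(fold_idx):
            try:
                train_mask = np.ones(n_cells, dtype=bool)
                train_mask[held] = False
                est = LatentDirichletAllocationGibbs(
                    n_topics=k, alpha=alpha, beta=beta, iterations=iterations,
                    sample_stride=sample_stride,
                    seed=_derive_seed(seed, "cv", k, f),
                    prior_style=prior_style,
                )
                est.fit(x[train_mask])
                perps = []
                for j, cell in enumerate(held):
                    tokens = x.indices[x.indptr[cell]: x.indptr[cell + 1]]
                    if tokens.size == 0:
                        continue
                    res = heldout_loglik_chib(
                        est.phi_, tokens, alpha,
                        iterations=chib_iterations,
                        seed=_derive_seed(seed, "chib", k, f, j),
                        cell=cell, prior_style=prior_style,
                    )
                    perps.append(res.perplexity)
                fold_perp[k].append(float(np.mean(perps)))
            except Exception as exc:  # partial report with failure flags
                failures.append(f"K={k} fold={f}: {exc}")
                logger.warning("CV failure at K=%d fold=%d: %s", k, f, exc)

    mean_perp = {k: float(np.mean(v)) if v else float("inf") for k, v in fold_perp.items()}
    spread = {k: float(np.std(v)) if v else float("nan") for k, v in fold_perp.items()}
    recommended = min(k_grid, key=lambda k: (mean_perp[k], k))
    return CVReport(
        k_grid=k_grid,
        fold_perplexities=fold_perp,
        mean_perplexity=mean_perp,
        spread=spread,
        recommended_k=recommended,
        final_k=final_topic_count(recommended),
        failures=failures,
    )


class TopicCountCV(BaseEstimator):
    """Estimator wrapper around :func:`select_num_topics` (GridSearchCV-style).

    After ``fit``, exposes ``report_``, ``recommended_k_`` and ``final_k_``.
    """

    def __init__(
        self, k_grid=(5, 10, 20), folds: int = 5, seed: int = 0,
        alpha: float = 3.0, beta: float = 2000.0, iterations: int = 400,
        sample_stride: int = 10, chib_iterations: int = 600,
        prior_style: str = "total",
    ):
        self.k_grid = k_grid
        self.folds = folds
        self.seed = seed
        self.alpha = alpha
        self.beta = beta
        self.iterations = iterations
        self.sample_stride = sample_stride
        self.chib_iterations = chib_iterations
        self.prior_style = prior_style

    def fit(self, X, y=None):
        self.report_ = select_num_topics(
            X, self.k_grid, folds=self.folds, seed=self.seed, alpha=self.alpha,
            beta=self.beta, iterations=self.iterations,
            sample_stride=self.sample_stride,
            chib_iterations=self.chib_iterations, prior_style=self.prior_style,
        )
        self.recommended_k_ = self.report_.recommended_k
        self.final_k_ = self.report_.final_k
        return self
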