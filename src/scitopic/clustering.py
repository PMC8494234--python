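"""Cell clustering from LDA topic mixtures.

Topics that correspond to coherent groups of cells are found by a centroid
score: for each topic, the 50 cells with the highest probability for the
topic define a centroid (their mean theta row), and the topic's score is the
mean dot product of those rows with the centroid. Topics scoring above 0.2
become candidate cell-type clusters; a cell joins a cluster outright when it
puts more than 50% of its probability on the cluster's topic (strict, so at
most one cluster can claim a cell). Small clusters (< 150 cells) are grown
by recruiting nearby unassigned cells in a 10-dimensional embedding of theta,
and clusters still below 50 cells are dissolved because they would have too
little pooled coverage for peak calling.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import KDTree
from sklearn.preprocessing import normalize

from .lda import _derive_seed

logger = logging.getLogger(__name__)

#: Label used for cells not assigned to any topic cluster.
UNASSIGNED = -1


def topic_centroid_score(theta: np.ndarray, topic: int, top_n: int = 50) -> float:
    """Cohesion of a topic's top cells around their centroid, in [0, 1].

    Cells are ranked by ``theta[:, topic]`` descending (ties in stable order
    by cell index); the score is the mean dot product between the top
    ``top_n`` rows and their mean row.
    """
    theta = np.asarray(theta)
    if theta.shape[0] < top_n:
        warnings.warn(
            f"only {theta.shape[0]} cells for top_n={top_n}; using all",
            stacklevel=2,
        )
        top_n = theta.shape[0]
    order = np.argsort(-theta[:, topic], kind="stable")[:top_n]
    rows = theta[order]
    centroid = rows.mean(axis=0)
    return float((rows @ centroid).mean())


def select_cluster_topics(
    theta: np.ndarray, threshold: float = 0.2, top_n: int = 50
) -> list[int]:
    """Topics whose centroid score exceeds ``threshold``, ranked by score."""
    theta = np.asarray(theta)
    scores = [topic_centroid_score(theta, t, top_n=top_n) for t in range(theta.shape[1])]
    selected = [t for t in range(theta.shape[1]) if scores[t] > threshold]
    if not selected:
        warnings.warn("no topic exceeds the centroid-score threshold", stacklevel=2)
    return sorted(selected, key=lambda t: -scores[t])


def assign_cells(theta: np.ndarray, selected_topics) -> np.ndarray:
    """Per-cell labels by the strict >50% rule; UNASSIGNED (-1) otherwise."""
    theta = np.asarray(theta)
    labels = np.full(theta.shape[0], UNASSIGNED, dtype=np.int64)
    selected = list(selected_topics)
    if not selected:
        return labels
    sub = theta[:, selected]
    best = np.argmax(sub, axis=1)
    best_p = sub[np.arange(theta.shape[0]), best]
    hit = best_p > 0.5
    labels[hit] = np.asarray(selected)[best[hit]]
    return labels


def _step_kernel(half_width: int = 10) -> np.ndarray:
    """Difference-of-steps kernel (-1 x half, 0, +1 x half): a slope detector."""
    return np.concatenate(
        [-np.ones(half_width), [0.0], np.ones(half_width)]
    )


def _distance_jump_convolution(distances: np.ndarray, half_width: int = 10) -> np.ndarray:
    """Correlate ranked distances with the step kernel (edge-replicated)."""
    kernel = _step_kernel(half_width)
    padded = np.pad(distances, half_width, mode="edge")
    return np.correlate(padded, kernel, mode="valid")


def augment_small_clusters(
    labels: np.ndarray,
    coords: np.ndarray,
    min_size: int = 150,
    seed: int = 0,
    kde_samples: int = 200,
    neighbor_factor: float = 1.25,
    iqr_factor: float = 1.5,
) -> np.ndarray:
    """Grow clusters below ``min_size`` by recruiting nearby unassigned cells.

    Per small cluster (processed in ascending size order), iteratively:
    estimate the cluster centroid as the mean of ``kde_samples`` draws from a
    Gaussian KDE of the member coordinates; query the ``ceil(neighbor_factor
    * size)`` nearest cells to the centroid; correlate the ranked neighbor
    distances with a step kernel to locate distance jumps; and admit the
    closest unassigned neighbor whose convolution value does not exceed
    ``iqr_factor`` times the IQR of all convolution values. Existing labels
    are never changed — only unassigned cells can be recruited.
    """
    labels = np.asarray(labels).copy()
    coords = np.asarray(coords, dtype=float)
    tree = KDTree(coords)
    cluster_ids, sizes = np.unique(labels[labels != UNASSIGNED], return_counts=True)
    rng_round = 0
    for cid in cluster_ids[np.argsort(sizes, kind="stable")]:
        members = np.nonzero(labels == cid)[0]
        if members.size >= min_size:
            continue
        if members.size < 2:
            warnings.warn(
                f"cluster {cid} has {members.size} member(s); KDE undefined, skipped",
                stacklevel=2,
            )
            continue
        while members.size < min_size:
            pts = coords[members].T
            try:
                kde = gaussian_kde(pts)
                draws = kde.resample(
                    kde_samples, seed=_derive_seed(seed, "kde", int(cid), rng_round)
                )
                centroid = draws.mean(axis=1)
            except np.linalg.LinAlgError:
                # degenerate member covariance (e.g. zero-padded embedding
                # dimensions): fall back to the plain member mean
                centroid = coords[members].mean(axis=0)
            rng_round += 1
            k = min(coords.shape[0], math.ceil(neighbor_factor * members.size))
            dist, idx = tree.query(centroid[None, :], k=k)
            dist, idx = dist[0], idx[0]  # sorted ascending by distance
            conv = _distance_jump_convolution(dist)
            q75, q25 = np.percentile(conv, [75, 25])
            cutoff = iqr_factor * (q75 - q25)
            added = False
            for j in range(k):
                if labels[idx[j]] != UNASSIGNED:
                    continue
                if conv[j] > cutoff:
                    continue
                labels[idx[j]] = cid
                members = np.nonzero(labels == cid)[0]
                added = True
                break
            if not added:
                break
    return labels


@dataclass
class ClusterReport:
    dissolved: dict[int, int] = field(default_factory=dict)  # topic -> size


def drop_small_clusters(
    labels: np.ndarray, min_cells: int = 50
) -> tuple[np.ndarray, ClusterReport]:
    """Dissolve clusters with fewer than ``min_cells`` members."""
    labels = np.asarray(labels).copy()
    report = ClusterReport()
    for cid in np.unique(labels[labels != UNASSIGNED]):
        n = int((labels == cid).sum())
        if n < min_cells:
            report.dissolved[int(cid)] = n
            labels[labels == cid] = UNASSIGNED
    if report.dissolved:
        logger.info("dissolved %d clusters below %d cells", len(report.dissolved), min_cells)
    return labels, report


def embed_theta(
    theta: np.ndarray,
    n_dims: int = 2,
    seed: int = 0,
    method="umap",
    **kwargs,
) -> np.ndarray:
    """L2-normalize theta rows, then reduce to ``n_dims`` coordinates.

    ``method`` is "umap" (default; deterministic given seed), "pca" (a fast
    deterministic fallback that keeps duplicate rows coincident), or any
    callable ``f(X, n_dims, seed) -> coords``.
    """
    theta = np.asarray(theta, dtype=float)
    norms = np.linalg.norm(theta, axis=1)
    if (norms == 0).any():
        raise ValueError("theta has all-zero rows")
    x = normalize(theta, norm="l2")
    if callable(method):
        return np.asarray(method(x, n_dims, seed))
    if method == "pca":
        n = min(n_dims, min(x.shape) - 1) or 1
        coords = PCA(n_components=n, random_state=seed).fit_transform(x)
        if coords.shape[1] < n_dims:  # pad so downstream shapes are stable
            coords = np.hstack(
                [coords, np.zeros((coords.shape[0], n_dims - coords.shape[1]))]
            )
        return coords
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=n_dims, random_state=seed, **kwargs)
        return np.asarray(reducer.fit_transform(x))
    raise ValueError(f"unknown embedding method {method!r}")


@dataclass
class TopicClustering:
    """Full clustering output: topics, labels, scores, embeddings."""

    selected_topics: list[int]
    centroid_scores: np.ndarray
    labels: np.ndarray
    assigned_by: np.ndarray  # "probability" | "augmentation" | ""
    embedding2: np.ndarray | None
    embedding10: np.ndarray | None
    dissolved: dict[int, int]

    def member_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels != UNASSIGNED], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


class TopicClusterer(ClusterMixin, BaseEstimator):
    """Topic-cluster assignment pipeline as an sklearn-style clusterer.

    ``fit(theta)`` runs: centroid scoring -> topic selection (score > 0.2)
    -> strict >50% assignment -> growth of small clusters in a 10-D
    embedding -> dissolution of clusters below the 50-cell floor. Exposes
    ``labels_``, ``selected_topics_``, ``centroid_scores_``, ``embedding2_``
    and ``embedding10_``.
    """

    def __init__(
        self,
        threshold: float = 0.2,
        top_n: int = 50,
        min_grow: int = 150,
        min_keep: int = 50,
        seed: int = 0,
        embed_method="umap",
        compute_2d: bool = True,
    ):
        self.threshold = threshold
        self.top_n = top_n
        self.min_grow = min_grow
        self.min_keep = min_keep
        self.seed = seed
        self.embed_method = embed_method
        self.compute_2d = compute_2d

    def fit(self, X, y=None):
        theta = np.asarray(X, dtype=float)
        scores = np.array(
            [topic_centroid_score(theta, t, top_n=self.top_n) for t in range(theta.shape[1])]
        )
        selected = [t for t in np.argsort(-scores, kind="stable") if scores[t] > self.threshold]
        labels = assign_cells(theta, selected)
        assigned_by = np.where(labels != UNASSIGNED, "probability", "")

        needs_growth = any(
            0 < (labels == t).sum() < self.min_grow for t in selected
        )
        emb10 = None
        if needs_growth:
            emb10 = embed_theta(theta, n_dims=10, seed=self.seed, method=self.embed_method)
            grown = augment_small_clusters(labels, emb10, min_size=self.min_grow, seed=self.seed)
            assigned_by = np.where(
                (grown != labels) & (grown != UNASSIGNED), "augmentation", assigned_by
            )
            labels = grown
        labels, report = drop_small_clusters(labels, min_cells=self.min_keep)
        assigned_by = np.where(labels == UNASSIGNED, "", assigned_by)

        emb2 = None
        if self.compute_2d:
            emb2 = embed_theta(theta, n_dims=2, seed=self.seed, method=self.embed_method)

        self.centroid_scores_ = scores
        self.selected_topics_ = [int(t) for t in selected]
        self.labels_ = labels
        self.assigned_by_ = assigned_by
        self.embedding2_ = emb2
        self.embedding10_ = emb10
        self.dissolved_ = report.dissolved
        return self

    def to_clustering(self) -> TopicClustering:
        return TopicClustering(
            selected_topics=self.selected_topics_,
            centroid_scores=self.centroid_scores_,
            labels=self.labels_,
            assigned_by=self.assigned_by_,
            embedding2=self.embedding2_,
            embedding10=self.embedding10_,
            dissolved=self.dissolved_,
        )
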