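"""Topic/tissue interpretation statistics.

Links topics to tissues by three routes: (1) topic-specific peaks near genes
with tissue-specific expression (gene assignment by nearest downstream exon
within 1200 bp, tissue enrichment against random gene draws); (2) overlap of
topic peaks with TF ChIP compendia (HOT sites excluded, null by drawing
peaks proportionally to per-topic peak counts); (3) per-stage overlap
enrichment for external peak sets assigned to stages by z-score. Also
provides the interval overlap/Fisher statistics, signal enrichment over
shuffled peaks, and the entropy / peak-diversity summary of how
tissue-specific a gene's regulation is relative to its expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import entropy as _shannon_entropy
from scipy.stats import fisher_exact, zscore

from .matrix import CellsByPeaksMatrix
from .peaks import PeakSet, SignalTrack, merge_peak_sets
from .preprocess import GenomeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """A stranded gene with exon intervals (0-based, half-open)."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    body: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        lo, hi = self.body
        for s, e in self.exons:
            if s < lo or e > hi:
                raise ValueError(f"exon outside gene body for {self.gene_id}")


# ---------------------------------------------------------------------------
# interval helpers (merged, sorted interval sets)
# ---------------------------------------------------------------------------

def _overlaps_any(
    chrom: str, start: int, end: int, other: PeakSet
) -> bool:
    s, e = other.intervals(chrom)
    if s.size == 0:
        return False
    lo = np.searchsorted(e, start, side="right")
    return lo < s.size and s[lo] < end


def count_element_overlaps(a: PeakSet, b: PeakSet) -> int:
    """Number of intervals in ``a`` overlapping >= 1 bp of ``b``."""
    n = 0
    for _, r in a.df.iterrows():
        if _overlaps_any(r["chrom"], int(r["start"]), int(r["end"]), b):
            n += 1
    return n


def _intersection_bp(a: PeakSet, b: PeakSet) -> int:
    total = 0
    chroms = set(a.df["chrom"]) & set(b.df["chrom"])
    for chrom in chroms:
        sa, ea = a.intervals(chrom)
        sb, eb = b.intervals(chrom)
        i = j = 0
        while i < sa.size and j < sb.size:
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += hi - lo
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return int(total)


# ---------------------------------------------------------------------------
# topic specificity and topic peak sets
# ---------------------------------------------------------------------------

def topic_specificity(
    matrix: CellsByPeaksMatrix, labels: np.ndarray, topic: int
) -> pd.Series:
    """Fraction of each peak's carrying cells that belong to the topic cluster.

    Peaks detected in zero cells are undefined and returned as NaN with a
    warning.
    """
    x = sp.csc_matrix(matrix.matrix)
    labels = np.asarray(labels)
    carriers = np.asarray(x.sum(axis=0)).ravel()
    in_cluster = np.asarray(x[labels == topic].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(carriers > 0, in_cluster / np.maximum(carriers, 1), np.nan)
    if (carriers == 0).any():
        warnings.warn(
            f"{int((carriers == 0).sum())} peaks have no carrying cells; "
            "specificity undefined (NaN)",
            stacklevel=2,
        )
    return pd.Series(frac, index=matrix.peaks, name=f"topic_{topic}")


def top_topic_peaks(
    specificities: pd.Series, n: int = 250, floor: float = 0.5
) -> pd.Index:
    """Top-``n`` peaks by specificity, or all above ``floor`` if more.

    Ties are broken deterministically by peak identifier (coordinate order).
    """
    s = specificities.dropna()
    above = s[s > floor]
    if len(above) >= n:
        chosen = above
    else:
        order = sorted(s.index, key=lambda p: (-s[p], str(p)))
        chosen = s.loc[order[:n]]
    order = sorted(chosen.index, key=lambda p: (-chosen[p], str(p)))
    return pd.Index(order)


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

def nearest_downstream_gene(
    peak,
    annotations,
    max_dist: int = 1200,
    allow_overlap: bool = False,
) -> str | None:
    """Assign a peak to the gene whose nearest exon lies downstream of it.

    "Downstream" is in the gene's orientation: on the + strand the exon
    starts at or after the peak end; on the - strand the exon ends at or
    before the peak start. Overlapping peak-exon pairs count as distance 0
    only when ``allow_overlap`` is set. Nearest by stranded gap, ties by
    gene id then exon coordinate.
    """
    chrom, pstart, pend = peak[0], int(peak[1]), int(peak[2])
    best: tuple[int, str] | None = None
    for gene in annotations:
        if gene.chrom != chrom:
            continue
        for (es, ee) in gene.exons:
            overlap = es < pend and ee > pstart
            if overlap:
                if not allow_overlap:
                    continue
                gap = 0
            elif gene.strand == "+" and es >= pend:
                gap = es - pend
            elif gene.strand == "-" and ee <= pstart:
                gap = pstart - ee
            else:
                continue  # exon upstream of the peak in the gene frame
            if gap <= max_dist:
                cand = (gap, gene.gene_id)
                if best is None or cand < best:
                    best = cand
    return best[1] if best else None


def assign_peaks_to_genes(
    peaks: PeakSet, annotations, max_dist: int = 1200, allow_overlap: bool = False
) -> dict[str, str]:
    """Map peak id -> gene id by :func:`nearest_downstream_gene`."""
    out = {}
    for _, r in peaks.df.iterrows():
        gid = nearest_downstream_gene(
            (r["chrom"], r["start"], r["end"]), annotations,
            max_dist=max_dist, allow_overlap=allow_overlap,
        )
        if gid is not None:
            out[f"{r['chrom']}:{r['start']}-{r['end']}"] = gid
    return out


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Observed-vs-null comparison with percentile confidence intervals."""

    categories: list
    observed: np.ndarray
    null_mean: np.ndarray
    log2_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_random: int
    flags: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed": self.observed,
                "null_mean": self.null_mean,
                "log2_ratio": self.log2_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            },
            index=pd.Index(self.categories, name="category"),
        )


def _percentile_ci(ratios: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.percentile(ratios, 2.5, axis=0),
        np.percentile(ratios, 97.5, axis=0),
    )


def tissue_enrichment(
    gene_set,
    table: pd.DataFrame,
    n_random: int = 100,
    sample_size: int = 250,
    seed: int = 0,
) -> EnrichmentResult:
    """Tissue-expression enrichment of a gene set against random gene draws.

    Each gene's expression row is normalized to a distribution over tissues;
    the observed profile is the mean distribution over ``gene_set``. For each
    of ``n_random`` draws of ``sample_size`` genes, the per-tissue log2 ratio
    of observed to draw mean is recorded; the result reports the mean ratio
    and the 2.5/97.5 percentile interval over draws.
    """
    gene_set = [g for g in gene_set]
    if not gene_set:
        raise ValueError("empty gene set")
    rowsum = table.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} genes with all-zero expression",
                      stacklevel=2)
        table = table.loc[~zero]
        rowsum = rowsum[~zero]
    dist = table.div(rowsum, axis=0)

    present = [g for g in gene_set if g in dist.index]
    missing = len(gene_set) - len(present)
    if missing:
        logger.info("tissue_enrichment: %d genes missing from the table", missing)
    if not present:
        raise ValueError("no gene of the set is present in the expression table")
    observed = dist.loc[present].mean(axis=0).to_numpy()

    rng = np.random.default_rng(seed)
    all_genes = dist.index.to_numpy()
    ratios = np.empty((n_random, dist.shape[1]))
    null_means = np.empty_like(ratios)
    for r in range(n_random):
        take = rng.choice(
            all_genes, size=min(sample_size, all_genes.size),
            replace=all_genes.size < sample_size,
        )
        null = dist.loc[take].mean(axis=0).to_numpy()
        null_means[r] = null
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios[r] = np.log2(observed / null)
    lo, hi = _percentile_ci(ratios)
    return EnrichmentResult(
        categories=list(table.columns),
        observed=observed,
        null_mean=null_means.mean(axis=0),
        log2_ratio=ratios.mean(axis=0),
        ci_low=lo, ci_high=hi, n_random=n_random,
    )


def filter_hot_sites(tf_peaks: pd.DataFrame, max_other: int = 40) -> pd.DataFrame:
    """Drop high-occupancy-target sites (seen in >= ``max_other`` + 1 experiments)."""
    return tf_peaks[tf_peaks["occupancy"] < max_other + 1].reset_index(drop=True)


def chip_overlap_enrichment(
    topic_peak_sets: dict,
    tf_peaks: PeakSet,
    topic_peak_counts: dict,
    n_random: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Per-topic enrichment of TF ChIP overlaps against a size-matched null.

    ``topic_peak_sets`` maps topic -> PeakSet of the topic's peaks (those
    with topic probability above zero); ``topic_peak_counts`` maps topic ->
    total peak count, which sets the null draw probabilities. The null draws
    the observed total number of overlapping peaks with per-topic
    probabilities proportional to the counts. Zero cells (observed or null)
    get a 0.5 pseudo-count and are flagged.
    """
    if not len(tf_peaks):
        raise ValueError("empty TF peak set")
    topics = sorted(topic_peak_sets)
    observed = np.array(
        [count_element_overlaps(topic_peak_sets[t], tf_peaks) for t in topics],
        dtype=float,
    )
    total = int(observed.sum())
    counts = np.array([topic_peak_counts[t] for t in topics], dtype=float)
    probs = counts / counts.sum()
    rng = np.random.default_rng(seed)
    flags = {}
    ratios = np.empty((n_random, len(topics)))
    null_draws = rng.multinomial(total, probs, size=n_random).astype(float)
    obs = observed.copy()
    if (obs == 0).any():
        flags["zero_observed_topics"] = [t for t, o in zip(topics, observed) if o == 0]
        obs = np.where(obs == 0, 0.5, obs)
    null = np.where(null_draws == 0, 0.5, null_draws)
    ratios = np.log2(obs[None, :] / null)
    lo, hi = _percentile_ci(ratios)
    return EnrichmentResult(
        categories=topics, observed=observed, null_mean=null_draws.mean(axis=0),
        log2_ratio=ratios.mean(axis=0), ci_low=lo, ci_high=hi,
        n_random=n_random, flags=flags,
    )


def assign_stages_by_zscore(
    signal: pd.DataFrame, z_threshold: float = 1.5
) -> dict[str, list]:
    """Assign each peak (row) to stages where its z-scored signal >= threshold.

    Rows with no variation across stages get z = 0 everywhere and are
    assigned nowhere.
    """
    z = zscore(signal.to_numpy(dtype=float), axis=1, nan_policy="omit")
    z = np.nan_to_num(z, nan=0.0)
    out: dict[str, list] = {stage: [] for stage in signal.columns}
    for i, peak in enumerate(signal.index):
        for j, stage in enumerate(signal.columns):
            if z[i, j] >= z_threshold:
                out[stage].append(peak)
    return out


def stage_enrichment(
    query_peaks: PeakSet,
    stage_sets: dict,
    universe: PeakSet,
    n_random: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Per-stage overlap enrichment of a query set vs random size-matched sets.

    Observed = per-stage count of query peaks overlapping the stage's peak
    set; the null repeatedly samples ``len(query_peaks)`` peaks from
    ``universe`` and counts the same overlaps.
    """
    stages = sorted(stage_sets)
    observed = np.array(
        [count_element_overlaps(query_peaks, stage_sets[s]) for s in stages],
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    n_universe = len(universe)
    ratios = np.empty((n_random, len(stages)))
    null_counts = np.empty_like(ratios)
    for r in range(n_random):
        take = rng.choice(n_universe, size=min(len(query_peaks), n_universe),
                          replace=n_universe < len(query_peaks))
        sample = PeakSet(universe.df.iloc[np.sort(take)])
        null_counts[r] = [
            count_element_overlaps(sample, stage_sets[s]) for s in stages
        ]
    obs = np.where(observed == 0, 0.5, observed)
    null = np.where(null_counts == 0, 0.5, null_counts)
    ratios = np.log2(obs[None, :] / null)
    lo, hi = _percentile_ci(ratios)
    return EnrichmentResult(
        categories=stages, observed=observed, null_mean=null_counts.mean(axis=0),
        log2_ratio=ratios.mean(axis=0), ci_low=lo, ci_high=hi, n_random=n_random,
    )


@dataclass
class OverlapStats:
    """Two-way element overlaps, base-pair totals, and the Fisher p-value."""

    a_in_b: int
    b_in_a: int
    bp_table: tuple[int, int, int, int]  # (A∩B, A-only, B-only, neither)
    genome_bp: int
    fisher_p: float

    @property
    def a_fraction_overlapping(self) -> float:
        return self.bp_table[0] / max(self.bp_table[0] + self.bp_table[1], 1)


def overlap_stats(a: PeakSet, b: PeakSet, genome: GenomeTable) -> OverlapStats:
    """Element overlaps and the base-pair 2x2 Fisher test (right-tailed).

    The 2x2 table partitions the genome's base pairs by membership in A and
    B; the right tail asks whether A and B share more bases than expected if
    intervals were placed independently. Inputs must be merged interval
    sets.
    """
    for ps in (a, b):
        for _, r in ps.df.iterrows():
            if r["chrom"] not in genome or r["end"] > genome[r["chrom"]]:
                raise ValueError(
                    f"interval {r['chrom']}:{r['start']}-{r['end']} exceeds genome"
                )
    inter = _intersection_bp(a, b)
    a_bp, b_bp = a.total_bp, b.total_bp
    n11 = inter
    n12 = a_bp - inter
    n21 = b_bp - inter
    n22 = genome.total_bp - (a_bp + b_bp - inter)
    _, p = fisher_exact([[n11, n12], [n21, n22]], alternative="greater")
    return OverlapStats(
        a_in_b=count_element_overlaps(a, b),
        b_in_a=count_element_overlaps(b, a),
        bp_table=(n11, n12, n21, n22),
        genome_bp=genome.total_bp,
        fisher_p=float(p),
    )


def shuffle_peaks(peaks: PeakSet, genome: GenomeTable, seed: int = 0,
                  max_tries: int = 1000) -> PeakSet:
    """Place each peak uniformly on its own chromosome, rejecting overlaps
    among the shuffled peaks (widths and per-chromosome counts preserved)."""
    rng = np.random.default_rng(seed)
    rows = []
    placed: dict[str, list[tuple[int, int]]] = {}
    for _, r in peaks.df.iterrows():
        chrom, width = r["chrom"], int(r["end"] - r["start"])
        ln = genome[chrom]
        if width > ln:
            raise ValueError(f"peak wider than chromosome {chrom}")
        for _ in range(max_tries):
            s = int(rng.integers(0, ln - width + 1))
            e = s + width
            if all(e <= ps or s >= pe for ps, pe in placed.get(chrom, [])):
                placed.setdefault(chrom, []).append((s, e))
                rows.append((chrom, s, e))
                break
        else:
            raise RuntimeError("could not place shuffled peak without overlap")
    return PeakSet.from_intervals(rows, source="shuffled")


def signal_enrichment_over_peaks(
    peaks: PeakSet,
    signal: SignalTrack,
    shuffled_peaks: PeakSet | None = None,
    genome: GenomeTable | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak log2(mean signal over peak / mean signal over its chromosome).

    Returns paired arrays for the true peaks and for same-chromosome
    non-overlapping shuffled peaks (generated internally when not given).
    Peaks on chromosomes with zero mean signal are skipped with a warning.
    """
    if shuffled_peaks is None:
        if genome is None:
            raise ValueError("provide either shuffled_peaks or a genome to shuffle on")
        shuffled_peaks = shuffle_peaks(peaks, genome, seed=seed)

    def _ratios(ps: PeakSet) -> np.ndarray:
        chrom_mean = {c: a.mean() for c, a in signal.arrays.items()}
        vals = []
        for _, r in ps.df.iterrows():
            cm = chrom_mean[r["chrom"]]
            if cm == 0:
                warnings.warn(
                    f"zero chromosome mean for {r['chrom']}; peak skipped", stacklevel=3
                )
                continue
            m = signal.region(r["chrom"], int(r["start"]), int(r["end"])).mean()
            vals.append(np.log2(m / cm) if m > 0 else -np.inf)
        return np.array(vals)

    return _ratios(peaks), _ratios(shuffled_peaks)


# ---------------------------------------------------------------------------
# entropy and peak diversity
# ---------------------------------------------------------------------------

def tissue_entropy(distribution, base: float = 2.0) -> float:
    """Shannon entropy (bits by default) of a non-negative tissue profile."""
    v = np.asarray(distribution, dtype=float)
    if (v < 0).any():
        raise ValueError("negative entries in distribution")
    if v.sum() <= 0:
        raise ValueError("zero distribution has no entropy")
    return float(_shannon_entropy(v, base=base))


def _linked_peaks(gene_id: str, peaks: PeakSet, annotations, max_dist: int = 1200):
    """Peaks assigned to the gene (nearest downstream exon, overlaps allowed)."""
    linked = []
    for _, r in peaks.df.iterrows():
        gid = nearest_downstream_gene(
            (r["chrom"], r["start"], r["end"]), annotations,
            max_dist=max_dist, allow_overlap=True,
        )
        if gid == gene_id:
            linked.append((r["chrom"], int(r["start"]), int(r["end"])))
    return linked


def mean_peak_entropy(
    gene_id: str,
    peaks: PeakSet,
    tissue_peak_sets: dict,
    annotations,
    max_dist: int = 1200,
    base: float = 2.0,
) -> float:
    """Mean tissue entropy of the peaks linked to a gene.

    Each linked peak's tissue profile is the count of overlapping peaks from
    each per-tissue set; its entropy summarizes how tissue-restricted the
    peak is. Genes with no linked peak are undefined (ValueError).
    """
    linked = _linked_peaks(gene_id, peaks, annotations, max_dist)
    if not linked:
        raise ValueError(f"gene {gene_id!r} has no linked peaks")
    tissues = sorted(tissue_peak_sets)
    entropies = []
    for chrom, s, e in linked:
        profile = np.array(
            [
                _count_overlapping(chrom, s, e, tissue_peak_sets[t])
                for t in tissues
            ],
            dtype=float,
        )
        if profile.sum() == 0:
            continue
        entropies.append(tissue_entropy(profile, base=base))
    if not entropies:
        raise ValueError(f"no linked peak of {gene_id!r} overlaps any tissue set")
    return float(np.mean(entropies))


def _count_overlapping(chrom: str, start: int, end: int, other: PeakSet) -> int:
    s, e = other.intervals(chrom)
    if s.size == 0:
        return 0
    lo = np.searchsorted(e, start, side="right")
    hi = np.searchsorted(s, end, side="left")
    return max(int(hi - lo), 0)


def peak_diversity_score(
    gene_id: str,
    tissue_peak_sets: dict,
    annotations,
    max_dist: int = 1200,
    dedup_signatures: bool = True,
) -> int:
    """Number of distinct tissue-combination patterns among a gene's peaks.

    The per-tissue peaks linked to the gene are grouped into connected
    components under the >= 1 bp overlap relation; each component's
    signature is the set of tissues contributing a peak to it. The score is
    the number of distinct signatures (or of components, with
    ``dedup_signatures=False``).
    """
    items = []  # (chrom, start, end, tissue)
    for tissue, ps in tissue_peak_sets.items():
        for chrom, s, e in _linked_peaks(gene_id, ps, annotations, max_dist):
            items.append((chrom, s, e, tissue))
    if not items:
        raise ValueError(f"gene {gene_id!r} has no linked peaks")
    items.sort()
    # single-pass union of overlapping intervals into components
    signatures = []
    cur_chrom, cur_end, cur_tissues = None, None, set()
    for chrom, s, e, tissue in items:
        if cur_chrom == chrom and s < cur_end:
            cur_end = max(cur_end, e)
            cur_tissues.add(tissue)
        else:
            if cur_tissues:
                signatures.append(frozenset(cur_tissues))
            cur_chrom, cur_end, cur_tissues = chrom, e, {tissue}
    signatures.append(frozenset(cur_tissues))
    return len(set(signatures)) if dedup_signatures else len(signatures)


def marker_gene_cells(
    gene_id: str,
    matrix: CellsByPeaksMatrix,
    annotations,
    upstream: int = 1200,
    downstream: int = 100,
) -> set:
    """Cells with any peak overlapping the gene body or its flanking window.

    The window runs from ``upstream`` bp 5' of the gene to ``downstream`` bp
    3' of it, in the gene's orientation (on the - strand the upstream
    extension is on the higher-coordinate side).
    """
    gene = next((g for g in annotations if g.gene_id == gene_id), None)
    if gene is None:
        raise KeyError(f"unknown gene {gene_id!r}")
    lo, hi = gene.body
    if gene.strand == "+":
        ws, we = lo - upstream, hi + downstream
    else:
        ws, we = lo - downstream, hi + upstream
    ws = max(ws, 0)

    hit_cols = []
    for j, pid in enumerate(matrix.peaks):
        chrom, span = str(pid).split(":")
        s, e = (int(x) for x in span.split("-"))
        if chrom == gene.chrom and s < we and e > ws:
            hit_cols.append(j)
    if not hit_cols:
        return set()
    x = sp.csc_matrix(matrix.matrix)
    carriers = np.zeros(x.shape[0], dtype=bool)
    for j in hit_cols:
        rows = x.indices[x.indptr[j]: x.indptr[j + 1]]
        carriers[rows] = True
    return {matrix.cells[i] for i in np.nonzero(carriers)[0]}
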