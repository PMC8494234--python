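"""Synthetic data generators with planted ground truth.

Every input class of the pipeline can be generated at desk scale so the full
analysis is testable without any download: binary cells-by-peaks matrices
with planted cell types, per-cell fragment streams over a toy genome,
tissue-block expression tables, and truth-linked ChIP-like interval sets.
All generators are pure functions of their parameters and seed, and return a
:class:`SyntheticTruth` sufficient to score any recovery metric.

The desk preset (600 cells, 5 types, 80 type-specific peaks per type, 100
shared peaks, detection rates 0.35 specific / 0.01 background) gives each
cell a few dozen detected peaks — sparse enough that recovery is non-trivial
but achievable, mimicking the very shallow per-cell coverage of worm
sci-ATAC libraries (median on the order of several hundred reads per cell;
the fragment generator defaults to 150 per cell, the coverage floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import CellsByPeaksMatrix
from .peaks import PeakSet
from .preprocess import FRAGMENT_COLUMNS, GenomeTable

#: Desk-scale preset for the planted-matrix generator.
DESK_PRESET = dict(
    n_cells=600,
    n_types=5,
    peaks_per_type=80,
    shared_peaks=100,
    detect_rate_specific=0.35,
    detect_rate_background=0.01,
)


@dataclass
class SyntheticTruth:
    """Planted ground truth: labels, coordinates, and generator parameters."""

    cell_types: np.ndarray | None = None          # per-cell true type
    peak_types: np.ndarray | None = None          # per-peak type label ("shared" ok)
    planted_peaks: dict | None = None             # type -> PeakSet
    marker_genes: dict | None = None              # tissue -> list of gene ids
    params: dict = field(default_factory=dict)
    seed: int = 0


def simulate_matrix(
    n_cells: int = 600,
    n_types: int = 5,
    peaks_per_type: int = 80,
    shared_peaks: int = 100,
    detect_rate_specific: float = 0.35,
    detect_rate_background: float = 0.01,
    seed: int = 0,
) -> tuple[CellsByPeaksMatrix, SyntheticTruth]:
    """Planted-cell-type binary matrix.

    A cell of type t detects each of type t's specific peaks with probability
    ``detect_rate_specific``, every other type's peaks with
    ``detect_rate_background``, and shared peaks with
    ``detect_rate_specific`` regardless of type; entries are independent
    Bernoulli given the labels.
    """
    for r in (detect_rate_specific, detect_rate_background):
        if not 0 <= r <= 1:
            raise ValueError("detection rates must be in [0, 1]")
    n_peaks = n_types * peaks_per_type + shared_peaks
    if detect_rate_specific == 0 and (detect_rate_background == 0 or n_peaks == 0):
        raise ValueError("expected matrix density is zero")

    rng = np.random.default_rng(seed)
    cell_types = np.arange(n_cells) % n_types
    peak_types = np.concatenate(
        [np.repeat(np.arange(n_types), peaks_per_type), np.full(shared_peaks, -1)]
    )
    prob = np.full((n_cells, n_peaks), detect_rate_background)
    for t in range(n_types):
        rows = cell_types == t
        prob[np.ix_(rows, peak_types == t)] = detect_rate_specific
    prob[:, peak_types == -1] = detect_rate_specific
    dense = rng.random((n_cells, n_peaks)) < prob

    cells = pd.Index([f"cell{i:05d}" for i in range(n_cells)])
    peaks = pd.Index([f"peak{j:05d}" for j in range(n_peaks)])
    m = CellsByPeaksMatrix(sp.csr_matrix(dense.astype(np.int8)), cells, peaks)
    truth = SyntheticTruth(
        cell_types=cell_types,
        peak_types=np.where(peak_types < 0, "shared", peak_types.astype(str)),
        params=dict(
            n_cells=n_cells, n_types=n_types, peaks_per_type=peaks_per_type,
            shared_peaks=shared_peaks, detect_rate_specific=detect_rate_specific,
            detect_rate_background=detect_rate_background,
        ),
        seed=seed,
    )
    return m, truth


def plant_peaks(
    genome: GenomeTable,
    n_types: int,
    peaks_per_type: int,
    peak_width: int = 300,
    spacing: int = 1000,
    seed: int = 0,
) -> dict[int, PeakSet]:
    """Lay out non-overlapping type-specific peak intervals on a toy genome."""
    rng = np.random.default_rng(seed)
    total = n_types * peaks_per_type
    chrom = genome.names[0]
    length = genome[chrom]
    stride = length // (total + 1)
    if stride < peak_width + spacing:
        raise ValueError("genome too small for the requested peak layout")
    positions = (np.arange(total) + 1) * stride
    rng.shuffle(positions)
    out: dict[int, PeakSet] = {}
    for t in range(n_types):
        pos = np.sort(positions[t * peaks_per_type: (t + 1) * peaks_per_type])
        rows = [(chrom, int(p), int(p + peak_width)) for p in pos]
        out[t] = PeakSet.from_intervals(rows, source=f"type_{t}")
    return out


def simulate_fragments(
    genome: GenomeTable,
    cells_per_type: int = 100,
    n_types: int = 3,
    strong_peaks_per_type: int = 10,
    weak_peaks_per_type: int = 10,
    peak_width: int = 300,
    frags_per_cell: int = 120,
    p_strong: float = 0.45,
    p_weak: float = 0.03,
    length_meanlog: float = 5.0,
    length_sdlog: float = 0.35,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-cell fragment streams with two tiers of planted type-specific peaks.

    Each cell of type t draws ``frags_per_cell`` fragments: with probability
    ``p_strong`` the fragment is centered uniformly inside one of t's
    *strong* peaks (accessible enough to be called even from pooled bulk
    data), with probability ``p_weak`` inside one of t's *weak* peaks
    (detectable only once the cells of the type are pooled on their own),
    and otherwise its start is uniform on the genome. Lengths are lognormal
    (median ~ e^5 ≈ 148 bp, the nucleosome-free ATAC regime).

    The truth carries ``planted_peaks`` (type -> all planted peaks) plus
    ``planted_strong`` / ``planted_weak`` in ``params`` for recovery scoring.
    """
    rng = np.random.default_rng(seed)
    per_type = strong_peaks_per_type + weak_peaks_per_type
    layout = plant_peaks(genome, n_types, per_type, peak_width=peak_width, seed=seed)
    strong: dict[int, PeakSet] = {}
    weak: dict[int, PeakSet] = {}
    for t in range(n_types):
        df = layout[t].df
        strong[t] = PeakSet(df.iloc[:strong_peaks_per_type])
        weak[t] = PeakSet(df.iloc[strong_peaks_per_type:])
    chrom = genome.names[0]
    length = genome[chrom]

    def _centers_in(ps: PeakSet, n: int) -> np.ndarray:
        s = ps.df["start"].to_numpy()
        e = ps.df["end"].to_numpy()
        which = rng.integers(0, s.size, n)
        offs = rng.random(n)
        return s[which] + (offs * (e[which] - s[which])).astype(np.int64)

    rows = []
    cell_types = []
    for t in range(n_types):
        for c in range(cells_per_type):
            barcode = f"t{t}c{c:04d}"
            cell_types.append(t)
            lens = np.maximum(
                rng.lognormal(length_meanlog, length_sdlog, frags_per_cell), 30
            ).astype(np.int64)
            u = rng.random(frags_per_cell)
            in_strong = u < p_strong
            in_weak = (u >= p_strong) & (u < p_strong + p_weak)
            centers = np.empty(frags_per_cell, dtype=np.int64)
            if in_strong.any():
                centers[in_strong] = _centers_in(strong[t], int(in_strong.sum()))
            if in_weak.any():
                centers[in_weak] = _centers_in(weak[t], int(in_weak.sum()))
            bg = ~(in_strong | in_weak)
            if bg.any():
                centers[bg] = rng.integers(0, length, int(bg.sum()))
            starts = np.clip(centers - lens // 2, 0, length - 1)
            ends = np.clip(starts + lens, 1, length)
            starts = np.minimum(starts, ends - 1)
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s), int(e), barcode))

    frags = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    frags = frags.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    truth = SyntheticTruth(
        cell_types=np.asarray(cell_types),
        planted_peaks=layout,
        params=dict(
            cells_per_type=cells_per_type, n_types=n_types,
            strong_peaks_per_type=strong_peaks_per_type,
            weak_peaks_per_type=weak_peaks_per_type, peak_width=peak_width,
            frags_per_cell=frags_per_cell, p_strong=p_strong, p_weak=p_weak,
            planted_strong=strong, planted_weak=weak,
        ),
        seed=seed,
    )
    return frags, truth


def simulate_background_fragments(
    genome: GenomeTable,
    n_fragments: int = 20_000,
    length_meanlog: float = 5.0,
    length_sdlog: float = 0.35,
    seed: int = 0,
    barcode: str = "naked",
) -> pd.DataFrame:
    """Uniform fragments over the genome (a naked-DNA input control)."""
    rng = np.random.default_rng(seed)
    chrom = genome.names[0]
    length = genome[chrom]
    lens = np.maximum(rng.lognormal(length_meanlog, length_sdlog, n_fragments), 30).astype(
        np.int64
    )
    starts = rng.integers(0, length - 1, n_fragments)
    ends = np.clip(starts + lens, 1, length)
    starts = np.minimum(starts, ends - 1)
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "barcode": barcode}
    )
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def simulate_expression(
    n_marker_genes_per_tissue: int = 20,
    n_housekeeping: int = 1500,
    tissues: list[str] | None = None,
    marker_tpm: float = 200.0,
    housekeeping_tpm: float = 50.0,
    off_tpm: float = 0.5,
    noise: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Genes x tissues TPM table with tissue-exclusive marker blocks.

    Marker genes express at ``marker_tpm`` in their tissue and ``off_tpm``
    elsewhere; housekeeping genes at ``housekeeping_tpm`` everywhere.
    Multiplicative lognormal noise with sigma ``noise`` is applied (zero
    noise gives exact block structure).
    """
    if tissues is None:
        # default mirrors the 27-tissue resolution of the worm expression atlas
        tissues = [f"tissue{t:02d}" for t in range(27)]
    rng = np.random.default_rng(seed)
    genes = []
    values = []
    markers: dict[str, list[str]] = {t: [] for t in tissues}
    for ti, tissue in enumerate(tissues):
        for g in range(n_marker_genes_per_tissue):
            gid = f"{tissue}_marker{g:03d}"
            genes.append(gid)
            markers[tissue].append(gid)
            row = np.full(len(tissues), off_tpm)
            row[ti] = marker_tpm
            values.append(row)
    for g in range(n_housekeeping):
        genes.append(f"hk{g:04d}")
        values.append(np.full(len(tissues), housekeeping_tpm))
    table = np.asarray(values)
    if noise > 0:
        table = table * rng.lognormal(0.0, noise, table.shape)
    df = pd.DataFrame(table, index=pd.Index(genes, name="gene"), columns=tissues)
    truth = SyntheticTruth(
        marker_genes=markers,
        params=dict(
            n_marker_genes_per_tissue=n_marker_genes_per_tissue,
            n_housekeeping=n_housekeeping, tissues=tissues, noise=noise,
        ),
        seed=seed,
    )
    return df, truth


def simulate_chip(
    planted_peaks: dict,
    genome: GenomeTable,
    fraction_covered: float = 0.8,
    decoy_count: int = 50,
    hot_fraction: float = 0.1,
    site_width: int = 200,
    stage_of_type: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """ChIP-like interval table with occupancy counts and stage labels.

    A ``fraction_covered`` share of each type's planted peaks receives a
    same-type TF site (jittered around the peak); ``decoy_count`` sites are
    placed uniformly; a ``hot_fraction`` share of all sites is marked
    high-occupancy (occupancy >= 41, removable by the non-HOT filter).
    Columns: chrom, start, end, tf, occupancy, stage.
    """
    rng = np.random.default_rng(seed)
    chrom = genome.names[0]
    length = genome[chrom]
    rows = []
    for t, ps in planted_peaks.items():
        stage = (stage_of_type or {}).get(t, "L2")
        for _, r in ps.df.iterrows():
            if rng.random() > fraction_covered:
                continue
            center = (int(r["start"]) + int(r["end"])) // 2 + int(rng.integers(-50, 51))
            s = max(center - site_width // 2, 0)
            e = min(s + site_width, length)
            rows.append((chrom, s, e, f"TF_type{t}", int(rng.integers(1, 6)), stage))
    for _ in range(decoy_count):
        s = int(rng.integers(0, max(length - site_width, 1)))
        rows.append((chrom, s, s + site_width, "TF_decoy", int(rng.integers(1, 6)), "embryo"))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "tf", "occupancy", "stage"]
    )
    n_hot = int(round(hot_fraction * len(df)))
    if n_hot:
        hot_idx = rng.choice(len(df), size=n_hot, replace=False)
        df.loc[df.index[hot_idx], "occupancy"] = 41 + rng.integers(0, 20, n_hot)
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
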