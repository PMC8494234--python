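"""Binary cells-by-peaks matrix construction and outlier filtering.

The corpus for the topic model is a binary sparse matrix: entry (cell, peak)
is 1 iff at least one cut site of the cell overlaps the peak by >= 1 bp,
regardless of multiplicity. Cells are documents and peaks are words.

Before modeling, outlier cells (too few peaks) and outlier peaks (detected in
too few or too many cells) are removed by a change-point rule on the sorted
per-item detection fractions: the sorted, mean-centered curve is convolved
with a sigmoid-shaped kernel (a smoothed slope estimate), and a change point
is declared at an extreme when the convolution exceeds the mean plus four
interquartile ranges of the convolution output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)


@dataclass
class CellsByPeaksMatrix:
    """Binary sparse cells x peaks matrix with identifier indices."""

    matrix: sp.csr_matrix
    cells: pd.Index
    peaks: pd.Index

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.matrix.data = np.ones_like(self.matrix.data)
        self.cells = pd.Index(self.cells)
        self.peaks = pd.Index(self.peaks)
        if self.matrix.shape != (len(self.cells), len(self.peaks)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cells)} cells x {len(self.peaks)} peaks"
            )
        if not self.cells.is_unique or not self.peaks.is_unique:
            raise ValueError("cell and peak identifiers must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def cell_counts(self) -> np.ndarray:
        """Number of peaks detected per cell."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def peak_counts(self) -> np.ndarray:
        """Number of cells in which each peak is detected."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def subset(self, cell_mask=None, peak_mask=None) -> "CellsByPeaksMatrix":
        m = self.matrix
        cells, peaks = self.cells, self.peaks
        if cell_mask is not None:
            m = m[cell_mask]
            cells = cells[cell_mask]
        if peak_mask is not None:
            m = m[:, peak_mask]
            peaks = peaks[peak_mask]
        return CellsByPeaksMatrix(sp.csr_matrix(m), cells, peaks)

    # -- MatrixMarket directory IO (matrix.mtx + cells.txt + peaks.txt) -----

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        mmwrite(str(d / "matrix.mtx"), self.matrix.tocoo(), field="integer")
        (d / "cells.txt").write_text("\n".join(map(str, self.cells)) + "\n")
        (d / "peaks.txt").write_text("\n".join(map(str, self.peaks)) + "\n")

    @classmethod
    def load(cls, directory) -> "CellsByPeaksMatrix":
        d = Path(directory)
        m = sp.csr_matrix(mmread(str(d / "matrix.mtx")))
        cells = (d / "cells.txt").read_text().splitlines()
        peaks = (d / "peaks.txt").read_text().splitlines()
        return cls(m, pd.Index(cells), pd.Index(peaks))


def build_matrix(cutsites: pd.DataFrame, peaks) -> CellsByPeaksMatrix:
    """Build the binary cells-by-peaks matrix from cut sites and merged peaks.

    ``peaks`` is a :class:`scitopic.peaks.PeakSet` (or its DataFrame) of
    non-overlapping, sorted intervals. An entry is 1 iff any cut site of the
    cell overlaps the peak by at least one base (half-open intervals, so an
    abutting window does not count).
    """
    peaks_df = getattr(peaks, "df", peaks)
    if peaks_df is None or not len(peaks_df):
        raise ValueError("empty peak set")

    peak_ids = [
        f"{c}:{s}-{e}"
        for c, s, e in zip(peaks_df["chrom"], peaks_df["start"], peaks_df["end"])
    ]
    cell_ids = pd.Index(pd.unique(cutsites["cell"]))
    cell_pos = {c: i for i, c in enumerate(cell_ids)}

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for chrom, pgrp in peaks_df.groupby("chrom", sort=False):
        cgrp = cutsites[cutsites["chrom"] == chrom]
        if not len(cgrp):
            continue
        pstart = pgrp["start"].to_numpy()
        pend = pgrp["end"].to_numpy()
        order = np.argsort(pstart, kind="stable")
        pstart, pend = pstart[order], pend[order]
        pidx = pgrp.index.to_numpy()[order]
        s = cgrp["start"].to_numpy()
        e = cgrp["end"].to_numpy()
        # first peak that could overlap: end > site start
        lo = np.searchsorted(pend, s, side="right")
        # first peak starting at/after site end (half-open: start >= e no overlap)
        hi = np.searchsorted(pstart, e, side="left")
        cells_np = cgrp["cell"].to_numpy()
        cell_rows = np.array([cell_pos[c] for c in cells_np])
        single = hi == lo + 1
        if single.any():
            rows.append(cell_rows[single])
            cols.append(pidx[lo[single]])
        for i in np.nonzero(hi > lo + 1)[0]:
            hits = np.arange(lo[i], hi[i])
            rows.append(np.full(hits.size, cell_rows[i]))
            cols.append(pidx[hits])

    peak_pos = {int(i): j for j, i in enumerate(peaks_df.index.to_numpy())}
    if rows:
        r = np.concatenate(rows)
        c = np.array([peak_pos[int(x)] for x in np.concatenate(cols)])
        data = np.ones(r.size, dtype=np.int8)
        m = sp.coo_matrix((data, (r, c)), shape=(len(cell_ids), len(peak_ids)))
        m = m.tocsr()
        m.data = np.ones_like(m.data)
    else:
        m = sp.csr_matrix((len(cell_ids), len(peak_ids)), dtype=np.int8)
    return CellsByPeaksMatrix(m, cell_ids, pd.Index(peak_ids))


def sigmoid_kernel(width: int = 101, span: float = 6.0) -> np.ndarray:
    """Logistic-curve kernel sampled on [-span, span], zero-centered.

    The zero-centered sigmoid is an ascending ramp; correlating it with a
    sorted curve yields a smoothed local-slope estimate.
    """
    t = np.linspace(-span, span, width)
    k = 1.0 / (1.0 + np.exp(-t))
    return k - k.mean()


@dataclass
class ChangePointResult:
    """Outcome of the sorted-curve convolution change-point filter."""

    order: np.ndarray           # argsort of the input values (ascending)
    sorted_values: np.ndarray
    convolution: np.ndarray     # valid-mode correlation with the sigmoid kernel
    threshold: float            # mean(conv) + n_iqr * IQR(conv)
    remove_mask: np.ndarray     # boolean, aligned to the *input* order
    side: str

    @property
    def n_removed(self) -> int:
        return int(self.remove_mask.sum())


def changepoint_filter(
    values: np.ndarray,
    kernel_width: int = 101,
    side: str = "high",
    n_iqr: float = 4.0,
) -> ChangePointResult:
    """Flag outlier items at the extremes of the sorted value curve.

    The sorted, mean-centered values are correlated (valid mode) with a
    zero-centered sigmoid kernel; the flagging threshold is
    ``mean(conv) + n_iqr * IQR(conv)`` (strict inequality, so a constant
    vector removes nothing). A change point is declared on a side when any
    window whose span lies on that half of the sorted order exceeds the
    threshold; the removal boundary is then placed at the largest adjacent
    gap in the sorted values on that side, and everything beyond the gap is
    flagged.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if side not in ("low", "high", "both"):
        raise ValueError(f"side must be low|high|both, got {side!r}")
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    if n < kernel_width:
        warnings.warn(
            f"changepoint_filter: {n} items < kernel width {kernel_width}; no-op",
            stacklevel=2,
        )
        return ChangePointResult(
            order, sorted_vals, np.zeros(0), np.nan, np.zeros(n, dtype=bool), side
        )

    kernel = sigmoid_kernel(kernel_width)
    centered = sorted_vals - sorted_vals.mean()
    conv = np.correlate(centered, kernel, mode="valid")
    q75, q25 = np.percentile(conv, [75, 25])
    threshold = conv.mean() + n_iqr * (q75 - q25)

    centers = np.arange(conv.size) + (kernel_width - 1) // 2
    exceed = conv > threshold
    remove_sorted = np.zeros(n, dtype=bool)

    half = n // 2
    if side in ("high", "both") and bool((exceed & (centers >= half)).any()):
        gaps = np.diff(sorted_vals[half:])
        j = half + int(np.argmax(gaps))  # boundary between j and j+1
        remove_sorted[j + 1:] = True
    if side in ("low", "both") and bool((exceed & (centers < half)).any()):
        gaps = np.diff(sorted_vals[: half + 1])
        j = int(np.argmax(gaps))
        remove_sorted[: j + 1] = True

    remove_mask = np.zeros(n, dtype=bool)
    remove_mask[order] = remove_sorted
    return ChangePointResult(order, sorted_vals, conv, float(threshold), remove_mask, side)


@dataclass
class MatrixFilterReport:
    """Identifiers removed by :func:`filter_matrix` and why."""

    removed_cells: dict[str, str] = field(default_factory=dict)
    removed_peaks: dict[str, str] = field(default_factory=dict)


def filter_matrix(
    m: CellsByPeaksMatrix, kernel_width: int = 101
) -> tuple[CellsByPeaksMatrix, MatrixFilterReport]:
    """Remove outlier cells (low side) and peaks (both sides), then empties.

    Cells are filtered on the fraction of all peaks detected in the cell
    (low outliers only: sparse cells are noise); peaks on the fraction of all
    cells in which they appear (both sides: near-empty peaks are noise,
    near-ubiquitous peaks carry no cell-type information). Rows/columns left
    all-zero are dropped afterwards.
    """
    report = MatrixFilterReport()

    cell_frac = m.cell_counts() / m.shape[1]
    cres = changepoint_filter(cell_frac, kernel_width=kernel_width, side="low")
    for cid in m.cells[cres.remove_mask]:
        report.removed_cells[str(cid)] = "low-coverage outlier"
    m2 = m.subset(cell_mask=~cres.remove_mask)

    peak_frac = m2.peak_counts() / m2.shape[0]
    pres = changepoint_filter(peak_frac, kernel_width=kernel_width, side="both")
    psorted = pres.remove_mask
    low_side = peak_frac <= np.median(peak_frac)
    for pid, is_low in zip(m2.peaks[psorted], low_side[psorted]):
        report.removed_peaks[str(pid)] = (
            "low-detection outlier" if is_low else "high-detection outlier"
        )
    m2 = m2.subset(peak_mask=~pres.remove_mask)

    empty_cells = m2.cell_counts() == 0
    for cid in m2.cells[empty_cells]:
        report.removed_cells[str(cid)] = "all-zero after peak filtering"
    empty_peaks = m2.peak_counts() == 0
    for pid in m2.peaks[empty_peaks]:
        report.removed_peaks[str(pid)] = "all-zero after cell filtering"
    if empty_cells.any() or empty_peaks.any():
        m2 = m2.subset(cell_mask=~empty_cells, peak_mask=~empty_peaks)

    logger.info(
        "filter_matrix: removed %d cells, %d peaks",
        len(report.removed_cells), len(report.removed_peaks),
    )
    return m2, report
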