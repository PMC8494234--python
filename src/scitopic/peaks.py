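"""Peak calling, merging, summit splitting, and the iterative pipeline.

Per-cluster ("pseudobulk") peak calling is the sensitivity engine of the
whole approach: regulatory sites specific to one cell type are diluted by
the background of all other cell types in bulk data, but stand out once the
cut sites of a homogeneous cluster are pooled. Two engines are provided:

* :func:`call_peaks_external` shells out to MACS2 with the exact flag set
  used for worm sci-ATAC data (BED input, effective genome 9e7, no model,
  q 0.05, 60-bp tags, SPMR, bedGraph output, summit calling) and parses the
  narrowPeak/bedGraph results.
* :func:`call_peaks_builtin` is a deliberately simple desk-scale caller (not
  a MACS2 reimplementation): cut-site midpoints are counted in sliding
  windows, each window is tested against a Poisson background whose rate is
  the maximum of the global rate, a local (10-kb flank) rate, and a
  depth-scaled control rate, p-values are Benjamini-Hochberg corrected, and
  significant windows are merged into peaks.

Wide multi-summit peaks are split into contiguous single-summit segments at
the minimum-signal position between adjacent summits.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import false_discovery_control, poisson

from .preprocess import GenomeTable

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "summit", "source", "score"]

#: MACS2 options used for worm sci-ATAC cut-site data.
MACS2_FLAGS = (
    "--format", "BED", "-g", "9e7", "--nomodel", "--qvalue", "0.05",
    "--SPMR", "--tsize", "60", "--bdg", "--keep-dup", "all", "--call-summits",
)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int | None = None
    source: str = "bulk"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak has start >= end: {self}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(f"summit outside peak: {self}")

    @property
    def width(self) -> int:
        return self.end - self.start


class PeakSet:
    """A sorted set of genomic intervals with optional summits and sources."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col, default in (("summit", pd.NA), ("source", "bulk"), ("score", pd.NA)):
            if col not in df.columns:
                df[col] = default
        df = df[PEAK_COLUMNS]
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        if (df["start"] >= df["end"]).any():
            raise ValueError("peak with start >= end")
        self.df = df

    @classmethod
    def from_peaks(cls, peaks) -> "PeakSet":
        rows = [
            (p.chrom, p.start, p.end, p.summit, p.source, p.score) for p in peaks
        ]
        return cls(pd.DataFrame(rows, columns=PEAK_COLUMNS))

    @classmethod
    def from_intervals(cls, intervals, source: str = "bulk") -> "PeakSet":
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
        df["source"] = source
        return cls(df)

    @classmethod
    def read_bed(cls, path, source: str | None = None) -> "PeakSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        ncol = df.shape[1]
        out = pd.DataFrame({
            "chrom": df[0].astype(str),
            "start": df[1].astype(np.int64),
            "end": df[2].astype(np.int64),
        })
        if source is not None:
            out["source"] = source
        elif ncol >= 4:
            out["source"] = df[3].astype(str)
        if ncol >= 5:
            out["score"] = pd.to_numeric(df[4], errors="coerce")
        return cls(out)

    def write_bed(self, path) -> None:
        cols = self.df[["chrom", "start", "end", "source"]].copy()
        cols.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_narrowpeak(cls, path, source: str | None = None) -> "PeakSet":
        names = ["chrom", "start", "end", "name", "score", "strand",
                 "signal", "pvalue", "qvalue", "peak_offset"]
        df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
        out = pd.DataFrame({
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "score": df["signal"],
            "source": source if source is not None else df["name"].astype(str),
        })
        offs = pd.to_numeric(df["peak_offset"], errors="coerce")
        out["summit"] = np.where(offs >= 0, df["start"] + offs, pd.NA)
        return cls(out)

    def write_narrowpeak(self, path, name_prefix: str = "peak") -> None:
        df = self.df
        with open(path, "w") as fh:
            for i, row in df.iterrows():
                summit = row["summit"]
                off = int(summit - row["start"]) if pd.notna(summit) else -1
                score = row["score"] if pd.notna(row["score"]) else 0
                fh.write(
                    f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                    f"{name_prefix}_{i}\t0\t.\t{score}\t-1\t-1\t{off}\n"
                )

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for _, r in self.df.iterrows():
            yield Peak(
                r["chrom"], int(r["start"]), int(r["end"]),
                int(r["summit"]) if pd.notna(r["summit"]) else None,
                str(r["source"]),
                float(r["score"]) if pd.notna(r["score"]) else None,
            )

    @property
    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def merge(self) -> "PeakSet":
        return merge_peak_sets([self])

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()


class SignalTrack:
    """Per-base non-negative signal over the chromosomes of a genome."""

    def __init__(self, genome: GenomeTable, arrays: dict[str, np.ndarray] | None = None):
        self.genome = genome
        self.arrays = arrays or {
            chrom: np.zeros(length, dtype=np.float64) for chrom, length in genome.items()
        }

    @classmethod
    def from_cutsites(cls, cutsites: pd.DataFrame, genome: GenomeTable) -> "SignalTrack":
        """Per-base cut-site interval coverage."""
        track = cls(genome)
        for chrom, grp in cutsites.groupby("chrom", sort=False):
            if chrom not in genome:
                raise ValueError(f"cut-site chromosome {chrom!r} not in genome")
            n = genome[chrom]
            diff = np.zeros(n + 1)
            np.add.at(diff, np.clip(grp["start"].to_numpy(), 0, n), 1.0)
            np.add.at(diff, np.clip(grp["end"].to_numpy(), 0, n), -1.0)
            track.arrays[chrom] = np.cumsum(diff[:-1])
        return track

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.arrays[chrom]

    def region(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.arrays[chrom][start:end]

    def subtract(self, other: "SignalTrack") -> "SignalTrack":
        out = SignalTrack(self.genome)
        for chrom in self.arrays:
            out.arrays[chrom] = np.maximum(self.arrays[chrom] - other.arrays[chrom], 0.0)
        return out

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.arrays.items():
                if arr.size == 0:
                    continue
                change = np.nonzero(np.diff(arr))[0] + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [arr.size]])
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    @classmethod
    def read_bedgraph(cls, path, genome: GenomeTable) -> "SignalTrack":
        track = cls(genome)
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            comment="#",
        )
        for _, row in df.iterrows():
            track.arrays[str(row["chrom"])][int(row["start"]): int(row["end"])] = row["value"]
        return track


def call_peaks_external(
    cutsites_bed,
    genome_size: float = 9e7,
    control_bed=None,
    outdir=None,
    name: str = "scitopic",
    macs2: str = "macs2",
) -> tuple[PeakSet, Path]:
    """Call peaks with MACS2 on a cut-site BED file; parse narrowPeak output.

    Returns the peak set and the treatment bedGraph path. Raises a
    FileNotFoundError pointing at :func:`call_peaks_builtin` when the MACS2
    executable is unavailable.
    """
    if shutil.which(macs2) is None:
        raise FileNotFoundError(
            f"{macs2!r} executable not found; install MACS2 or use "
            "call_peaks_builtin for desk-scale data"
        )
    outdir = Path(outdir or Path(cutsites_bed).parent)
    cmd = [macs2, "callpeak", "--treatment", str(cutsites_bed),
           "--name", name, "--outdir", str(outdir), *MACS2_FLAGS]
    cmd[cmd.index("9e7")] = str(genome_size)
    if control_bed is not None:
        cmd += ["--control", str(control_bed)]
    else:
        logger.info("no control provided; running MACS2 without one")
    subprocess.run(cmd, check=True, capture_output=True)
    np_path = outdir / f"{name}_peaks.narrowPeak"
    if not np_path.exists():
        raise RuntimeError(f"MACS2 produced no narrowPeak output at {np_path}")
    peaks = PeakSet.read_narrowpeak(np_path, source="bulk")
    return peaks, outdir / f"{name}_treat_pileup.bdg"


def call_peaks_builtin(
    cutsites: pd.DataFrame,
    genome: GenomeTable,
    control: pd.DataFrame | None = None,
    window: int = 150,
    step: int = 75,
    q_threshold: float = 0.05,
    flank: int = 10_000,
    source: str = "bulk",
) -> tuple[PeakSet, SignalTrack]:
    """Windowed Poisson peak caller for desk-scale synthetic data.

    Cut-site midpoints are counted in ``window``-bp windows stepped by
    ``step``. Each window's count is tested against a Poisson rate equal to
    the max of the genome-wide rate, the local rate in ``flank``-bp flanks,
    and the depth-scaled control rate; q-values are Benjamini-Hochberg over
    all windows and windows passing ``q_threshold`` are merged into peaks
    (summit = maximum of the per-base coverage). Not a MACS2 equivalent.
    """
    if not len(cutsites):
        return PeakSet(pd.DataFrame(columns=PEAK_COLUMNS[:3])), SignalTrack(genome)

    track = SignalTrack.from_cutsites(cutsites, genome)
    mids = {
        chrom: np.sort(
            ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2)
        )
        for chrom, grp in cutsites.groupby("chrom", sort=False)
    }
    n_treat = sum(m.size for m in mids.values())
    ctrl_mids = {}
    n_ctrl = 0
    if control is not None and len(control):
        ctrl_mids = {
            chrom: np.sort(((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2))
            for chrom, grp in control.groupby("chrom", sort=False)
        }
        n_ctrl = sum(m.size for m in ctrl_mids.values())
    global_rate = n_treat / genome.total_bp  # midpoints per bp

    recs = []  # (chrom, win_start, win_end, count, lam)
    for chrom, length in genome.items():
        m = mids.get(chrom, np.array([], dtype=np.int64))
        if m.size == 0:
            continue
        starts = np.arange(0, max(length - window, 0) + 1, step)
        ends = np.minimum(starts + window, length)
        counts = np.searchsorted(m, ends) - np.searchsorted(m, starts)
        lam_global = global_rate * (ends - starts)
        ls = np.maximum(starts - flank, 0)
        le = np.minimum(ends + flank, length)
        local_counts = np.searchsorted(m, le) - np.searchsorted(m, ls)
        lam_local = local_counts / (le - ls) * (ends - starts)
        lam = np.maximum(lam_global, lam_local)
        if n_ctrl:
            c = ctrl_mids.get(chrom, np.array([], dtype=np.int64))
            scale = n_treat / n_ctrl
            c_local = np.searchsorted(c, le) - np.searchsorted(c, ls)
            lam_ctrl = c_local / (le - ls) * (ends - starts) * scale
            lam = np.maximum(lam, lam_ctrl)
        for s, e, cnt, lm in zip(starts, ends, counts, lam):
            recs.append((chrom, int(s), int(e), int(cnt), float(lm)))

    if not recs:
        return PeakSet(pd.DataFrame(columns=PEAK_COLUMNS[:3])), track

    counts = np.array([r[3] for r in recs], dtype=float)
    lam = np.array([r[4] for r in recs])
    pvals = poisson.sf(counts - 1, np.maximum(lam, 1e-12))
    qvals = false_discovery_control(pvals, method="bh")
    sig = qvals <= q_threshold

    rows = []
    for keep, (chrom, s, e, cnt, _lm) in zip(sig, recs):
        if keep:
            rows.append((chrom, s, e))
    if not rows:
        return PeakSet(pd.DataFrame(columns=PEAK_COLUMNS[:3])), track

    merged = merge_peak_sets([PeakSet.from_intervals(rows, source=source)])
    # place summits at the per-base coverage maximum within each peak
    summits = []
    for _, r in merged.df.iterrows():
        sig_arr = track.region(r["chrom"], r["start"], r["end"])
        summits.append(int(r["start"] + np.argmax(sig_arr)))
    merged.df["summit"] = summits
    merged.df["source"] = source
    return merged, track


def merge_peak_sets(peak_sets) -> PeakSet:
    """Union of interval sets; overlapping or abutting intervals are merged."""
    frames = [ps.df if isinstance(ps, PeakSet) else ps for ps in peak_sets]
    frames = [f for f in frames if len(f)]
    if not frames:
        return PeakSet(pd.DataFrame(columns=PEAK_COLUMNS[:3]))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "start", "end"], kind="stable")
    out_rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        cur_s = cur_e = None
        sources: list[str] = []
        for _, r in grp.iterrows():
            if cur_s is None:
                cur_s, cur_e = int(r["start"]), int(r["end"])
                sources = [str(r["source"])]
            elif r["start"] <= cur_e:  # overlapping or abutting
                cur_e = max(cur_e, int(r["end"]))
                sources.append(str(r["source"]))
            else:
                out_rows.append((chrom, cur_s, cur_e, ",".join(dict.fromkeys(sources))))
                cur_s, cur_e = int(r["start"]), int(r["end"])
                sources = [str(r["source"])]
        out_rows.append((chrom, cur_s, cur_e, ",".join(dict.fromkeys(sources))))
    out = pd.DataFrame(out_rows, columns=["chrom", "start", "end", "source"])
    return PeakSet(out)


def split_multisummit(
    peak: Peak,
    signal: SignalTrack,
    smooth_window: int = 50,
    min_prominence: float = 0.1,
) -> list[Peak]:
    """Split a multi-summit peak into contiguous single-summit segments.

    The signal over the peak is smoothed with a moving average of
    ``smooth_window`` bp; local maxima with prominence at least
    ``min_prominence`` times the smoothed maximum are summits. Boundaries
    fall at the minimum-signal position between adjacent summits (ties
    resolved toward the midpoint between the summits). Segments exactly tile
    ``[start, end)`` with one summit each.
    """
    sig = np.asarray(signal.region(peak.chrom, peak.start, peak.end), dtype=float)
    if sig.size == 0 or not np.any(sig > 0):
        warnings.warn(f"all-zero signal over {peak}; returned unchanged", stacklevel=2)
        return [peak]
    if smooth_window > 1:
        w = min(smooth_window, sig.size)
        sm = np.convolve(sig, np.ones(w) / w, mode="same")
    else:
        sm = sig
    prom = min_prominence * sm.max()
    summits, _ = find_peaks(sm, prominence=prom)
    if summits.size == 0:
        summits = np.array([int(np.argmax(sm))])
    if summits.size == 1:
        return [Peak(peak.chrom, peak.start, peak.end,
                     summit=peak.start + int(summits[0]),
                     source=peak.source, score=peak.score)]

    boundaries = [0]
    for s1, s2 in zip(summits[:-1], summits[1:]):
        valley = sm[s1 + 1: s2]
        vmin = valley.min()
        cands = np.nonzero(valley == vmin)[0] + s1 + 1
        mid = (s1 + s2) / 2.0
        v = int(cands[np.argmin(np.abs(cands - mid))])
        boundaries.append(v + 1)
    boundaries.append(sig.size)

    segments = []
    for (b0, b1), summit in zip(zip(boundaries[:-1], boundaries[1:]), summits):
        segments.append(
            Peak(
                peak.chrom, peak.start + b0, peak.start + b1,
                summit=peak.start + int(summit),
                source=peak.source, score=peak.score,
            )
        )
    return segments


def split_all_peaks(
    peaks: PeakSet, signal: SignalTrack, smooth_window: int = 50,
    min_prominence: float = 0.1,
) -> PeakSet:
    out = []
    for p in peaks:
        out.extend(split_multisummit(p, signal, smooth_window, min_prominence))
    return PeakSet.from_peaks(out)


@dataclass
class IterationResult:
    model: object
    clustering: object
    peaks: PeakSet
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_iteration(
    cutsites: pd.DataFrame,
    current_peaks: PeakSet,
    genome: GenomeTable,
    lda_config,
    control: pd.DataFrame | None = None,
    cluster_params: dict | None = None,
    caller_params: dict | None = None,
    kernel_width: int = 101,
) -> IterationResult:
    """One clustering/peak-calling round of the iterative pipeline.

    Build and filter the cells-by-peaks matrix over ``current_peaks``, fit
    LDA, cluster the cells by topic, pool the cut sites of each cluster,
    call peaks per cluster with the built-in caller, and merge the cluster
    peak sets into the next peak list. With zero clusters the input peaks
    are returned with a warning.
    """
    from .clustering import UNASSIGNED, TopicClusterer
    from .lda import fit_lda
    from .matrix import build_matrix, filter_matrix

    if not len(cutsites):
        raise ValueError("empty cell set: no cut sites provided")

    m = build_matrix(cutsites, current_peaks)
    m, _ = filter_matrix(m, kernel_width=kernel_width)
    stage_counts = {"cells": m.shape[0], "input_peaks": len(current_peaks)}

    model = fit_lda(m, lda_config)
    clusterer = TopicClusterer(seed=lda_config.seed, **(cluster_params or {}))
    clusterer.fit(model.theta)
    labels = clusterer.labels_
    cluster_ids = np.unique(labels[labels != UNASSIGNED])
    stage_counts["clusters"] = int(cluster_ids.size)
    stage_counts["assigned_cells"] = int((labels != UNASSIGNED).sum())

    if cluster_ids.size == 0:
        warnings.warn("no topic clusters found; returning input peaks", stacklevel=2)
        return IterationResult(model, clusterer.to_clustering(), current_peaks, stage_counts)

    cell_of = pd.Series(labels, index=m.cells)
    per_cluster = []
    for cid in cluster_ids:
        members = set(cell_of.index[cell_of == cid])
        pooled = cutsites[cutsites["cell"].isin(members)]
        ps, _track = call_peaks_builtin(
            pooled, genome, control=control, source=f"cluster_{cid}",
            **(caller_params or {}),
        )
        stage_counts[f"peaks_cluster_{cid}"] = len(ps)
        if len(ps):
            per_cluster.append(ps)

    if not per_cluster:
        warnings.warn("no cluster produced peaks; returning input peaks", stacklevel=2)
        return IterationResult(model, clusterer.to_clustering(), current_peaks, stage_counts)

    merged = merge_peak_sets(per_cluster)
    stage_counts["merged_peaks"] = len(merged)
    return IterationResult(model, clusterer.to_clustering(), merged, stage_counts)
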