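"""Fragment-level preprocessing for combinatorial-indexing scATAC-seq.

Converts per-cell mapped fragments into Tn5 cut-site windows, corrects cell
barcodes against a whitelist, removes PCR duplicates, and drops cells with too
few unique fragments to be informative.

The coordinate conventions are BED-style throughout: 0-based, half-open
``[start, end)`` intervals. A "cut site" is the 60-bp window centered on a Tn5
insertion point. Each fragment contributes two insertion points, one per end,
shifted by the canonical +4/-5 bp to account for the 9-bp staggered duplication
Tn5 leaves at its insertion site: the left (plus-strand) end is shifted +4 from
``start`` and the right (minus-strand) end is shifted -5 from the last covered
base (``end - 1``).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of a fragments table (BED3 + cell barcode).
FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode"]

#: Column order of a cut-sites table (BED3 + cell identifier).
CUTSITE_COLUMNS = ["chrom", "start", "end", "cell"]

#: Half-width of the Tn5 cut-site window (window width = 60 bp).
CUTSITE_HALF_WIDTH = 30

#: Plus-strand / minus-strand Tn5 insertion-point shifts.
PLUS_SHIFT = 4
MINUS_SHIFT = -5


@dataclass(frozen=True)
class Fragment:
    """A mapped, deduplicated DNA fragment belonging to one cell."""

    chrom: str
    start: int
    end: int
    barcode: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment has start >= end: {self}")


@dataclass(frozen=True)
class CutSite:
    """A 60-bp (or clipped) Tn5 insertion window derived from a fragment end."""

    chrom: str
    start: int
    end: int
    cell: str


class GenomeTable:
    """Ordered chromosome names with lengths in bp."""

    def __init__(self, sizes: dict[str, int] | Sequence[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, dict) else list(sizes)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome table")
        for name, length in items:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes: dict[str, int] = dict(items)

    @classmethod
    def from_file(cls, path) -> "GenomeTable":
        """Read a two-column chrom-sizes file (name<TAB>length)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(list(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def items(self):
        return self._sizes.items()


class BarcodeMatch(NamedTuple):
    """Result of matching an observed barcode against a whitelist.

    ``barcode`` is the accepted whitelist entry, or ``None`` with ``reason``
    set to ``"no-match"`` or ``"ambiguous"``.
    """

    barcode: Optional[str]
    reason: Optional[str]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _levenshtein(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b)["editDistance"]


def correct_barcode(
    observed: str,
    whitelist: Iterable[str],
    max_edits: int = 3,
    exclusion_edits: int = 5,
    metric: str = "hamming",
) -> BarcodeMatch:
    """Assign an observed barcode to its best-matching whitelist entry.

    The observed sequence is accepted iff exactly one whitelist entry is within
    ``max_edits`` edits and no *other* entry is within ``exclusion_edits``
    edits. Barcodes are fixed length within a run, so Hamming distance is the
    default metric; set ``metric="levenshtein"`` for edit distance proper.
    """
    wl = list(whitelist)
    if not wl:
        raise ValueError("whitelist is empty")
    if metric == "hamming":
        for entry in wl:
            if len(entry) != len(observed):
                raise ValueError(
                    f"barcode length mismatch: observed {len(observed)} bp, "
                    f"whitelist entry {entry!r} is {len(entry)} bp"
                )
        dist = _hamming
    elif metric == "levenshtein":
        dist = _levenshtein
    else:
        raise ValueError(f"unknown metric {metric!r}")

    distances = np.array([dist(observed, entry) for entry in wl])
    best = int(distances.argmin())
    if distances[best] > max_edits:
        return BarcodeMatch(None, "no-match")
    others = np.delete(distances, best)
    if others.size and others.min() <= exclusion_edits:
        return BarcodeMatch(None, "ambiguous")
    return BarcodeMatch(wl[best], None)


def deduplicate_fragments(fragments: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: one fragment per (barcode, chrom, start, end).

    Output is coordinate sorted; the operation is idempotent.
    """
    out = (
        fragments.drop_duplicates(subset=FRAGMENT_COLUMNS)
        .sort_values(["chrom", "start", "end", "barcode"], kind="stable")
        .reset_index(drop=True)
    )
    return out


@dataclass
class CoverageFilterReport:
    """Barcodes removed by the minimum-coverage filter and their counts."""

    removed: dict[str, int] = field(default_factory=dict)
    kept: int = 0

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_low_coverage_cells(
    fragments: pd.DataFrame, min_fragments: int = 150
) -> tuple[pd.DataFrame, CoverageFilterReport]:
    """Drop cells with fewer than ``min_fragments`` unique fragments.

    Expects deduplicated input. A barcode with exactly ``min_fragments``
    fragments is kept.
    """
    counts = fragments["barcode"].value_counts()
    bad = counts[counts < min_fragments]
    report = CoverageFilterReport(
        removed={str(k): int(v) for k, v in bad.items()},
        kept=int((counts >= min_fragments).sum()),
    )
    if len(bad):
        logger.info(
            "coverage filter: removed %d/%d barcodes with < %d fragments",
            len(bad), len(counts), min_fragments,
        )
    keep = fragments[~fragments["barcode"].isin(bad.index)].reset_index(drop=True)
    return keep, report


def fragments_to_cutsites(
    fragments: pd.DataFrame,
    genome: GenomeTable,
    blacklist: Sequence[str] = (),
) -> tuple[pd.DataFrame, int]:
    """Expand each fragment into its two Tn5 cut-site windows.

    Each fragment yields windows ``[c - 30, c + 30)`` around the two shifted
    insertion centers (left ``start + 4``, right ``(end - 1) - 5``), clipped at
    chromosome bounds. Returns the sorted cut-site table and the number of
    windows dropped because clipping left them empty. Chromosomes listed in
    ``blacklist`` (e.g. the mitochondrial genome) are excluded up front.
    """
    frags = fragments
    if blacklist:
        frags = frags[~frags["chrom"].isin(set(blacklist))]
    if not len(frags):
        return pd.DataFrame(columns=CUTSITE_COLUMNS), 0

    for chrom in frags["chrom"].unique():
        if chrom not in genome:
            raise ValueError(f"fragment chromosome {chrom!r} not in genome table")
    lengths = frags["chrom"].map(dict(genome.items())).to_numpy()
    starts = frags["start"].to_numpy()
    ends = frags["end"].to_numpy()
    bad = (starts < 0) | (ends > lengths)
    if bad.any():
        row = frags[bad].iloc[0]
        raise ValueError(
            f"fragment off chromosome: {row['chrom']}:{row['start']}-{row['end']} "
            f"(barcode {row['barcode']})"
        )

    left_center = starts + PLUS_SHIFT
    right_center = (ends - 1) + MINUS_SHIFT
    centers = np.concatenate([left_center, right_center])
    chroms = np.tile(frags["chrom"].to_numpy(), 2)
    cells = np.tile(frags["barcode"].to_numpy(), 2)
    lens2 = np.tile(lengths, 2)

    win_start = np.clip(centers - CUTSITE_HALF_WIDTH, 0, lens2)
    win_end = np.clip(centers + CUTSITE_HALF_WIDTH, 0, lens2)
    nonempty = win_start < win_end
    n_dropped = int((~nonempty).sum())
    if n_dropped:
        logger.info("dropped %d zero-width cut-site windows after clipping", n_dropped)

    out = pd.DataFrame(
        {
            "chrom": chroms[nonempty],
            "start": win_start[nonempty].astype(np.int64),
            "end": win_end[nonempty].astype(np.int64),
            "cell": cells[nonempty],
        }
    )
    out = out.sort_values(["chrom", "start", "end", "cell"], kind="stable").reset_index(
        drop=True
    )
    return out, n_dropped


def read_fragments(path) -> pd.DataFrame:
    """Read a fragments file (TSV: chrom, start, end, barcode; gzip ok)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=FRAGMENT_COLUMNS, comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "barcode": str},
    )
    return df


def write_fragments(fragments: pd.DataFrame, path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fragments.to_csv(fh, sep="\t", header=False, index=False)


def read_cutsites(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=CUTSITE_COLUMNS, comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "cell": str},
    )


def write_cutsites(cutsites: pd.DataFrame, path) -> None:
    cutsites.to_csv(path, sep="\t", header=False, index=False)
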