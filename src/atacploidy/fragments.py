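"""Fragment file I/O, interval masks, and fragment-level filtering.

Fragments follow the de-facto 10x "fragments" dialect: tab-separated
``chrom  start  end  barcode  [count]``, 0-based half-open coordinates,
optionally gzip-compressed, ``#`` comment lines allowed.  PCR duplicates
(identical chrom/start/end/barcode tuples) collapse to a single fragment;
a fifth duplicate-count column is ignored for depth purposes.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode"]

#: Per-barcode fragment-count bounds used for the atlas analyses (inclusive).
ATLAS_FRAGMENT_BOUNDS = (1_000, 100_000)
#: Per-barcode fragment-count bounds used for the CNV analyses (inclusive):
#: 5x10^3 to 10^5.5 fragments per nucleus.
CNV_FRAGMENT_BOUNDS = (5_000, int(10 ** 5.5))


class FragmentFileError(ValueError):
    """Raised for malformed fragment files (bad coordinates, empty input)."""


@dataclass
class FragmentSet:
    """Deduplicated, position-sorted fragments for a set of barcodes.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``chrom, start, end, barcode``; sorted by
        (chrom, start, end, barcode); no duplicate rows.
    genome_label : str
        Free-text assembly tag.
    """

    df: pd.DataFrame
    genome_label: str = ""

    def __post_init__(self) -> None:
        self.df = _canonicalize(self.df)

    @property
    def barcodes(self) -> np.ndarray:
        return self.df["barcode"].unique()

    @property
    def n_fragments(self) -> int:
        return len(self.df)

    def barcode_counts(self) -> pd.Series:
        return self.df["barcode"].value_counts()

    def subset_barcodes(self, barcodes) -> "FragmentSet":
        keep = self.df["barcode"].isin(set(barcodes))
        return FragmentSet(self.df.loc[keep].copy(), self.genome_label)

    def chrom_spans(self) -> dict[str, int]:
        """Maximum fragment end per chromosome (a crude genome extent)."""
        return self.df.groupby("chrom", observed=True)["end"].max().to_dict()

    def write(self, path) -> None:
        """Write fragments in the same TSV dialect (gzip if path ends .gz)."""
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            self.df.to_csv(fh, sep="\t", header=False, index=False)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))


@dataclass
class IntervalMask:
    """Per-chromosome disjoint, sorted, half-open intervals.

    Used for simple-repeat exclusion and for replication-origin /
    terminus region membership tests.
    """

    intervals: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, mapping: dict[str, list[tuple[int, int]]]) -> "IntervalMask":
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivals in mapping.items():
            if not len(ivals):
                continue
            arr = np.asarray(sorted(ivals), dtype=np.int64)
            starts, ends = _merge_sorted(arr[:, 0], arr[:, 1])
            out[chrom] = (starts, ends)
        return cls(out)

    @classmethod
    def from_bed(cls, path) -> "IntervalMask":
        """Read a BED (3+ columns, 0-based half-open) into a mask.

        UCSC simple-repeat exports saved as BED are accepted.
        """
        opener = gzip.open if str(path).endswith(".gz") else open
        rows: dict[str, list[tuple[int, int]]] = {}
        with opener(path, "rt") as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                rows.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
        return cls.from_intervals(rows)

    @property
    def chroms(self) -> set[str]:
        return set(self.intervals)

    def contains(self, chrom: str, positions) -> np.ndarray:
        """Vectorized membership: is each position inside a mask interval?"""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self.intervals:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = self.intervals[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        inside = idx >= 0
        inside[inside] = positions[inside] < ends[idx[inside]]
        return inside

    def total_length(self) -> int:
        return int(sum((e - s).sum() for s, e in self.intervals.values()))

    def complement(self, spans: dict[str, tuple[int, int]]) -> "IntervalMask":
        """Complement of the mask within the given per-chromosome spans."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, (lo, hi) in spans.items():
            gaps: list[tuple[int, int]] = []
            cursor = lo
            for s, e in zip(*self.intervals.get(chrom, (np.array([]), np.array([])))):
                s, e = max(int(s), lo), min(int(e), hi)
                if e <= lo or s >= hi:
                    continue
                if s > cursor:
                    gaps.append((cursor, s))
                cursor = max(cursor, e)
            if cursor < hi:
                gaps.append((cursor, hi))
            out[chrom] = gaps
        return IntervalMask.from_intervals(out)


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ms, me = [], []
    for s, e in zip(starts, ends):
        if e <= s:
            raise ValueError(f"invalid interval [{s}, {e})")
        if me and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64)


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df[FRAGMENT_COLUMNS].drop_duplicates()
    df = df.sort_values(FRAGMENT_COLUMNS, kind="mergesort").reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_fragments(
    path,
    min_frag: int | None = None,
    max_frag: int | None = None,
    genome_label: str = "",
) -> FragmentSet:
    """Read a fragments TSV(.gz) into a deduplicated, sorted FragmentSet.

    Barcodes whose total unique-fragment count falls outside the inclusive
    ``[min_frag, max_frag]`` range are dropped.  Malformed lines
    (non-integer coordinates, start >= end, fewer than 4 columns) raise
    :class:`FragmentFileError` naming the offending line number.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    barcodes: list[str] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FragmentFileError(
                    f"{path}: line {lineno}: expected >=4 tab-separated columns"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FragmentFileError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if not 0 <= start < end:
                raise FragmentFileError(
                    f"{path}: line {lineno}: require 0 <= start < end, "
                    f"got [{start}, {end})"
                )
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            barcodes.append(parts[3])
    if not chroms:
        raise FragmentFileError(f"{path}: no fragment records found")
    df = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "barcode": barcodes}
    )
    fs = FragmentSet(df, genome_label=genome_label)
    if min_frag is not None or max_frag is not None:
        counts = fs.barcode_counts()
        lo = -np.inf if min_frag is None else min_frag
        hi = np.inf if max_frag is None else max_frag
        keep = counts.index[(counts >= lo) & (counts <= hi)]
        fs = fs.subset_barcodes(keep)
    return fs


def filter_fragments(
    fs: FragmentSet,
    autosomes: set[str] | None = None,
    repeats: IntervalMask | None = None,
) -> FragmentSet:
    """Retain autosomal fragments with neither end inside a repeat mask.

    The 5' end tested is ``start``; the 3' end tested is ``end - 1``
    (the last covered base under half-open coordinates).  Chromosomes
    present in the fragments but absent from the mask trigger a warning
    and their fragments are kept unmasked.
    """
    df = fs.df
    if autosomes is not None:
        df = df[df["chrom"].isin(autosomes)]
    if repeats is not None and len(df):
        unmasked = sorted(set(df["chrom"]) - repeats.chroms)
        if unmasked:
            warnings.warn(
                "no repeat mask for chromosomes: " + ", ".join(unmasked),
                stacklevel=2,
            )
        keep_parts = []
        for chrom, grp in df.groupby("chrom", sort=False, observed=True):
            bad = repeats.contains(chrom, grp["start"].to_numpy()) | repeats.contains(
                chrom, grp["end"].to_numpy() - 1
            )
            keep_parts.append(grp.loc[~bad])
        df = pd.concat(keep_parts) if keep_parts else df.iloc[:0]
    return FragmentSet(df.copy(), fs.genome_label)


def barcode_qc_table(fs: FragmentSet, min_frag: int, max_frag: int) -> pd.DataFrame:
    """Per-barcode QC table: barcode, n_fragments, retained flag."""
    counts = fs.barcode_counts().sort_index()
    return pd.DataFrame(
        {
            "barcode": counts.index,
            "n_fragments": counts.to_numpy(),
            "retained": (counts.to_numpy() >= min_frag)
            & (counts.to_numpy() <= max_frag),
        }
    ).reset_index(drop=True)
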