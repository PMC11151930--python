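"""Fragment-end depth count statistics (FEDECS).

The observable underlying all inference in this package: for each cell,
the observation points are the *distinct* 5'-end positions (``start`` on
the positive strand) of that cell's fragments; the depth at a point is
the number of the cell's fragments whose half-open interval covers it.
``f[x]`` counts observation points of depth exactly ``x``.  Depth >= 1
always holds (each fragment covers its own 5' end), so depths follow a
zero-truncated distribution under the binomial site model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentSet

DEFAULT_DEPTH_CAP = 6


@dataclass
class Fedecs:
    """Per-barcode fragment-end depth counts.

    ``depth_counts`` is the exact, uncapped tally {depth: n_sites}; the
    capped vector ``f`` accumulates depths >= cap into its last entry.
    The uncapped tally feeds the moment estimator so binning never
    biases it; the capped vector is the EM interchange representation.
    """

    barcode: str
    depth_counts: dict[int, int]
    n_fragments: int
    cap: int = DEFAULT_DEPTH_CAP

    def __post_init__(self) -> None:
        if not self.depth_counts:
            raise ValueError(f"barcode {self.barcode!r}: empty depth tally")
        if any(d < 1 or c < 0 for d, c in self.depth_counts.items()):
            raise ValueError(f"barcode {self.barcode!r}: invalid depth tally")

    @property
    def n_points(self) -> int:
        return sum(self.depth_counts.values())

    @property
    def f(self) -> np.ndarray:
        """Capped counts (f1..f_cap); f[cap] pools all depths >= cap."""
        out = np.zeros(self.cap, dtype=np.int64)
        for depth, count in self.depth_counts.items():
            out[min(depth, self.cap) - 1] += count
        return out


def point_depths(fs: FragmentSet) -> pd.DataFrame:
    """Depth at every distinct 5'-end position, per barcode.

    Returns a DataFrame with columns ``barcode, chrom, pos, depth``.
    For a sorted start array S and end array E of one barcode+chromosome,
    the depth at position q is #{i: S[i] <= q} - #{i: E[i] <= q} --
    fragments started at or before q minus fragments already closed.
    """
    rows = []
    for (barcode, chrom), grp in fs.df.groupby(
        ["barcode", "chrom"], sort=True, observed=True
    ):
        starts = grp["start"].to_numpy()
        ends = np.sort(grp["end"].to_numpy())
        pos = np.unique(starts)
        depth = np.searchsorted(starts, pos, side="right") - np.searchsorted(
            ends, pos, side="right"
        )
        rows.append(
            pd.DataFrame(
                {"barcode": barcode, "chrom": chrom, "pos": pos, "depth": depth}
            )
        )
    if not rows:
        return pd.DataFrame(columns=["barcode", "chrom", "pos", "depth"])
    return pd.concat(rows, ignore_index=True)


def tally_depths(
    depths: np.ndarray, barcode: str, n_fragments: int, cap: int = DEFAULT_DEPTH_CAP
) -> Fedecs:
    counts = Counter(int(d) for d in depths)
    return Fedecs(barcode, dict(counts), n_fragments=n_fragments, cap=cap)


def compute_fedecs(
    fs: FragmentSet, cap: int = DEFAULT_DEPTH_CAP
) -> dict[str, Fedecs]:
    """FEDECS for every barcode of a filtered, deduplicated FragmentSet."""
    pd_table = point_depths(fs)
    frag_counts = fs.barcode_counts()
    out: dict[str, Fedecs] = {}
    for barcode, grp in pd_table.groupby("barcode", sort=True, observed=True):
        out[str(barcode)] = tally_depths(
            grp["depth"].to_numpy(), str(barcode), int(frag_counts[barcode]), cap
        )
    return out


def fedecs_to_frame(feds: dict[str, Fedecs]) -> pd.DataFrame:
    """Interchange table: barcode, n_fragments, f1..f_cap (one row/cell)."""
    if not feds:
        raise ValueError("no cells")
    cap = next(iter(feds.values())).cap
    recs = []
    for barcode in sorted(feds):
        fed = feds[barcode]
        rec = {"barcode": barcode, "n_fragments": fed.n_fragments}
        rec.update({f"f{i + 1}": c for i, c in enumerate(fed.f)})
        recs.append(rec)
    return pd.DataFrame(recs)


def frame_to_fedecs(df: pd.DataFrame) -> dict[str, Fedecs]:
    """Rebuild Fedecs from the interchange table.

    The uncapped tally is unavailable in the TSV, so depths beyond the
    cap are represented at the cap value; moment statistics computed
    from re-read tables are therefore capped approximations.
    """
    fcols = sorted(
        (c for c in df.columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    cap = int(fcols[-1][1:])
    out = {}
    for _, row in df.iterrows():
        counts = {
            int(c[1:]): int(row[c]) for c in fcols if int(row[c]) > 0
        }
        out[str(row["barcode"])] = Fedecs(
            str(row["barcode"]), counts, int(row["n_fragments"]), cap=cap
        )
    return out


def write_fedecs(feds: dict[str, Fedecs], path) -> None:
    fedecs_to_frame(feds).to_csv(path, sep="\t", index=False)


def read_fedecs(path) -> dict[str, Fedecs]:
    return frame_to_fedecs(pd.read_csv(path, sep="\t"))
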