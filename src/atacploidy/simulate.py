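"""Synthetic fragment data with the statistical structure the inference assumes.

The generator realises the binomial site model directly: observation
sites are pre-placed on a synthetic genome at a fixed spacing of twice
the fragment length, so every site's 5' end is covered only by its own
fragments and the depth observed at it equals its own binomial draw.
Two sampling modes exist:

* ``truncate=True`` (default): per-site depths are drawn from
  binomial(p, s) conditioned on >= 1 success, so every one of
  ``n_sites`` sites is observed — this makes
  ``compute_fedecs(simulate_fragments(cfg))`` reproduce
  ``simulate_fedecs(cfg)`` draw-for-draw.
* ``truncate=False``: depths are unconditioned binomial(p, s) on the
  shared site grid and only sites with >= 1 success emit fragments.
  Single-nucleus observed depths are identically distributed in both
  modes, but only the unconditioned mode makes in-silico merging exact:
  pooling k diploid nuclei drawn on the same grid yields
  binomial(2k, s)-truncated depths, hence E[U] = (2k - 1)s.

CNV events multiply the local copy number before drawing, so the whole
window/segment pipeline can be exercised end to end with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .fedecs import DEFAULT_DEPTH_CAP, Fedecs
from .fragments import FragmentSet


@dataclass(frozen=True)
class CnvEvent:
    """Copy-number event: p -> p + copy_delta inside [start, end) of
    ``chrom`` for the first ceil(cell_fraction * n_cells) cells."""

    chrom: str
    start: int
    end: int
    cell_fraction: float
    copy_delta: int


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    ploidies : per-cell ploidy (one entry per cell).
    s : per-site, per-chromosome-copy capture probability.
    n_sites : observation sites per cell.
    fragment_length : minimum fragment length; actual lengths are
        jittered within [fragment_length, 2*fragment_length).
    genome : list of (chrom, length); defaults to one chromosome just
        large enough for the site grid.
    """

    ploidies: list[int]
    s: float = 0.02
    n_sites: int = 50_000
    fragment_length: int = 200
    genome: list[tuple[str, int]] | None = None
    seed: int = 0
    cnv_spec: list[CnvEvent] = field(default_factory=list)
    truncate: bool = True
    barcode_prefix: str = "cell"

    def __post_init__(self) -> None:
        if not 0.0 < self.s < 1.0:
            raise ValueError("require 0 < s < 1")
        if self.n_sites < 1:
            raise ValueError("require n_sites >= 1")
        if any(p < 1 for p in self.ploidies):
            raise ValueError("ploidies must be >= 1")
        if self.genome is None:
            spacing = 2 * self.fragment_length
            self.genome = [("chr1", (self.n_sites + 1) * spacing)]

    @property
    def n_cells(self) -> int:
        return len(self.ploidies)

    def barcodes(self) -> list[str]:
        width = max(4, len(str(self.n_cells - 1)))
        return [f"{self.barcode_prefix}{i:0{width}d}" for i in range(self.n_cells)]


def _site_layout(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic site grid: (chrom index per site, position per site).

    Sites are spread evenly across the genome at a fixed spacing of at
    least twice the fragment length, so no fragment can reach the next
    site and the depth observed at a site is exactly its own draw.
    """
    min_spacing = 2 * cfg.fragment_length
    total = sum(length for _, length in cfg.genome)

    def capacities(spacing: int) -> list[int]:
        return [
            max((length - min_spacing) // spacing, 0) for _, length in cfg.genome
        ]

    spacing = max(min_spacing, (total - min_spacing * len(cfg.genome)) // (cfg.n_sites + 1))
    if sum(capacities(spacing)) < cfg.n_sites:
        spacing = min_spacing
    caps = capacities(spacing)
    if sum(caps) < cfg.n_sites:
        raise ValueError(
            f"genome too small for {cfg.n_sites} sites at spacing {spacing}"
        )
    chrom_idx, pos = [], []
    remaining = cfg.n_sites
    for ci, cap in enumerate(caps):
        take = min(cap, remaining)
        if take > 0:
            chrom_idx.append(np.full(take, ci))
            pos.append(np.arange(take, dtype=np.int64) * spacing)
        remaining -= take
        if remaining == 0:
            break
    return np.concatenate(chrom_idx), np.concatenate(pos)


def _site_ploidies(cfg: SimConfig, cell_index: int, layout) -> np.ndarray:
    """Per-site copy number for one cell, after CNV events."""
    chrom_idx, pos = layout
    p = np.full(cfg.n_sites, cfg.ploidies[cell_index], dtype=np.int64)
    for ev in cfg.cnv_spec:
        n_affected = int(np.ceil(ev.cell_fraction * cfg.n_cells))
        if cell_index >= n_affected:
            continue
        ci = next(
            (i for i, (c, _) in enumerate(cfg.genome) if c == ev.chrom), None
        )
        if ci is None:
            raise ValueError(f"CNV event chromosome {ev.chrom!r} not in genome")
        hit = (chrom_idx == ci) & (pos >= ev.start) & (pos < ev.end)
        p[hit] = p[hit] + ev.copy_delta
    if cfg.truncate and np.any(p < 1):
        raise ValueError("CNV events drove copy number below 1 in truncated mode")
    if np.any(p < 0):
        raise ValueError("CNV events drove copy number below 0")
    return p


def _depth_cdfs(p: int, s: float, truncate: bool) -> np.ndarray:
    """CDF over depths (1..p truncated, or 0..p unconditioned)."""
    if truncate:
        pmf = binom.pmf(np.arange(1, p + 1), p, s) / (1.0 - (1.0 - s) ** p)
    else:
        pmf = binom.pmf(np.arange(0, p + 1), p, s)
    return np.cumsum(pmf)


def _draw_site_depths(
    rng: np.random.Generator, site_p: np.ndarray, s: float, truncate: bool
) -> np.ndarray:
    """Inverse-CDF depths from one uniform draw per site.

    A single ``rng.random`` call per cell keeps the random stream
    independent of the copy-number pattern, so fragment- and
    FEDECS-level simulation of the same config consume identical draws.
    """
    u = rng.random(len(site_p))
    depths = np.zeros(len(site_p), dtype=np.int64)
    for p in np.unique(site_p):
        mask = site_p == p
        if p == 0:
            continue  # unconditioned zero-copy sites are never observed
        cdf = _depth_cdfs(int(p), s, truncate)
        d = np.searchsorted(cdf, u[mask], side="right")
        depths[mask] = d + 1 if truncate else d
    return depths


def _cell_streams(cfg: SimConfig):
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_cells + 1)
    return (
        [np.random.default_rng(c) for c in children[: cfg.n_cells]],
        np.random.default_rng(children[-1]),
    )


def simulate_fedecs(cfg: SimConfig, cap: int = DEFAULT_DEPTH_CAP) -> dict[str, Fedecs]:
    """Per-cell FEDECS drawn from the (truncated) binomial site model."""
    layout = _site_layout(cfg)
    cell_rngs, _ = _cell_streams(cfg)
    out: dict[str, Fedecs] = {}
    for i, barcode in enumerate(cfg.barcodes()):
        site_p = _site_ploidies(cfg, i, layout)
        depths = _draw_site_depths(cell_rngs[i], site_p, cfg.s, cfg.truncate)
        depths = depths[depths >= 1]
        if len(depths) == 0:
            continue
        counts = np.bincount(depths)
        tally = {int(d): int(c) for d, c in enumerate(counts) if d >= 1 and c > 0}
        out[barcode] = Fedecs(barcode, tally, n_fragments=int(depths.sum()), cap=cap)
    return out


def simulate_fragments(cfg: SimConfig) -> FragmentSet:
    """Fragment intervals realising the same draws as simulate_fedecs.

    Each site with depth d >= 1 emits d fragments sharing the site as
    their 5' end, with lengths jittered within
    [fragment_length, 2*fragment_length); duplicate lengths at one site
    of one cell are redrawn until distinct, so a cell's fragments are
    never coordinate-identical (which would collapse as PCR duplicates).
    """
    layout = _site_layout(cfg)
    chrom_idx, pos = layout
    chrom_names = [c for c, _ in cfg.genome]
    cell_rngs, len_rng = _cell_streams(cfg)
    frames = []
    for i, barcode in enumerate(cfg.barcodes()):
        site_p = _site_ploidies(cfg, i, layout)
        depths = _draw_site_depths(cell_rngs[i], site_p, cfg.s, cfg.truncate)
        observed = np.nonzero(depths)[0]
        if not len(observed):
            continue
        site_rep = np.repeat(observed, depths[observed])
        jit = len_rng.integers(0, cfg.fragment_length, size=len(site_rep))
        while True:  # resolve intra-site length collisions
            order = np.lexsort((jit, site_rep))
            dup_sorted = np.zeros(len(order), dtype=bool)
            dup_sorted[1:] = (site_rep[order][1:] == site_rep[order][:-1]) & (
                jit[order][1:] == jit[order][:-1]
            )
            if not dup_sorted.any():
                break
            dup = np.zeros(len(order), dtype=bool)
            dup[order] = dup_sorted
            jit[dup] = len_rng.integers(0, cfg.fragment_length, size=int(dup.sum()))
        starts = pos[site_rep]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": np.asarray(chrom_names, dtype=object)[
                        chrom_idx[site_rep]
                    ],
                    "start": starts,
                    "end": starts + cfg.fragment_length + jit,
                    "barcode": barcode,
                }
            )
        )
    if not frames:
        raise ValueError("simulation produced no fragments")
    return FragmentSet(pd.concat(frames, ignore_index=True), genome_label="synthetic")


def truth_table(cfg: SimConfig) -> pd.DataFrame:
    return pd.DataFrame({"barcode": cfg.barcodes(), "ploidy": cfg.ploidies})


def merge_nuclei_insilico(
    fs: FragmentSet,
    groups: dict[str, list[str]],
    allowed_sizes: tuple[int, ...] | None = (1, 2, 4),
) -> FragmentSet:
    """Pool fragments of each barcode group under a new synthetic barcode.

    Mirrors the construction of in-silico polyploids: merging 2 (4)
    diploid nuclei emulates a tetraploid (octoploid).  Coordinate-
    identical fragments arising across members collapse to one, exactly
    as PCR duplicates would in a real assay.
    """
    seen: set[str] = set()
    for new_bc, members in groups.items():
        if allowed_sizes is not None and len(members) not in allowed_sizes:
            raise ValueError(
                f"group {new_bc!r} has {len(members)} members; "
                f"allowed sizes are {allowed_sizes}"
            )
        dup = seen.intersection(members)
        if dup:
            raise ValueError(f"overlapping groups: barcodes {sorted(dup)} reused")
        seen.update(members)
    rename = {m: new_bc for new_bc, members in groups.items() for m in members}
    df = fs.df[fs.df["barcode"].isin(rename)].copy()
    df["barcode"] = df["barcode"].map(rename)
    return FragmentSet(df, genome_label=fs.genome_label)


def merge_design(
    barcodes: list[str], seed: int = 0, sizes: tuple[int, ...] = (1, 2, 4)
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Random partition into merge groups of the given sizes.

    Draws groups of ``sum(sizes)`` nuclei repeatedly (as many complete
    draws as the cohort allows) and splits each into one group per size.
    Returns (groups, truth) where truth maps each synthetic barcode to
    its intended ploidy 2*size.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.asarray(barcodes, dtype=object))
    per_rep = sum(sizes)
    n_rep = len(order) // per_rep
    groups: dict[str, list[str]] = {}
    truth = []
    cursor = 0
    for rep in range(n_rep):
        for size in sizes:
            members = list(order[cursor : cursor + size])
            cursor += size
            new_bc = f"merge{rep:05d}_x{size}"
            groups[new_bc] = members
            truth.append({"barcode": new_bc, "ploidy": 2 * size})
    return groups, pd.DataFrame(truth)


def classification_metrics(truth, predicted) -> pd.DataFrame:
    """Per-class sensitivity, specificity, precision and NPV.

    NPV for a class c is, among items NOT predicted c, the fraction
    truly not c — for diploids this is the probability that a cell
    flagged as polyploid really is polyploid.
    """
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("truth and prediction must align")
    rows = []
    for c in np.unique(np.concatenate([t, p])):
        tp = np.sum((t == c) & (p == c))
        fn = np.sum((t == c) & (p != c))
        fp = np.sum((t != c) & (p == c))
        tn = np.sum((t != c) & (p != c))
        rows.append(
            {
                "class": c,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
                "precision": tp / (tp + fp) if tp + fp else np.nan,
                "npv": tn / (tn + fn) if tn + fn else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("class")
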