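"""Replication (S-phase) scoring from origin- vs terminus-region depth.

In mid-S-phase cells the DNA copy number — and hence the fragment-overlap
statistic U — is elevated near replication origins, where replication has
already fired, relative to replication termini, where it has not.  In G1
cells the origin/terminus ratio is constant regardless of ploidy, so an
ordinary least-squares fit of U_ori on U_ter across cells captures the
resting relationship and its residual is the S-phase score: positive
values flag cells with an origin-proximal copy-number excess, i.e.
active replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fedecs import point_depths, tally_depths
from .fragments import FragmentSet, IntervalMask
from .moment import estimate_u

ORIGIN_FLANK_CAP = 50_000  # bp


@dataclass
class OriginRegions:
    """Origin-flank intervals and their terminus complement."""

    origin_intervals: IntervalMask
    terminus_intervals: IntervalMask
    spans: dict[str, tuple[int, int]]


def origin_flank_regions(
    origins: dict[str, np.ndarray], cap: int = ORIGIN_FLANK_CAP
) -> OriginRegions:
    """Flank each origin by a quarter of the gap to its neighbours.

    For origin o with neighbours o_prev and o_next the region is
    [o - min((o - o_prev)/4, cap), o + min((o_next - o)/4, cap));
    the first and last origin of a chromosome use the cap on their open
    side.  Termini are the complement within the covered span
    [first - cap, last + cap).
    """
    ori: dict[str, list[tuple[int, int]]] = {}
    spans: dict[str, tuple[int, int]] = {}
    for chrom, pos in origins.items():
        pos = np.asarray(pos, dtype=np.int64)
        if len(pos) < 2:
            raise ValueError(f"{chrom}: need >= 2 origins per chromosome")
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{chrom}: origins must be sorted and distinct")
        half_left = np.minimum(np.diff(pos) / 4.0, cap)
        lefts = np.concatenate([[cap], half_left])
        rights = np.concatenate([half_left, [cap]])
        lo = np.floor(pos - lefts).astype(np.int64)
        hi = np.floor(pos + rights).astype(np.int64)
        lo = np.maximum(lo, 0)
        ori[chrom] = list(zip(lo.tolist(), hi.tolist()))
        spans[chrom] = (int(max(pos[0] - cap, 0)), int(pos[-1] + cap))
    origin_mask = IntervalMask.from_intervals(ori)
    terminus_mask = origin_mask.complement(spans)
    return OriginRegions(origin_mask, terminus_mask, spans)


def read_origins_bed(path) -> dict[str, np.ndarray]:
    """Origins from BED; a point origin is the interval midpoint."""
    mask = IntervalMask.from_bed(path)
    return {
        chrom: np.unique((starts + ends) // 2)
        for chrom, (starts, ends) in mask.intervals.items()
    }


def regional_u(fs: FragmentSet, regions: OriginRegions) -> pd.DataFrame:
    """Per-cell U over origin-region and terminus-region observation points.

    Observation points (distinct 5' ends) keep the depth computed from
    *all* of the cell's fragments; only the tally is restricted by
    region membership.  Cells lacking points in either region class are
    excluded (listed in ``attrs['excluded']``).
    """
    pts = point_depths(fs)
    in_ori = np.zeros(len(pts), dtype=bool)
    in_ter = np.zeros(len(pts), dtype=bool)
    for chrom, grp in pts.groupby("chrom", sort=False, observed=True):
        idx = grp.index.to_numpy()
        in_ori[idx] = regions.origin_intervals.contains(chrom, grp["pos"].to_numpy())
        in_ter[idx] = regions.terminus_intervals.contains(chrom, grp["pos"].to_numpy())
    rows, excluded = [], []
    for barcode, grp in pts.groupby("barcode", sort=True, observed=True):
        idx = grp.index.to_numpy()
        d_ori = grp.loc[in_ori[idx], "depth"].to_numpy()
        d_ter = grp.loc[in_ter[idx], "depth"].to_numpy()
        if len(d_ori) == 0 or len(d_ter) == 0:
            excluded.append(str(barcode))
            continue
        u_ori = estimate_u(tally_depths(d_ori, str(barcode), 0)).u
        u_ter = estimate_u(tally_depths(d_ter, str(barcode), 0)).u
        rows.append(
            {
                "barcode": str(barcode),
                "u_ori": u_ori,
                "u_ter": u_ter,
                "n_points_ori": len(d_ori),
                "n_points_ter": len(d_ter),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def sphase_score(
    u_table: pd.DataFrame, r2_warn: float = 0.8
) -> tuple[pd.DataFrame, float]:
    """Residual S-phase score from OLS of u_ori on u_ter (with intercept).

    Returns (table with a ``score`` column, R^2 of the fit).  A warning
    is emitted when the terminus statistic explains the origin statistic
    poorly (R^2 below ``r2_warn``), in which case the score is unlikely
    to isolate replication signal.
    """
    if len(u_table) < 3:
        raise ValueError("need >= 3 cells to fit the origin-terminus regression")
    exog = sm.add_constant(u_table["u_ter"].to_numpy())
    res = sm.OLS(u_table["u_ori"].to_numpy(), exog).fit()
    out = u_table.copy()
    out["score"] = res.resid
    r2 = float(res.rsquared)
    if r2 < r2_warn:
        warnings.warn(
            f"origin-terminus regression R^2 = {r2:.3f} < {r2_warn}: "
            "S-phase scores may be unreliable",
            stacklevel=2,
        )
    return out, r2


def sphase_group_test(scores: pd.DataFrame) -> pd.DataFrame:
    """Group-level departure of the origin excess from a baseline group.

    Refits u_ori on u_ter with group indicators (and sum-coded
    experiment covariates when more than one experiment is present).
    The baseline is the group whose coefficient is the ceil(n/4)-th
    smallest (the first-quartile rank); each group's departure from it
    is tested two-sided via a linear contrast.
    """
    required = {"u_ori", "u_ter", "group"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    groups = sorted(scores["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    G = np.zeros((len(scores), len(groups)))
    garr = scores["group"].to_numpy()
    for j, g in enumerate(groups):
        G[garr == g, j] = 1.0
    cols = [G, scores["u_ter"].to_numpy()[:, None]]
    if "experiment" in scores.columns:
        exps = sorted(scores["experiment"].unique())
        if len(exps) > 1:
            E = np.zeros((len(scores), len(exps) - 1))
            earr = scores["experiment"].to_numpy()
            for j, e in enumerate(exps[:-1]):
                E[earr == e, j] = 1.0
            E[earr == exps[-1], :] = -1.0
            cols.append(E)
    exog = np.column_stack(cols)
    res = sm.OLS(scores["u_ori"].to_numpy(), exog).fit()
    coefs = res.params[: len(groups)]
    rank = max(int(np.ceil(len(groups) / 4)), 1)
    baseline_idx = int(np.argsort(coefs, kind="mergesort")[rank - 1])

    rows = []
    for j, g in enumerate(groups):
        contrast = np.zeros(exog.shape[1])
        contrast[j] = 1.0
        contrast[baseline_idx] -= 1.0
        if j == baseline_idx:
            est, se, p = 0.0, 0.0, 1.0
        else:
            tt = res.t_test(contrast)
            est = float(np.squeeze(tt.effect))
            se = float(np.squeeze(tt.sd))
            p = float(np.squeeze(tt.pvalue))
        rows.append(
            {
                "group": g,
                "estimate": est,
                "se": se,
                "p_two_sided": p,
                "is_baseline": j == baseline_idx,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["baseline_group"] = groups[baseline_idx]
    return out


class SPhaseModel:
    """S-phase scoring model over per-cell origin/terminus U statistics.

    Construct either from a FragmentSet plus OriginRegions, or directly
    from a table with ``u_ori``/``u_ter`` (and optional ``group``,
    ``experiment``) columns via :meth:`from_table`.
    """

    def __init__(self, fs: FragmentSet, regions: OriginRegions, annotations=None):
        table = regional_u(fs, regions)
        if annotations is not None:
            table = table.merge(annotations, on="barcode", how="left")
        self.u_table = table
        self.excluded = table.attrs.get("excluded", [])

    @classmethod
    def from_table(cls, u_table: pd.DataFrame) -> "SPhaseModel":
        obj = cls.__new__(cls)
        obj.u_table = u_table
        obj.excluded = u_table.attrs.get("excluded", [])
        return obj

    def fit(self, r2_warn: float = 0.8) -> "SPhaseResults":
        scored, r2 = sphase_score(self.u_table, r2_warn=r2_warn)
        group_table = None
        if "group" in scored.columns and scored["group"].nunique() > 1:
            group_table = sphase_group_test(scored)
        return SPhaseResults(self, scored, r2, group_table)


class SPhaseResults:
    def __init__(self, model, scores, r2, group_table):
        self.model = model
        self.scores = scores
        self.r2 = r2
        self.group_table = group_table

    def summary(self) -> str:
        lines = [
            "S-phase score (residual of U_ori on U_ter)",
            f"  cells scored:     {len(self.scores)} "
            f"(excluded: {len(self.model.excluded)})",
            f"  regression R^2:   {self.r2:.4f}",
        ]
        if self.group_table is not None:
            lines.append(
                f"  baseline group:   {self.group_table.attrs['baseline_group']}"
            )
            lines.append(
                f"  groups tested:    {len(self.group_table)}"
            )
        return "\n".join(lines)

    def to_tsv(self, path, group_path=None) -> None:
        self.scores.to_csv(path, sep="\t", index=False)
        if group_path is not None and self.group_table is not None:
            self.group_table.to_csv(group_path, sep="\t", index=False)
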