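"""Shared copy-number variation calling from windowed depth statistics.

Pipeline: (1) the overlap statistic U is computed per cell for every
20 Mb genomic window; (2) U is corrected for chromatin accessibility by
a robust (Huber) regression fitted on diploid cells, yielding U' ~ U/s;
(3) each cell-window's copy number is rescaled as if the cell were
diploid, p_tilde = 2*(U'_cw + 1)/(U'_cell + 1) with U'_cell the cell's
median over windows, and flagged gain (p_tilde >= 3) or loss (<= 1);
(4) runs of >= 2 consecutive windows whose gain (or loss) flags
concentrate in a subset of cells are scored by the drop in BIC from a
single-rate Bernoulli model of the 0/1 flag matrix to a two-block model
(one rate inside the cells-by-windows block, one outside), and accepted
greedily from the most negative ΔBIC, without overlap within a kind.

Because the block's cell subset and window span are themselves chosen to
maximise the likelihood, raw ΔBIC < 0 is anticonservative; the greedy
selector therefore additionally discounts the number of candidate
configurations (a Bayes-factor correction with a uniform prior over
blocks) and requires a minimum member-cell count.  The raw ΔBIC remains
the reported statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .fedecs import point_depths
from .fragments import FragmentSet

DEFAULT_WINDOW_SIZE = 20_000_000
MIN_TERMINAL_WINDOW = 10_000_000
DEFAULT_MIN_POINTS = 50
GAIN, LOSS, NEUTRAL = 1, -1, 0
STATE_CODES = {GAIN: "gain", LOSS: "loss", NEUTRAL: "neutral"}


def make_windows(
    chrom_lengths: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_terminal: int = MIN_TERMINAL_WINDOW,
) -> pd.DataFrame:
    """Fixed-width windows; short terminal remainders merge backwards."""
    if window_size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        edges = list(range(0, length, window_size)) + [length]
        if len(edges) > 2 and edges[-1] - edges[-2] < min_terminal:
            del edges[-2]
        for lo, hi in zip(edges[:-1], edges[1:]):
            rows.append({"chrom": chrom, "start": lo, "end": hi})
    return pd.DataFrame(rows)


@dataclass
class WindowMatrix:
    """Cells x windows container for U and its derivatives.

    ``U``, ``n_points`` (and later ``U_prime``, ``p_tilde``, ``state``)
    are DataFrames indexed by barcode with one column per window row of
    ``windows``; NaN marks missing (insufficient observation points).
    ``state`` uses +1 gain / -1 loss / 0 neutral / NaN missing.
    """

    windows: pd.DataFrame
    U: pd.DataFrame
    n_points: pd.DataFrame
    U_prime: pd.DataFrame | None = None
    p_tilde: pd.DataFrame | None = None
    state: pd.DataFrame | None = None
    cell_ploidy: pd.Series | None = None

    @property
    def barcodes(self) -> list[str]:
        return list(self.U.index)

    @classmethod
    def from_state(cls, state: pd.DataFrame, windows: pd.DataFrame) -> "WindowMatrix":
        """Build a matrix directly from a state matrix (for segment calling)."""
        nan = state * np.nan
        return cls(windows=windows, U=nan, n_points=nan, state=state)


def window_u_matrix(
    fs: FragmentSet,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_points: int = DEFAULT_MIN_POINTS,
    chrom_lengths: dict[str, int] | None = None,
) -> WindowMatrix:
    """Per cell-window U from FEDECS restricted to the window."""
    if window_size <= 0:
        raise ValueError("window size must be positive")
    if chrom_lengths is None:
        chrom_lengths = fs.chrom_spans()
    windows = make_windows(chrom_lengths, window_size)
    pts = point_depths(fs)

    widx = np.full(len(pts), -1, dtype=np.int64)
    for chrom, grp in pts.groupby("chrom", sort=False, observed=True):
        wrows = windows.index[windows["chrom"] == chrom]
        if not len(wrows):
            continue
        starts = windows.loc[wrows, "start"].to_numpy()
        ends = windows.loc[wrows, "end"].to_numpy()
        pos = grp["pos"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(wrows) - 1)])
        widx[grp.index.to_numpy()[ok]] = wrows.to_numpy()[j[ok]]
    pts = pts.assign(window=widx)
    pts = pts[pts["window"] >= 0]

    barcodes = sorted(map(str, fs.barcodes))
    n_w = len(windows)
    U = pd.DataFrame(np.nan, index=barcodes, columns=range(n_w))
    n_points = pd.DataFrame(0.0, index=barcodes, columns=range(n_w))
    agg = pts.groupby(["barcode", "window"], observed=True)["depth"].agg(
        t1="sum", t2=lambda d: float(np.sum(np.asarray(d, dtype=float) ** 2)), n="count"
    )
    for (barcode, w), row in agg.iterrows():
        n_points.loc[str(barcode), w] = row["n"]
        if row["n"] >= min_points:
            U.loc[str(barcode), w] = row["t2"] / row["t1"] - 1.0
    return WindowMatrix(windows=windows, U=U, n_points=n_points)


def accessibility_vector(windows: pd.DataFrame, acc: pd.DataFrame) -> np.ndarray:
    """Mean accessibility of covariate rows overlapping each window."""
    values = np.full(len(windows), np.nan)
    for i, w in windows.iterrows():
        rows = acc[
            (acc["chrom"] == w["chrom"])
            & (acc["end"] > w["start"])
            & (acc["start"] < w["end"])
        ]
        if len(rows):
            values[i] = rows["value"].mean()
    return values


def normalize_u(
    wm: WindowMatrix,
    accessibility=None,
    diploid_cells=None,
) -> WindowMatrix:
    """Accessibility-corrected U' = U / fitted, fitted on diploid cells.

    A Huber robust regression (tuning constant 1.345) of the diploid
    cells' U on the per-window accessibility covariate gives a fitted
    value varying only by window; dividing by it removes both the
    accessibility effect and the overall capture scale s, so U'
    estimates U/s.  Without a covariate an intercept-only robust fit is
    used (a pure rescaling) and a warning is emitted.
    """
    if diploid_cells is None or not len(diploid_cells):
        raise ValueError("normalize_u requires a nonempty diploid cell subset")
    diploid_cells = [b for b in diploid_cells if b in wm.U.index]
    if not diploid_cells:
        raise ValueError("none of the diploid cells are present in the matrix")
    n_w = wm.U.shape[1]
    if accessibility is None:
        warnings.warn(
            "no accessibility covariate: intercept-only robust fit "
            "(correction is a pure rescaling)",
            stacklevel=2,
        )
        acc = None
    else:
        if isinstance(accessibility, pd.DataFrame):
            acc = accessibility_vector(wm.windows, accessibility)
        else:
            acc = np.asarray(accessibility, dtype=float)
        if len(acc) != n_w or not np.all(np.isfinite(acc)):
            raise ValueError("accessibility must supply one finite value per window")

    Ud = wm.U.loc[diploid_cells].to_numpy()
    mask = np.isfinite(Ud)
    y = Ud[mask]
    if acc is None:
        exog = np.ones((len(y), 1))
    else:
        x = np.broadcast_to(acc, Ud.shape)[mask]
        exog = sm.add_constant(x)
    rlm = sm.RLM(y, exog, M=sm.robust.norms.HuberT(t=1.345))
    res = rlm.fit(conv="coefs", tol=1e-8)
    if acc is None:
        fitted = np.full(n_w, float(res.params[0]))
    else:
        fitted = res.params[0] + res.params[1] * acc

    bad = fitted <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} windows have non-positive fitted accessibility; "
            "set to missing",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        Up = wm.U.to_numpy() / fitted[None, :]
    Up[:, bad] = np.nan
    wm.U_prime = pd.DataFrame(Up, index=wm.U.index, columns=wm.U.columns)
    return wm


def call_gain_loss(wm: WindowMatrix) -> WindowMatrix:
    """Normalized cell-window ploidy and gain/loss/neutral states.

    p_tilde = 2*(U'_cw + 1)/(U'_cell + 1), with U'_cell the median of
    the cell's non-missing U'.  Gain when p_tilde >= 3 (one extra copy
    on a diploid baseline), loss when p_tilde <= 1.
    """
    if wm.U_prime is None:
        raise ValueError("run normalize_u first")
    Up = wm.U_prime.to_numpy()
    if np.all(~np.isfinite(Up), axis=1).any():
        raise ValueError("some cells have no non-missing windows")
    u_cell = np.nanmedian(Up, axis=1)
    p_tilde = 2.0 * (Up + 1.0) / (u_cell[:, None] + 1.0)
    state = np.where(p_tilde >= 3.0, GAIN, np.where(p_tilde <= 1.0, LOSS, NEUTRAL))
    state = np.where(np.isfinite(p_tilde), state, np.nan)
    wm.p_tilde = pd.DataFrame(p_tilde, index=wm.U.index, columns=wm.U.columns)
    wm.state = pd.DataFrame(state, index=wm.U.index, columns=wm.U.columns)
    return wm


# ---------------------------------------------------------------------------
# ΔBIC block scan


def _bern_ll(ones: float, n: float) -> float:
    """Bernoulli log-likelihood at the MLE rate; 0*log(0) = 0."""
    if n <= 0:
        return 0.0
    out = 0.0
    if ones > 0:
        out += ones * np.log(ones / n)
    if n - ones > 0:
        out += (n - ones) * np.log((n - ones) / n)
    return out


@dataclass
class BlockCandidate:
    chrom: str
    w_lo: int  # window indices, inclusive
    w_hi: int
    cells: list[str]
    delta_bic: float
    inside_rate: float
    outside_rate: float


def _chrom_series(windows: pd.DataFrame):
    """All within-chromosome runs of >= 2 consecutive windows."""
    for chrom in windows["chrom"].unique():
        idx = windows.index[windows["chrom"] == chrom].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                yield chrom, idx[a : b + 1]


def n_candidate_series(windows: pd.DataFrame) -> int:
    counts = windows["chrom"].value_counts()
    return int(sum(w * (w - 1) // 2 for w in counts))


def scan_blocks(
    B: np.ndarray, windows: pd.DataFrame, barcodes: list[str]
) -> list[BlockCandidate]:
    """Best prefix-subset block per window series (hot direction).

    Cells are ranked by their proportion of 1s within the series and the
    top-k prefix evaluated for every k; the k minimising the two-block
    BIC is retained.  With no missing entries this attains, per series,
    the maximal inside-ones count achievable by any subset of each size.
    """
    finite = np.isfinite(B)
    N = int(finite.sum())
    T = float(np.nansum(B))
    if N == 0 or T == 0:
        return []
    ll1 = _bern_ll(T, N)
    logN = np.log(N)
    out: list[BlockCandidate] = []
    for chrom, idx in _chrom_series(windows):
        sub = B[:, idx]
        m = np.isfinite(sub).sum(axis=1).astype(float)
        o = np.nansum(sub, axis=1)
        usable = m > 0
        if not usable.any():
            continue
        prop = np.where(usable, o / np.maximum(m, 1), -1.0)
        order = np.lexsort((np.arange(len(prop)), -o, -prop))
        order = order[usable[order]]
        cm = np.cumsum(m[order])
        co = np.cumsum(o[order])
        best = None
        for k in range(1, len(order) + 1):
            n_in, n1 = cm[k - 1], co[k - 1]
            ll2 = _bern_ll(n1, n_in) + _bern_ll(T - n1, N - n_in)
            dbic = -2.0 * (ll2 - ll1) + logN
            if best is None or dbic < best[0] - 1e-12:
                best = (dbic, k, n1, n_in)
        dbic, k, n1, n_in = best
        inside_rate = n1 / n_in if n_in else 0.0
        outside_rate = (T - n1) / (N - n_in) if N > n_in else 0.0
        out.append(
            BlockCandidate(
                chrom=str(chrom),
                w_lo=int(idx[0]),
                w_hi=int(idx[-1]),
                cells=[barcodes[i] for i in order[:k]],
                delta_bic=float(dbic),
                inside_rate=float(inside_rate),
                outside_rate=float(outside_rate),
            )
        )
    return out


def best_block_delta_bic(B: np.ndarray, windows: pd.DataFrame) -> float:
    """Smallest raw ΔBIC over all series and prefix subsets, both
    directions (enriched and depleted blocks).

    With no missing entries this equals the optimum over *all* cell
    subsets, because the two-block log-likelihood is convex in the
    inside-ones count at fixed subset size, so the extremes — attained
    by descending- and ascending-proportion prefixes — dominate.
    """
    finite = np.isfinite(B)
    N = int(finite.sum())
    T = float(np.nansum(B))
    if N == 0:
        return 0.0
    ll1 = _bern_ll(T, N)
    logN = np.log(N)
    best = np.inf
    for _, idx in _chrom_series(windows):
        sub = B[:, idx]
        m = np.isfinite(sub).sum(axis=1).astype(float)
        o = np.nansum(sub, axis=1)
        usable = m > 0
        if not usable.any():
            continue
        prop = o / np.maximum(m, 1)
        for sign in (-1.0, 1.0):
            order = np.lexsort((np.arange(len(prop)), sign * o, sign * prop))
            order = order[usable[order]]
            cm = np.cumsum(m[order])
            co = np.cumsum(o[order])
            ll2 = np.array(
                [
                    _bern_ll(co[k], cm[k]) + _bern_ll(T - co[k], N - cm[k])
                    for k in range(len(order))
                ]
            )
            dbic = -2.0 * (ll2 - ll1) + logN
            best = min(best, float(dbic.min()))
    return best


def _selection_penalty(n_cells: int, k: int, n_series: int) -> float:
    """2*log of the number of block configurations of this shape."""
    log_choose = (
        gammaln(n_cells + 1) - gammaln(k + 1) - gammaln(n_cells - k + 1)
    )
    return 2.0 * (np.log(max(n_series, 1)) + log_choose)


@dataclass
class CnvSegment:
    kind: str  # 'gain' | 'loss'
    chrom: str
    window_lo: int
    window_hi: int
    start: int
    end: int
    member_cells: list[str] = field(repr=False)
    delta_bic: float = 0.0
    inside_rate: float = 0.0
    outside_rate: float = 0.0

    @property
    def n_member_cells(self) -> int:
        return len(self.member_cells)


def detect_cnv_segments(
    wm: WindowMatrix,
    min_member_cells: int = 3,
    multiplicity_penalty: bool = True,
) -> list[CnvSegment]:
    """Greedy selection of shared gain/loss segments by ΔBIC.

    Gains and losses are scanned independently; accepted segments of the
    same kind never overlap in windows.  A candidate is accepted when
    its raw ΔBIC is negative, every window of the series is individually
    enriched in the member cells relative to the rest of the matrix (so
    a single aberrant window cannot ride in on a neutral neighbour), it
    has at least ``min_member_cells`` members, and (by default) the ΔBIC
    survives the configuration-count discount.
    """
    if wm.state is None:
        raise ValueError("state matrix not computed")
    state = wm.state.to_numpy(dtype=float)
    barcodes = wm.barcodes
    bc_row = {b: i for i, b in enumerate(barcodes)}
    n_cells = state.shape[0]
    n_series = n_candidate_series(wm.windows)
    segments: list[CnvSegment] = []
    for kind, code in (("gain", GAIN), ("loss", LOSS)):
        B = np.where(np.isfinite(state), (state == code).astype(float), np.nan)
        candidates = scan_blocks(B, wm.windows, barcodes)
        accepted: list[CnvSegment] = []
        taken: dict[str, list[tuple[int, int]]] = {}
        for cand in sorted(
            candidates, key=lambda c: (c.delta_bic, c.chrom, c.w_lo, c.w_hi)
        ):
            if cand.delta_bic >= 0:
                continue
            if cand.inside_rate <= cand.outside_rate:
                continue
            if len(cand.cells) < min_member_cells:
                continue
            rows = [bc_row[b] for b in cand.cells]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                per_window = np.nanmean(
                    B[np.ix_(rows, range(cand.w_lo, cand.w_hi + 1))], axis=0
                )
            if not np.all(per_window > cand.outside_rate):
                continue
            if multiplicity_penalty:
                penalty = _selection_penalty(n_cells, len(cand.cells), n_series)
                if cand.delta_bic + penalty >= 0:
                    continue
            overlap = any(
                not (cand.w_hi < lo or cand.w_lo > hi)
                for lo, hi in taken.get(cand.chrom, [])
            )
            if overlap:
                continue
            taken.setdefault(cand.chrom, []).append((cand.w_lo, cand.w_hi))
            accepted.append(
                CnvSegment(
                    kind=kind,
                    chrom=cand.chrom,
                    window_lo=cand.w_lo,
                    window_hi=cand.w_hi,
                    start=int(wm.windows.loc[cand.w_lo, "start"]),
                    end=int(wm.windows.loc[cand.w_hi, "end"]),
                    member_cells=cand.cells,
                    delta_bic=cand.delta_bic,
                    inside_rate=cand.inside_rate,
                    outside_rate=cand.outside_rate,
                )
            )
        segments.extend(accepted)
    return segments


def segments_to_frame(segments: list[CnvSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "kind": s.kind,
                "n_member_cells": s.n_member_cells,
                "delta_bic": s.delta_bic,
                "inside_rate": s.inside_rate,
                "outside_rate": s.outside_rate,
            }
            for s in segments
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "kind",
            "n_member_cells",
            "delta_bic",
            "inside_rate",
            "outside_rate",
        ],
    )


class CnvModel:
    """CNV detection model over a windowed U matrix.

    Parameters
    ----------
    wm : WindowMatrix with raw U (see :func:`window_u_matrix`).
    accessibility : optional per-window covariate (array or
        chrom/start/end/value DataFrame).
    diploid_cells : barcodes treated as the diploid reference for the
        accessibility regression (from ploidy inference with P = {2, 4}).
    """

    def __init__(self, wm: WindowMatrix, accessibility=None, diploid_cells=None):
        self.wm = wm
        self.accessibility = accessibility
        self.diploid_cells = diploid_cells

    @classmethod
    def from_fragments(
        cls,
        fs: FragmentSet,
        window_size: int = DEFAULT_WINDOW_SIZE,
        min_points: int = DEFAULT_MIN_POINTS,
        accessibility=None,
        diploid_cells=None,
        chrom_lengths=None,
    ) -> "CnvModel":
        wm = window_u_matrix(fs, window_size, min_points, chrom_lengths)
        return cls(wm, accessibility, diploid_cells)

    def fit(
        self, min_member_cells: int = 3, multiplicity_penalty: bool = True
    ) -> "CnvResults":
        wm = self.wm
        if wm.U_prime is None:
            normalize_u(wm, self.accessibility, self.diploid_cells)
        if wm.state is None:
            call_gain_loss(wm)
        segments = detect_cnv_segments(
            wm, min_member_cells=min_member_cells,
            multiplicity_penalty=multiplicity_penalty,
        )
        return CnvResults(self, wm, segments)


class CnvResults:
    def __init__(self, model, wm: WindowMatrix, segments: list[CnvSegment]):
        self.model = model
        self.wm = wm
        self.segments = segments

    @property
    def segment_table(self) -> pd.DataFrame:
        return segments_to_frame(self.segments)

    def summary(self) -> str:
        n_gain = sum(1 for s in self.segments if s.kind == "gain")
        n_loss = sum(1 for s in self.segments if s.kind == "loss")
        lines = [
            "CNV segment detection (two-block Bernoulli ΔBIC)",
            f"  cells x windows:  {self.wm.U.shape[0]} x {self.wm.U.shape[1]}",
            f"  gains:            {n_gain}",
            f"  losses:           {n_loss}",
        ]
        for s in self.segments:
            lines.append(
                f"    {s.kind:<5} {s.chrom}:{s.start}-{s.end} "
                f"cells={s.n_member_cells} dBIC={s.delta_bic:.1f}"
            )
        return "\n".join(lines)

    def matrix_to_tsv(self, path) -> None:
        """Export p_tilde and state codes for external heatmapping."""
        pt = self.wm.p_tilde.copy()
        st = self.wm.state.replace(
            {GAIN: "gain", LOSS: "loss", NEUTRAL: "neutral"}
        ).fillna("missing")
        cols = [
            f"{r.chrom}:{r.start}-{r.end}" for r in self.wm.windows.itertuples()
        ]
        pt.columns = cols
        st.columns = cols
        pt.to_csv(str(path) + ".p_tilde.tsv", sep="\t")
        st.to_csv(str(path) + ".state.tsv", sep="\t")

    def segments_to_tsv(self, path) -> None:
        self.segment_table.to_csv(path, sep="\t", index=False)
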