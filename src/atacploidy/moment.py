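"""Method-of-moments ploidy inference from truncated-binomial depth counts.

Model: at an observed 5'-end site of a p-ploid cell the fragment depth x
follows a binomial(p, s) distribution truncated to x >= 1, where s is the
per-chromosome-copy capture probability.  With T1 = sum x*f_x and
T2 = sum x^2*f_x, the ratio statistic

    U = T2/T1 - 1

estimates (p - 1)*s, because E[T2]/E[T1] - 1 = (p - 1)*s and the unknown
number of sites cancels.  Across a cell mixture, log U clusters at
log(p - 1) + log s for the ploidies p present, at fixed spacing
log(p-1) ratios (2-1):(4-1):(8-1) for a diploid/tetraploid/octoploid mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fedecs import Fedecs

DEFAULT_PLOIDIES = (2, 4, 8)
CNV_PLOIDIES = (2, 4)


@dataclass(frozen=True)
class MomentStats:
    """Raw-moment sums and the ratio statistic for one cell."""

    t1: float
    t2: float
    u: float


def estimate_u(fed: Fedecs | dict[int, int]) -> MomentStats:
    """T1, T2 and U = T2/T1 - 1 from the uncapped depth tally."""
    counts = fed.depth_counts if isinstance(fed, Fedecs) else fed
    if not counts or sum(counts.values()) == 0:
        raise ValueError("empty depth tally: U undefined")
    depths = np.array(list(counts.keys()), dtype=float)
    n = np.array(list(counts.values()), dtype=float)
    t1 = float(np.sum(depths * n))
    t2 = float(np.sum(depths**2 * n))
    return MomentStats(t1, t2, t2 / t1 - 1.0)


def winsorize_log_u(u_values) -> np.ndarray:
    """log U, clipped for robustness to [2*Q1 - med, 2*Q3 - med].

    Quartiles (linear-interpolation convention) are taken over the
    original log U distribution across cells.  Cells with U = 0 carry no
    overlap signal; their log is undefined and they are assigned the
    lower clip bound (the most diploid-leaning value).
    """
    u = np.asarray(u_values, dtype=float)
    if len(u) < 4:
        raise ValueError("need >= 4 cells to define quartiles")
    if np.any(u < 0):
        raise ValueError("negative U encountered")
    pos = u > 0
    if not np.any(pos):
        raise ValueError("all U values are zero: no overlap signal")
    with np.errstate(divide="ignore"):
        logu = np.log(u)
    q1, med, q3 = np.quantile(logu[pos], [0.25, 0.5, 0.75])
    lo, hi = 2 * q1 - med, 2 * q3 - med
    v = np.clip(logu, lo, hi)
    v[~pos] = lo
    return v


def _assign(v: np.ndarray, log_s: float, offsets: np.ndarray) -> np.ndarray:
    """Index of the closest cluster center; ties break to smaller ploidy.

    ``offsets`` is log(p - 1) for sorted candidate ploidies, so argmin
    over squared distance with first-occurrence ties is the conservative
    (smaller-ploidy) assignment.
    """
    d2 = (v[:, None] - (offsets[None, :] + log_s)) ** 2
    return np.argmin(d2, axis=1)


def fit_scale(v_values, ploidies=DEFAULT_PLOIDIES) -> tuple[float, np.ndarray]:
    """Least-squares shared scale s_hat and per-cell ploidy assignment.

    Minimises sum_i min_p (V_i - log(p-1) - log s)^2.  The objective is
    piecewise quadratic in log s; we alternate assignment and the
    closed-form mean update (1-D k-means with fixed cluster offsets),
    multistarting from each candidate ploidy's implied scale.
    Deterministic given the input.
    """
    v = np.asarray(v_values, dtype=float)
    P = np.array(sorted(set(int(p) for p in ploidies)))
    if len(P) == 0 or P[0] < 2:
        raise ValueError("candidate ploidies must all be >= 2")
    offsets = np.log(P - 1.0)
    best = None
    for p0 in offsets:
        log_s = float(np.mean(v)) - p0
        for _ in range(200):
            lab = _assign(v, log_s, offsets)
            new = float(np.mean(v - offsets[lab]))
            if abs(new - log_s) < 1e-12:
                log_s = new
                break
            log_s = new
        else:
            raise RuntimeError(
                "scale optimisation did not converge; "
                f"V range [{v.min():.3g}, {v.max():.3g}], n={len(v)}"
            )
        lab = _assign(v, log_s, offsets)
        obj = float(np.sum((v - offsets[lab] - log_s) ** 2))
        if best is None or obj < best[0] - 1e-15:
            best = (obj, log_s)
    log_s = best[1]
    return float(np.exp(log_s)), _assign(v, log_s, offsets)


def infer_ploidy_moment(
    u_values, ploidies=DEFAULT_PLOIDIES
) -> tuple[float, pd.DataFrame]:
    """Full moment pipeline: winsorize, fit scale, assign ploidies.

    Returns (s_hat, table) where the table has columns
    ``U, V, ploidy, fractional_ploidy`` in input cell order.
    """
    u = np.asarray(u_values, dtype=float)
    P = np.array(sorted(set(int(p) for p in ploidies)))
    if len(P) == 1:
        # single-component closed form: s_hat = exp(mean V) / (p - 1)
        v = winsorize_log_u(u)
        s_hat = float(np.exp(np.mean(v) - np.log(P[0] - 1.0)))
        lab = np.zeros(len(u), dtype=int)
    else:
        v = winsorize_log_u(u)
        s_hat, lab = fit_scale(v, P)
    table = pd.DataFrame(
        {
            "U": u,
            "V": v,
            "ploidy": P[lab],
            "fractional_ploidy": u / s_hat + 1.0,
        }
    )
    return s_hat, table


class MomentPloidyModel:
    """Ploidy inference by the method of moments.

    Parameters
    ----------
    feds : mapping barcode -> Fedecs, or a DataFrame with a ``barcode``
        column plus per-depth counts (the FEDECS interchange table).
    """

    def __init__(self, feds):
        if isinstance(feds, pd.DataFrame):
            from .fedecs import frame_to_fedecs

            feds = frame_to_fedecs(feds)
        self.feds = dict(feds)
        self.barcodes = sorted(self.feds)

    def fit(self, ploidies=DEFAULT_PLOIDIES) -> "MomentPloidyResults":
        stats = [estimate_u(self.feds[b]) for b in self.barcodes]
        u = np.array([st.u for st in stats])
        s_hat, table = infer_ploidy_moment(u, ploidies)
        table.insert(0, "barcode", self.barcodes)
        table.insert(2, "T1", [st.t1 for st in stats])
        table.insert(3, "T2", [st.t2 for st in stats])
        return MomentPloidyResults(self, s_hat, tuple(sorted(set(ploidies))), table)


class MomentPloidyResults:
    """Results of :meth:`MomentPloidyModel.fit`.

    Attributes
    ----------
    s_hat : float
        Shared per-copy capture probability estimate.
    calls : pandas.DataFrame
        barcode, U, T1, T2, V, ploidy, fractional_ploidy.
    """

    def __init__(self, model, s_hat, ploidies, calls):
        self.model = model
        self.s_hat = s_hat
        self.ploidies = ploidies
        self.calls = calls

    @property
    def ploidy(self) -> pd.Series:
        return self.calls.set_index("barcode")["ploidy"]

    def summary(self) -> str:
        counts = self.calls["ploidy"].value_counts().sort_index()
        lines = [
            "Moment-method ploidy inference",
            f"  cells:            {len(self.calls)}",
            f"  candidate set P:  {{{', '.join(map(str, self.ploidies))}}}",
            f"  s_hat:            {self.s_hat:.6g}",
            "  calls:            "
            + ", ".join(f"{p}n: {c}" for p, c in counts.items()),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)
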