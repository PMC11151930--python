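"""Group-level test for an excess of polyploid nuclei.

Each "organ-cell type" group is tested for a higher proportion of
polyploid (ploidy > 2) nuclei than a background level, defined as the
first quartile of the model-based proportion estimates across groups —
the polyploid rate observable even in genuinely diploid cell types.
Experiment identifiers enter the binomial GLM as sum-to-zero-coded
batch covariates so that each group coefficient is the logit proportion
at the average batch; proportions and standard errors are recovered on
the probability scale by the delta method, and the one-sided excess
Z-score is compared against a Bonferroni-corrected normal threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm


def _sum_coded(levels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (effects) coding, dropping the last level."""
    cats = sorted(levels.unique())
    if len(cats) <= 1:
        return np.zeros((len(levels), 0)), []
    cols = cats[:-1]
    X = np.zeros((len(levels), len(cols)))
    arr = levels.to_numpy()
    for j, c in enumerate(cols):
        X[arr == c, j] = 1.0
    X[arr == cats[-1], :] = -1.0
    return X, [f"experiment[{c}]" for c in cols]


def polyploid_excess_test(
    cells: pd.DataFrame,
    alpha: float = 0.01,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Per-group polyploidy-excess test.

    Parameters
    ----------
    cells : DataFrame with columns ``ploidy`` (numeric), ``group`` and
        ``experiment`` (the batch identifier); one row per cell.
    alpha : family-wise significance level.
    n_tests : Bonferroni divisor; defaults to the number of groups in
        this run.

    Returns
    -------
    DataFrame with one row per group: n_cells, n_polyploid,
    prop_estimate, prop_se, z, p_one_sided, significant, boundary;
    the attrs carry ``background``, ``threshold`` and ``n_tests``.
    """
    required = {"ploidy", "group", "experiment"}
    if not required.issubset(cells.columns):
        raise ValueError(f"cells table needs columns {sorted(required)}")
    df = cells.copy()
    df["polyploid"] = (df["ploidy"] > 2).astype(int)

    agg = (
        df.groupby(["group", "experiment"], observed=True)["polyploid"]
        .agg(succ="sum", n="count")
        .reset_index()
    )
    agg["succ"] = agg["succ"].astype(float)
    agg["fail"] = (agg["n"] - agg["succ"]).astype(float)

    groups = sorted(agg["group"].unique())
    totals = agg.groupby("group", observed=True)[["succ", "n"]].sum()
    boundary = {
        g: totals.loc[g, "succ"] == 0 or totals.loc[g, "succ"] == totals.loc[g, "n"]
        for g in groups
    }
    # continuity adjustment keeps boundary-group logits finite (flagged)
    for g in groups:
        if boundary[g]:
            rows = agg["group"] == g
            agg.loc[rows, "succ"] = agg.loc[rows, "succ"] + 0.5
            agg.loc[rows, "fail"] = agg.loc[rows, "fail"] + 0.5

    G = np.zeros((len(agg), len(groups)))
    garr = agg["group"].to_numpy()
    for j, g in enumerate(groups):
        G[garr == g, j] = 1.0
    E, enames = _sum_coded(agg["experiment"])
    exog = np.column_stack([G, E]) if E.shape[1] else G
    names = [f"group[{g}]" for g in groups] + enames

    endog = agg[["succ", "fail"]].to_numpy(dtype=float)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    res = model.fit()

    eta = res.params[: len(groups)]
    se_eta = res.bse[: len(groups)]
    prop = 1.0 / (1.0 + np.exp(-eta))
    prop_se = se_eta * prop * (1.0 - prop)  # delta method on the logit

    background = float(np.quantile(prop, 0.25))
    z = (prop - background) / prop_se
    p = norm.sf(z)
    if n_tests is None:
        n_tests = len(groups)
    threshold = alpha / n_tests

    out = pd.DataFrame(
        {
            "group": groups,
            "n_cells": [int(totals.loc[g, "n"]) for g in groups],
            "n_polyploid": [int(df[df["group"] == g]["polyploid"].sum()) for g in groups],
            "prop_estimate": prop,
            "prop_se": prop_se,
            "z": z,
            "p_one_sided": p,
            "significant": p < threshold,
            "boundary": [bool(boundary[g]) for g in groups],
        }
    )
    out.attrs["background"] = background
    out.attrs["threshold"] = threshold
    out.attrs["n_tests"] = n_tests
    out.attrs["alpha"] = alpha
    out.attrs["param_names"] = names
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


class PolyploidyExcessModel:
    """Binomial-GLM test of polyploid excess per organ-cell-type group."""

    def __init__(self, cells: pd.DataFrame):
        self.cells = cells

    def fit(self, alpha: float = 0.01, n_tests: int | None = None):
        table = polyploid_excess_test(self.cells, alpha=alpha, n_tests=n_tests)
        return PolyploidyExcessResults(self, table)


class PolyploidyExcessResults:
    def __init__(self, model, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def background(self) -> float:
        return self.table.attrs["background"]

    @property
    def threshold(self) -> float:
        return self.table.attrs["threshold"]

    def summary(self) -> str:
        t = self.table
        lines = [
            "Polyploid-excess test (binomial GLM, logit link)",
            f"  groups tested:       {len(t)}",
            f"  background (Q1):     {self.background:.4g}",
            f"  Bonferroni level:    {self.threshold:.3e} "
            f"(alpha {t.attrs['alpha']}, {t.attrs['n_tests']} tests)",
            f"  significant groups:  {int(t['significant'].sum())}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
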