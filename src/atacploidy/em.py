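"""Ploidy classification by an EM-fitted mixture of categorical distributions.

Each cell's capped depth counts over a small set of informative depth
categories — (f2, f3, f4) by default, since f1 dwarfs the rest and
carries little shape information — are modelled as a multinomial draw
with a cell-specific total from one of k component categorical
distributions, one per candidate ploidy.  No binomial shape is imposed
on the component probabilities, which makes the classifier robust to
violations of the uniform-capture assumption behind the moment method.

Components are mapped to ploidies by the size ordering of their
probability on the *last* used category (f4 for the default choice):
higher terminal-depth mass means higher ploidy.  If EM fails to
converge on (f2, f3, f4), the fit is retried on (f3, f4, f5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .fedecs import Fedecs

DEFAULT_CATEGORIES = (2, 3, 4)
FALLBACK_CATEGORIES = (3, 4, 5)
PROB_FLOOR = 1e-10


class EmConvergenceError(RuntimeError):
    """Both category choices failed to converge; carries both trajectories."""

    def __init__(self, trajectories):
        self.trajectories = trajectories
        super().__init__(
            "EM failed to converge on both category choices; "
            f"final log-likelihoods: {[t[-1] for t in trajectories]}"
        )


@dataclass
class EmFit:
    """Fitted mixture of categorical distributions."""

    k: int
    mixing_weights: np.ndarray
    component_probs: np.ndarray  # k x m, rows sum to 1
    responsibilities: np.ndarray  # cells x k, rows sum to 1
    used_categories: tuple[int, ...]
    converged: bool
    loglik: float
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))


def _em_run(
    X: np.ndarray,
    k: int,
    resp0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, list[float]]:
    n = X.shape[0]
    resp = resp0
    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # M step
        weights = resp.sum(axis=0) / n
        probs = resp.T @ X
        probs = np.maximum(probs, 0.0) + PROB_FLOOR
        probs /= probs.sum(axis=1, keepdims=True)
        if np.any(weights < 1.0 / (10.0 * n)):
            converged = False
            break
        # E step (log domain; the multinomial coefficient is component-free)
        log_comp = X @ np.log(probs).T + np.log(weights)[None, :]
        norm = logsumexp(log_comp, axis=1)
        resp = np.exp(log_comp - norm[:, None])
        ll = float(norm.sum())
        trace.append(ll)
        if prev > -np.inf and abs(ll - prev) <= tol * (abs(prev) + 1e-300):
            converged = True
            break
        prev = ll
    return weights, probs, resp, converged, trace


def _init_responsibilities(
    X: np.ndarray, k: int, restart: int, rng: np.random.Generator
) -> np.ndarray:
    n = X.shape[0]
    if restart == 0:
        # deterministic split by the terminal-category fraction
        ratio = X[:, -1] / X.sum(axis=1)
        order = np.argsort(ratio, kind="mergesort")
        resp = np.zeros((n, k))
        for j, chunk in enumerate(np.array_split(order, k)):
            resp[chunk, j] = 1.0
        # slight smoothing so empty categories cannot freeze a component
        resp = 0.9 * resp + 0.1 / k
        return resp
    resp = rng.random((n, k)) + 1e-3
    return resp / resp.sum(axis=1, keepdims=True)


def fit_categorical_mixture(
    counts: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 2,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[EmFit | None, list[float]]:
    """Best converged EM fit over a deterministic init plus random restarts."""
    X = np.asarray(counts, dtype=float)
    rng = np.random.default_rng(seed)
    best: EmFit | None = None
    longest_trace: list[float] = [float("-inf")]
    for restart in range(1 + n_restarts):
        resp0 = _init_responsibilities(X, k, restart, rng)
        weights, probs, resp, converged, trace = _em_run(X, k, resp0, max_iter, tol)
        if trace and trace[-1] > longest_trace[-1]:
            longest_trace = trace
        if converged and (best is None or trace[-1] > best.loglik):
            best = EmFit(
                k=k,
                mixing_weights=weights,
                component_probs=probs,
                responsibilities=resp,
                used_categories=(),
                converged=True,
                loglik=trace[-1],
                loglik_trace=np.asarray(trace),
            )
    return best, longest_trace


def _category_matrix(
    feds: dict[str, Fedecs], barcodes, categories
) -> np.ndarray:
    X = np.zeros((len(barcodes), len(categories)))
    for i, b in enumerate(barcodes):
        f = feds[b].f
        for j, depth in enumerate(categories):
            if depth - 1 < len(f):
                X[i, j] = f[depth - 1]
    return X


def infer_ploidy_em(
    feds: dict[str, Fedecs],
    ploidies=(2, 4, 8),
    seed: int = 0,
    n_restarts: int = 2,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[EmFit, pd.DataFrame, list[str]]:
    """EM ploidy labels for a cell collection.

    Returns (fit, labels table, excluded barcodes).  Cells whose counts
    over the used categories are all zero are excluded and reported.
    """
    P = sorted(set(int(p) for p in ploidies))
    k = len(P)
    barcodes = sorted(feds)
    if k == 1:
        table = pd.DataFrame({"barcode": barcodes, "ploidy": P[0]})
        fit = EmFit(
            k=1,
            mixing_weights=np.array([1.0]),
            component_probs=np.ones((1, 1)),
            responsibilities=np.ones((len(barcodes), 1)),
            used_categories=DEFAULT_CATEGORIES,
            converged=True,
            loglik=0.0,
        )
        return fit, table, []
    if len(barcodes) < 10 * k:
        raise ValueError(f"need >= {10 * k} cells for |P| = {k}, got {len(barcodes)}")

    trajectories = []
    for categories in (DEFAULT_CATEGORIES, FALLBACK_CATEGORIES):
        X_all = _category_matrix(feds, barcodes, categories)
        usable = X_all.sum(axis=1) > 0
        used_barcodes = [b for b, u in zip(barcodes, usable) if u]
        excluded = [b for b, u in zip(barcodes, usable) if not u]
        X = X_all[usable]
        if len(used_barcodes) < 10 * k:
            trajectories.append([float("-inf")])
            continue
        fit, trace = fit_categorical_mixture(
            X, k, seed=seed, n_restarts=n_restarts, max_iter=max_iter, tol=tol
        )
        trajectories.append(trace)
        if fit is not None:
            fit.used_categories = tuple(categories)
            # rank components by the last-category parameter: ascending
            # terminal-depth mass maps to ascending ploidy in sorted P
            order = np.argsort(fit.component_probs[:, -1], kind="mergesort")
            ploidy_of_component = np.empty(k, dtype=int)
            ploidy_of_component[order] = P
            labels = ploidy_of_component[np.argmax(fit.responsibilities, axis=1)]
            table = pd.DataFrame({"barcode": used_barcodes, "ploidy": labels})
            return fit, table, excluded
    raise EmConvergenceError(trajectories)


class EMPloidyModel:
    """Ploidy inference by EM over a mixture of categorical distributions."""

    def __init__(self, feds):
        if isinstance(feds, pd.DataFrame):
            from .fedecs import frame_to_fedecs

            feds = frame_to_fedecs(feds)
        self.feds = dict(feds)

    def fit(
        self, ploidies=(2, 4, 8), seed: int = 0, n_restarts: int = 2, **kwargs
    ) -> "EMPloidyResults":
        fit, table, excluded = infer_ploidy_em(
            self.feds, ploidies, seed=seed, n_restarts=n_restarts, **kwargs
        )
        return EMPloidyResults(self, fit, table, excluded, tuple(sorted(set(ploidies))))


class EMPloidyResults:
    """Results of :meth:`EMPloidyModel.fit`."""

    def __init__(self, model, emfit: EmFit, calls: pd.DataFrame, excluded, ploidies):
        self.model = model
        self.emfit = emfit
        self.calls = calls
        self.excluded = list(excluded)
        self.ploidies = ploidies

    @property
    def ploidy(self) -> pd.Series:
        return self.calls.set_index("barcode")["ploidy"]

    @property
    def responsibilities(self) -> pd.DataFrame:
        cols = [f"p{p}" for p in self.ploidies]
        order = np.argsort(self.emfit.component_probs[:, -1], kind="mergesort")
        resp = self.emfit.responsibilities[:, order]
        return pd.DataFrame(resp, index=self.calls["barcode"], columns=cols)

    def summary(self) -> str:
        counts = self.calls["ploidy"].value_counts().sort_index()
        fit = self.emfit
        lines = [
            "EM categorical-mixture ploidy inference",
            f"  cells fitted:     {len(self.calls)} (excluded: {len(self.excluded)})",
            f"  candidate set P:  {{{', '.join(map(str, self.ploidies))}}}",
            f"  used categories:  f{', f'.join(map(str, fit.used_categories))}",
            f"  converged:        {fit.converged} "
            f"({len(fit.loglik_trace)} iterations, loglik {fit.loglik:.4f})",
            "  calls:            "
            + ", ".join(f"{p}n: {c}" for p, c in counts.items()),
        ]
        return "\n".join(lines)

    def to_tsv(self, path, responsibilities_path=None) -> None:
        self.calls.to_csv(path, sep="\t", index=False)
        if responsibilities_path is not None:
            self.responsibilities.to_csv(responsibilities_path, sep="\t")
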