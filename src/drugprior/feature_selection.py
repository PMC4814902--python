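"""Gene selection: CFS best-first search, F-stepping, top-k, significance.

The two-stage pipeline mirrors the standard practice for IC50 regression on
cell-line panels: correlation-based feature subset selection (CFS) first
shrinks the gene set by rewarding feature–target correlation while
penalizing inter-feature redundancy, then a wrapper backward pass
(F-stepping) drops every gene whose removal does not hurt a cross-validated
model. Two lighter selectors are also provided: the top-k genes by absolute
Pearson correlation with IC50, and genes whose mutant-vs-wild IC50 test is
significant across a minimum number of drugs.

Binary (0/1) features enter all correlations numerically, i.e. as
point-biserial correlations.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_data import DataError, DrugResponseTable, FeatureMatrix
from .response_stats import mutant_vs_wild_test


class SelectionWarning(UserWarning):
    pass


@dataclass
class FeatureSubset:
    """A selected gene subset plus its score and decision history.

    ``history`` records (action, gene, score) triples — e.g. ``("add", g,
    merit)`` during CFS search or ``("remove"/"keep", g, score)`` during
    F-stepping — and replays deterministically for the same data and order.
    """

    genes: list[str]
    merit: float
    history: list[tuple[str, str | None, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate genes in subset")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------

def _abs_corr_with_target(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| of each column with y; zero-variance columns get 0."""
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.abs(xc.T @ yc) / (sx * sy)
    bad = (sx == 0) | (sy == 0)
    if bad.any():
        warnings.warn(
            "zero-variance feature(s) or target; correlations treated as 0",
            SelectionWarning, stacklevel=3,
        )
    r[~np.isfinite(r)] = 0.0
    return r


def _abs_corr_matrix(X: np.ndarray) -> np.ndarray:
    """|Pearson r| between all column pairs; zero-variance rows/cols get 0."""
    sd = X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(np.corrcoef(X, rowvar=False))
    c = np.atleast_2d(c)
    c[~np.isfinite(c)] = 0.0
    c[sd == 0, :] = 0.0
    c[:, sd == 0] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def _merit_from_sums(k: int, sum_cf: float, sum_ff: float) -> float:
    """CFS merit from the sum of target- and pairwise correlations.

    merit = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff) with r̄ the mean absolute
    correlations over the subset; collapses to |r_cf| for a single feature.
    """
    if k == 0:
        return 0.0
    r_cf = sum_cf / k
    r_ff = 2.0 * sum_ff / (k * (k - 1)) if k > 1 else 0.0
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def cfs_merit(
    subset: Sequence[str], matrix: FeatureMatrix, target: pd.Series | np.ndarray
) -> float:
    """CFS merit of a gene subset against an IC50 target vector."""
    if not subset:
        raise DataError("subset must be non-empty")
    genes = list(subset)
    X = matrix.values[genes].to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    rcf = _abs_corr_with_target(X, y)
    rff = _abs_corr_matrix(X)
    k = len(genes)
    sum_ff = (rff.sum() - k) / 2.0  # upper triangle, diagonal excluded
    return float(_merit_from_sums(k, float(rcf.sum()), sum_ff))


def cfs_select(
    matrix: FeatureMatrix,
    target: pd.Series | np.ndarray,
    max_stale: int = 5,
    max_expansions: int = 10_000,
) -> FeatureSubset:
    """Best-first forward search maximizing the CFS merit.

    Starts from the empty set, repeatedly expands the best open subset by
    one gene, and stops after ``max_stale`` consecutive expansions that fail
    to improve the best merit found (the classic best-first stopping rule).
    Deterministic given the matrix column order.
    """
    genes = matrix.genes
    X = matrix.values.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise DataError("matrix and target have different cell-line counts")
    rcf = _abs_corr_with_target(X, y)
    rff = _abs_corr_matrix(X)
    if not np.any(rcf > 0):
        warnings.warn("all features uncorrelated or constant; empty subset",
                      SelectionWarning, stacklevel=2)
        return FeatureSubset(genes=[], merit=0.0, history=[])

    n = len(genes)
    history: list[tuple[str, str | None, float]] = []
    # node = (mask as frozenset of indices, sum_cf, sum_ff)
    start = (frozenset(), 0.0, 0.0)
    counter = 0
    open_heap: list[tuple[float, int, tuple]] = [(0.0, counter, start)]
    visited: set[frozenset] = {frozenset()}
    best_merit = 0.0
    best_set: frozenset = frozenset()
    stale = 0
    expansions = 0
    while open_heap and stale < max_stale and expansions < max_expansions:
        _, _, (node, sum_cf, sum_ff) = heapq.heappop(open_heap)
        expansions += 1
        improved = False
        for j in range(n):
            if j in node:
                continue
            child = node | {j}
            if child in visited:
                continue
            visited.add(child)
            c_cf = sum_cf + rcf[j]
            c_ff = sum_ff + sum(rff[j, i] for i in node)
            merit = _merit_from_sums(len(child), c_cf, c_ff)
            counter += 1
            heapq.heappush(open_heap, (-merit, counter, (child, c_cf, c_ff)))
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_set = child
                improved = True
                history.append(("best", genes[j], float(merit)))
        stale = 0 if improved else stale + 1
    selected = [genes[j] for j in sorted(best_set)]
    return FeatureSubset(genes=selected, merit=float(best_merit), history=history)


# ---------------------------------------------------------------------------
# F-stepping
# ---------------------------------------------------------------------------

def f_stepping(
    subset: FeatureSubset | Sequence[str],
    matrix: FeatureMatrix,
    target: pd.Series | np.ndarray,
    evaluator: Callable[[list[str]], float],
    iterate: bool = False,
    score_decimals: int | None = 3,
) -> FeatureSubset:
    """Leave-one-out backward elimination over a gene subset.

    Sweeps the genes in descending single-gene |r| with the target (a fixed,
    deterministic order) and removes each gene whose removal leaves the
    evaluator score equal or higher — ties remove. Scores are compared at
    ``score_decimals`` decimal places (the precision at which correlations
    are reported); two models whose cross-validated correlations agree to
    that precision count as equal, so a feature whose removal changes the
    score only below reportable precision is dropped. Pass ``None`` to
    compare at full floating precision. The compared (rounded) score never
    decreases during the sweep. One sweep by default; ``iterate=True``
    repeats sweeps until no gene is removed. The evaluator maps a gene list
    to a score where higher is better (typically a cross-validated Pearson
    correlation) and must be deterministic.
    """
    genes = list(subset.genes if isinstance(subset, FeatureSubset) else subset)
    if not genes:
        raise DataError("cannot F-step an empty subset")
    y = np.asarray(target, dtype=float)
    X = matrix.values[genes].to_numpy(dtype=float)
    order = _sweep_order(genes, X, y)

    def compare(x: float) -> float:
        return round(x, score_decimals) if score_decimals is not None else x

    history: list[tuple[str, str | None, float]] = []
    current = list(genes)
    score = float(evaluator(current))
    history.append(("start", None, score))
    while True:
        removed_any = False
        for gene in order:
            if gene not in current:
                continue
            if len(current) == 1:
                history.append(("keep", gene, score))
                continue
            trial = [g for g in current if g != gene]
            trial_score = float(evaluator(trial))
            if compare(trial_score) >= compare(score):
                current = trial
                score = trial_score
                removed_any = True
                history.append(("remove", gene, score))
            else:
                history.append(("keep", gene, score))
        if not iterate or not removed_any:
            break
    return FeatureSubset(genes=current, merit=score, history=history)


def _sweep_order(genes: list[str], X: np.ndarray, y: np.ndarray) -> list[str]:
    r = _abs_corr_with_target(X, y)
    return [g for _, g in sorted(zip(-r, genes), key=lambda t: (t[0], t[1]))]


# ---------------------------------------------------------------------------
# Lightweight selectors
# ---------------------------------------------------------------------------

def top_correlated(
    matrix: FeatureMatrix, target: pd.Series | np.ndarray, k: int = 50
) -> list[str]:
    """Top-k genes by |Pearson r| with the target, sign-blind.

    Ties break lexicographically; zero-variance genes rank last.
    """
    genes = matrix.genes
    if k > len(genes):
        raise DataError(f"k={k} exceeds the {len(genes)} available genes")
    X = matrix.values.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    r = _abs_corr_with_target(X, y)
    sd = X.std(axis=0)
    rank_r = np.where(sd == 0, -np.inf, r)
    ranked = sorted(zip(genes, rank_r), key=lambda t: (-t[1], t[0]))
    return [g for g, _ in ranked[:k]]


def significant_genes(
    response: DrugResponseTable,
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    min_drugs: int = 7,
    test: str = "mannwhitney",
) -> list[str]:
    """Genes whose mutant-vs-wild IC50 test reaches p < alpha in ≥ min_drugs.

    Untestable (gene, drug) pairs (empty group, undefined p-value) count as
    non-significant. Returns gene symbols sorted lexicographically.
    """
    hits = []
    for gene in matrix.genes:
        n_sig = 0
        for drug in response.drugs:
            try:
                rec = mutant_vs_wild_test(response, matrix, gene, drug, test=test)
            except DataError:
                continue
            if rec.testable and rec.p_value < alpha:
                n_sig += 1
        if n_sig >= min_drugs:
            hits.append(gene)
    return sorted(hits)
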