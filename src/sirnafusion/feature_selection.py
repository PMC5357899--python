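"""F-score feature ranking and binary-search subset selection.

The F-score of feature i over a two-class labeling is

    F(i) = [ (x_bar_pos - x_bar)^2 + (x_bar_neg - x_bar)^2 ]
           / [ s2_pos + s2_neg ]

where s2_pos and s2_neg are the unbiased (1/(n-1)) within-class scatters.
Larger F means better class separation. Features are ranked by descending
F-score and the subset size is chosen by a halving-then-bisection search over
top-k prefixes of the ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

ACTIVITY_THRESHOLD = 70.0


def binarize_labels(efficacies: Sequence[float]) -> np.ndarray:
    """Active/inactive labels from percent knockdown: active iff efficacy >= 70."""
    eff = np.asarray(efficacies, dtype=float)
    if eff.size == 0:
        raise ValueError("no efficacies given")
    if np.any((eff < 0) | (eff > 100)):
        raise ValueError("efficacies must lie in [0, 100]")
    return eff >= ACTIVITY_THRESHOLD


@dataclass(frozen=True)
class FScoreReport:
    """Per-feature F-scores and the descending ranking they induce."""

    names: tuple[str, ...]
    f_scores: np.ndarray
    #: feature indices sorted by descending F-score, ties broken by index
    ranking: np.ndarray

    def top(self, k: int) -> np.ndarray:
        return self.ranking[:k]


def f_score(
    matrix: np.ndarray, labels: Sequence[bool], names: Sequence[str] | None = None
) -> FScoreReport:
    """F-scores of every column of ``matrix`` under a binary labeling.

    A feature with zero within-class scatter but separated class means gets
    the +infinity sentinel (ranked first); an everywhere-constant feature
    gets 0. Ranking is stable: equal scores keep original column order, and
    +inf features sort before all finite ones, among themselves by index.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("matrix rows and labels must align")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    pos, neg = X[y], X[~y]
    mean_all = X.mean(axis=0)
    mean_pos, mean_neg = pos.mean(axis=0), neg.mean(axis=0)
    numerator = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2
    scatter_pos = ((pos - mean_pos) ** 2).sum(axis=0) / max(n_pos - 1, 1)
    scatter_neg = ((neg - mean_neg) ** 2).sum(axis=0) / max(n_neg - 1, 1)
    denominator = scatter_pos + scatter_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = numerator / denominator
    scores[(denominator == 0) & (numerator > 0)] = np.inf
    scores[(denominator == 0) & (numerator == 0)] = 0.0
    ranking = np.argsort(-scores, kind="stable")
    if names is None:
        names = tuple(f"f{i}" for i in range(X.shape[1]))
    return FScoreReport(names=tuple(names), f_scores=scores, ranking=ranking)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the subset-size search over an F-score ranking."""

    trace: tuple[tuple[int, int, float], ...]  # (iteration, subset_size, score)
    selected_size: int
    selected_indices: np.ndarray
    best_score: float


def binary_search_subset(
    ranking: Sequence[int],
    evaluate: Callable[[int], float],
    d: int | None = None,
) -> SelectionResult:
    """Choose the best top-k prefix of a feature ranking by halving + bisection.

    Starting from the full size d, the size is halved (integer division) while
    the evaluation score keeps improving. On the first drop — at ``lo`` with
    the last improving size ``hi`` — the search bisects: test
    mid = lo + (hi - lo) // 2, move the failing bound ``lo`` up to mid whenever
    the mid score does not exceed the best seen, and move ``hi`` down to mid
    when it does. The search stops once at most one untested size remains
    strictly inside (lo, hi). The returned size is the best-scoring one
    visited, with the full trace.
    """
    ranking = np.asarray(ranking, dtype=int)
    if d is None:
        d = len(ranking)
    if d < 2:
        raise ValueError("need at least 2 features to search over")

    trace: list[tuple[int, int, float]] = []
    iteration = 0

    def visit(k: int) -> float:
        nonlocal iteration
        iteration += 1
        score = float(evaluate(k))
        trace.append((iteration, k, score))
        return score

    best_k = d
    best_score = visit(d)
    k = d
    lo = None
    while k // 2 >= 1:
        k_next = k // 2
        score = visit(k_next)
        if score > best_score:
            best_score, best_k = score, k_next
            k = k_next
        else:
            lo, hi = k_next, k
            break
    else:
        lo = None

    if lo is not None:
        while hi - lo > 2:
            mid = lo + (hi - lo) // 2
            score = visit(mid)
            if score > best_score:
                best_score, best_k = score, mid
                hi = mid
            else:
                lo = mid

    return SelectionResult(
        trace=tuple(trace),
        selected_size=best_k,
        selected_indices=ranking[:best_k].copy(),
        best_score=best_score,
    )


def apply_selection(data: np.ndarray, selected_indices: Sequence[int]) -> np.ndarray:
    """Restrict a feature vector or matrix to the selected columns, in rank order."""
    idx = np.asarray(selected_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    data = np.asarray(data)
    width = data.shape[-1]
    if idx.min() < 0 or idx.max() >= width:
        raise IndexError(f"selection index out of range for width {width}")
    return data[..., idx]
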