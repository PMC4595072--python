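"""Conservation-priority ranking of plots by retained beta diversity.

A complementarity-style greedy rule: repeatedly remove the plot whose
removal leaves the remaining set with the highest effective beta
diversity. Plots removed early are the most redundant (lowest
conservation priority); the plots that survive longest contribute the
most compositional distinctiveness. Rankings from different survey
methods are compared by Spearman rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
from scipy import stats as _stats

from .community import CommunityMatrix
from .errors import DegenerateInputError, LabelMismatchError
from .hill import _hill_alpha, _hill_gamma


@dataclass
class PriorityRanking:
    """Greedy removal order and the retained-beta trajectory.

    ``removal_order[0]`` is the first plot removed, i.e. the *lowest*
    conservation priority; the last entries are the most irreplaceable
    plots. ``retained_beta[k]`` is the effective beta of the plots
    remaining after the k-th removal (recorded until 2 plots remain).
    ``rank_of`` maps plot id -> priority rank, 1 = highest priority
    (last removed).
    """

    removal_order: list[str]
    retained_beta: list[float]
    method: str
    q: float

    @property
    def rank_of(self) -> dict[str, int]:
        n = len(self.removal_order)
        return {p: n - i for i, p in enumerate(self.removal_order)}


def _beta_of(p: np.ndarray, idx: list[int], q: float) -> float:
    sub = p[idx]
    n = len(idx)
    w = np.full(n, 1.0 / n)
    return _hill_gamma(w @ sub, q) / _hill_alpha(sub, w, q)


def greedy_beta_ranking(cm: CommunityMatrix, q: float = 1.0) -> PriorityRanking:
    """Rank plots by iteratively removing the one that maximizes remaining beta.

    At every step each candidate removal is evaluated by the effective
    beta diversity (order ``q``, equal weights) of the plots that would
    remain, and the removal giving the largest remaining beta is taken.
    Ties break lexicographically by plot id. The loop stops when two
    plots remain (beta of a single plot is degenerate); the final pair
    is appended in lexicographic order so ``removal_order`` is a full
    permutation of the plots.
    """
    if not cm.is_plot_level():
        raise DegenerateInputError(
            "greedy ranking expects a plot-level matrix; use pool_to_plots first"
        )
    plots = cm.sample_ids
    if len(plots) < 3:
        raise DegenerateInputError("need at least 3 plots to rank")
    p = cm.relative_abundances()
    remaining = list(range(len(plots)))
    order: list[str] = []
    retained: list[float] = []
    while len(remaining) > 2:
        best_beta, best_i = -np.inf, None
        # iterate in lexicographic plot-id order so ties remove the smallest id
        for i in sorted(remaining, key=lambda k: plots[k]):
            cand = [k for k in remaining if k != i]
            beta = _beta_of(p, cand, q)
            if beta > best_beta + 1e-12:
                best_beta, best_i = beta, i
        order.append(plots[best_i])
        remaining.remove(best_i)
        retained.append(best_beta)
    order.extend(sorted(plots[k] for k in remaining))
    return PriorityRanking(
        removal_order=order, retained_beta=retained, method=cm.marker, q=float(q)
    )


def spearman_rank_correlation(
    rank1: PriorityRanking,
    rank2: PriorityRanking,
    exact_limit: int = 8,
) -> tuple[float, float]:
    """Spearman rho between two priority rankings, with exact small-n p.

    Rho is the tie-corrected rank correlation of the two priority
    rankings over the shared plot set. For ``n <= exact_limit`` the
    two-sided p-value is exact, by enumerating all n! permutations of
    one ranking; beyond that the t-approximation is used.
    """
    plots = sorted(rank1.rank_of)
    if sorted(rank2.rank_of) != plots:
        raise LabelMismatchError("rankings cover different plot sets")
    r1 = np.array([rank1.rank_of[p] for p in plots], dtype=float)
    r2 = np.array([rank2.rank_of[p] for p in plots], dtype=float)
    rho = float(_stats.spearmanr(r1, r2).statistic)
    n = len(plots)
    if n <= exact_limit:
        # exact null: all orderings of r2 equally likely
        perm_rhos = np.array([
            _stats.pearsonr(r1, r2[list(perm)]).statistic
            for perm in _permutations(range(n))
        ])
        p = float(np.mean(np.abs(perm_rhos) >= abs(rho) - 1e-12))
    else:
        p = float(_stats.spearmanr(r1, r2).pvalue)
    return rho, p
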