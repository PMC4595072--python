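"""Cross-method comparison of beta-diversity structure.

Each survey method (an eDNA marker or a traditional census) yields a
plot-by-plot turnover matrix; methods are compared by how correlated
those matrices are (Mantel tests), summarized in a method-by-method
correlation matrix, ordinated by second-stage MDS, and checked for
elevational distance decay by regressing pairwise beta on pairwise
elevation differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .community import CommunityMatrix
from .distance import DistanceMatrix
from .errors import DegenerateInputError, LabelMismatchError
from .hill import pairwise_turnover_matrix
from .ordination import EXHAUSTIVE_LIMIT, OrdinationResult, nmds


@dataclass(frozen=True)
class MantelResult:
    """Mantel statistic with one-tailed (greater) permutation p-value."""

    r: float
    p: float
    n_perm: int
    tail: str = "greater"
    exhaustive: bool = False


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear model summary (slope, intercept, r, R², F-test p)."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    p: float
    n: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise DegenerateInputError("zero-variance off-diagonal vector")
    return float((a * b).sum() / denom)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 4999,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> MantelResult:
    """Mantel test of matrix correlation by joint row/column permutation.

    ``r`` is the Pearson correlation of the n(n-1)/2 off-diagonal pairs;
    the one-tailed p-value counts permutations of ``d2``'s labels whose
    correlation reaches the observed one, with +1 smoothing so
    ``p >= 1/(n_perm+1)``. All ``n!`` relabelings are enumerated when
    ``n! <= 5040`` (or ``exhaustive=True``), making p exact.
    """
    if d1.labels != d2.labels:
        raise LabelMismatchError("distance matrices must share labels in order")
    n = d1.n
    if n < 4:
        raise DegenerateInputError("Mantel test needs at least 4 objects")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    r_obs = _pearson(v1, d2.values[iu])

    if exhaustive is None:
        exhaustive = math.factorial(n) <= EXHAUSTIVE_LIMIT
    if exhaustive:
        perms = np.array(list(_permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
    # permute rows/columns of d2 jointly and correlate with v1
    permuted = d2.values[perms[:, :, None], perms[:, None, :]][:, iu[0], iu[1]]
    a = v1 - v1.mean()
    b = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum() * (b**2).sum(axis=1))
    r_star = (b @ a) / denom
    if exhaustive:
        p = float(np.mean(r_star >= r_obs - 1e-12))
        return MantelResult(r=r_obs, p=p, n_perm=len(perms), exhaustive=True)
    hits = int(np.sum(r_star >= r_obs - 1e-12))
    p = (1.0 + hits) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm)


@dataclass
class MethodCorrelation:
    """Method-by-method Mantel correlation matrix (Table-5 style)."""

    methods: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n_perm: int

    def long_format(self) -> pd.DataFrame:
        rows = []
        for i, m1 in enumerate(self.methods):
            for m2 in self.methods[i + 1:]:
                rows.append((m1, m2, self.r.loc[m1, m2], self.p.loc[m1, m2]))
        return pd.DataFrame(rows, columns=["method1", "method2", "r", "p"])


def method_correlation_matrix(
    mats: Mapping[str, DistanceMatrix],
    n_perm: int = 4999,
    seed: int = 0,
) -> MethodCorrelation:
    """All pairwise Mantel correlations among methods on their common plots.

    Matrices are restricted to the plots shared by every method (at
    least 4 required) before testing, so each cell equals the pairwise
    Mantel test on the pre-restricted matrices.
    """
    methods = list(mats)
    if len(methods) < 2:
        raise DegenerateInputError("need at least 2 methods")
    common = [lab for lab in mats[methods[0]].labels
              if all(lab in mats[m].labels for m in methods)]
    if len(common) < 4:
        raise DegenerateInputError(
            f"only {len(common)} plots common to all methods; need >= 4"
        )
    restricted = {m: mats[m].restrict(common) for m in methods}
    r = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    p = pd.DataFrame(np.zeros((len(methods), len(methods))), index=methods, columns=methods)
    for i, m1 in enumerate(methods):
        for j in range(i + 1, len(methods)):
            m2 = methods[j]
            res = mantel_test(restricted[m1], restricted[m2], n_perm=n_perm, seed=seed)
            r.loc[m1, m2] = r.loc[m2, m1] = res.r
            p.loc[m1, m2] = p.loc[m2, m1] = res.p
    return MethodCorrelation(methods=methods, r=r, p=p, n_perm=n_perm)


def second_stage_mds(
    corr: pd.DataFrame | MethodCorrelation,
    dims: int = 2,
    seed: int = 0,
    n_starts: int = 20,
) -> OrdinationResult:
    """Ordinate methods by the similarity of their beta-diversity patterns.

    The Mantel correlation matrix is converted to dissimilarities
    ``1 - r`` and passed to NMDS, placing methods whose pairwise beta
    diversities covary most strongly closest together.
    """
    if isinstance(corr, MethodCorrelation):
        corr = corr.r
    delta = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(delta, 0.0)
    delta = np.clip(delta, 0.0, None)
    d = DistanceMatrix(
        labels=list(corr.index.astype(str)), values=delta, metric="one-minus-mantel-r"
    )
    return nmds(d, dims=dims, seed=seed, n_starts=n_starts)


def elevation_distance_matrix(elevations: Mapping[str, float]) -> DistanceMatrix:
    """|Δ elevation| (m) between plots, as a distance matrix."""
    labels = list(elevations)
    e = np.array([elevations[k] for k in labels], dtype=float)
    values = np.abs(e[:, None] - e[None, :])
    return DistanceMatrix(labels=labels, values=values, metric="euclidean-on-elevation")


def distance_decay_regression(
    beta: DistanceMatrix,
    elevations: Mapping[str, float],
) -> RegressionResult:
    """OLS of pairwise beta dissimilarity on pairwise elevation difference.

    A positive slope with small F-test p indicates distance decay:
    compositional similarity declining with elevational separation.
    """
    missing = [lab for lab in beta.labels if lab not in elevations]
    if missing:
        raise LabelMismatchError(f"no elevation for plots: {missing}")
    e = np.array([elevations[lab] for lab in beta.labels], dtype=float)
    iu = np.triu_indices(beta.n, k=1)
    x = np.abs(e[:, None] - e[None, :])[iu]
    y = beta.values[iu]
    if np.ptp(x) == 0:
        raise DegenerateInputError("all elevations equal; constant predictor")
    fit = _stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=len(x),
    )


@dataclass
class TurnoverSplit:
    """Turnover values split into within-plot and between-plot pairs."""

    within: np.ndarray
    between: np.ndarray

    @property
    def within_mean(self) -> float:
        return float(self.within.mean())

    @property
    def between_mean(self) -> float:
        return float(self.between.mean())


def within_between_turnover(cm: CommunityMatrix, q: float = 1.0) -> TurnoverSplit:
    """Partition all pairwise turnover values by shared-plot membership.

    Requires a subplot-level matrix with at least two plots having two
    or more subplots each, so both groups are populated. Lower
    within-plot than between-plot means indicate plot-scale community
    structure.
    """
    t = pairwise_turnover_matrix(cm, q=q)
    plots = [cm.plot_of[s] for s in cm.sample_ids]
    iu = np.triu_indices(cm.n_samples, k=1)
    same = np.array([plots[i] == plots[j] for i, j in zip(*iu)])
    vals = t.values[iu]
    if not same.any():
        raise DegenerateInputError("no within-plot pairs (matrix is plot-level?)")
    if same.all():
        raise DegenerateInputError("no between-plot pairs (single plot)")
    return TurnoverSplit(within=vals[same], between=vals[~same])
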