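"""Community distances, unconstrained ordination, and Procrustes tests.

NMDS minimizes stress-1 between a monotone transform of the input
dissimilarities and configuration distances; PCoA (metric scaling)
eigendecomposes the double-centered Gower matrix. PROTEST superimposes
two ordinations by translation/rotation/uniform scaling and permutes row
labels to test concordance; its statistic ``m12^2`` is the residual sum
of squares after optimal superimposition of unit-scaled configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _permutations
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS as _SkMDS

from .community import CommunityMatrix, to_presence_absence
from .distance import DistanceMatrix
from .errors import DegenerateInputError, EmptySampleError, LabelMismatchError
from .hill import pairwise_turnover_matrix

#: permutation tests enumerate all n! relabelings when n! <= this bound
EXHAUSTIVE_LIMIT = 5040


@dataclass
class OrdinationResult:
    """Low-dimensional sample configuration.

    ``coordinates`` is points x dims, column-centered and rotated to
    principal axes. NMDS fills ``stress`` (stress-1); PCoA fills
    ``eigenvalues`` (descending) and ``negative_inertia`` (summed
    magnitude of dropped negative eigenvalues).
    """

    labels: list[str]
    coordinates: np.ndarray
    stress: float | None = None
    eigenvalues: np.ndarray | None = None
    negative_inertia: float = 0.0
    seed: int | None = None
    converged: bool = True

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ProcrustesResult:
    """Procrustes superimposition statistic with permutation significance.

    ``m12_squared`` in [0, 1]; ``r = sqrt(1 - m12_squared)`` is the
    correlation-like concordance statistic tested by permutation.
    """

    m12_squared: float
    r: float
    p: float
    n_perm: int
    exhaustive: bool = False


def community_distance(
    cm: CommunityMatrix,
    metric: str = "jaccard",
    q: float = 1.0,
    quantitative_jaccard: bool = False,
) -> DistanceMatrix:
    """Pairwise sample dissimilarity under a named community metric.

    ``jaccard``
        1 - |A∩B| / |A∪B| on presence/absence (the quantitative Ružička
        form via ``quantitative_jaccard=True``).
    ``horn-morisita``
        1 - 2 Σ x_i y_i / [(Σx_i²/X² + Σy_i²/Y²)·X·Y], abundance-based
        overlap with row totals X, Y.
    ``turnover``
        normalized pairwise effective beta of order ``q`` (delegated to
        the Hill partition).
    """
    if cm.n_samples < 2:
        raise DegenerateInputError("need at least 2 samples")
    if metric == "turnover":
        return pairwise_turnover_matrix(cm, q=q)
    x = cm.counts
    if metric == "jaccard":
        if quantitative_jaccard:
            # Ružička: 1 - sum(min)/sum(max)
            n = x.shape[0]
            out = np.zeros((n, n))
            for j in range(n):
                mins = np.minimum(x[j], x).sum(axis=1)
                maxs = np.maximum(x[j], x).sum(axis=1)
                out[j] = 1.0 - mins / maxs
            np.fill_diagonal(out, 0.0)
            out = (out + out.T) / 2
        else:
            b = (x > 0)
            out = squareform(pdist(b, metric="jaccard"))
        return DistanceMatrix(labels=cm.sample_ids, values=out, metric="jaccard")
    if metric == "horn-morisita":
        totals = x.sum(axis=1)
        rel2 = (x**2).sum(axis=1) / totals**2  # Σ x_i² / X² per sample
        cross = x @ x.T
        denom = (rel2[:, None] + rel2[None, :]) * totals[:, None] * totals[None, :]
        sim = 2.0 * cross / denom
        out = 1.0 - sim
        np.fill_diagonal(out, 0.0)
        out = np.clip((out + out.T) / 2, 0.0, 1.0)
        np.fill_diagonal(out, 0.0)
        return DistanceMatrix(labels=cm.sample_ids, values=out, metric="horn-morisita")
    raise ValueError(f"unknown metric {metric!r}")


def _principal_axis_rotation(coords: np.ndarray) -> np.ndarray:
    """Center and rotate to principal axes with a fixed sign convention."""
    coords = coords - coords.mean(axis=0)
    u, s, vt = np.linalg.svd(coords, full_matrices=False)
    rotated = coords @ vt.T
    # sign convention: largest-magnitude loading on each axis is positive
    for k in range(rotated.shape[1]):
        i = np.argmax(np.abs(rotated[:, k]))
        if rotated[i, k] < 0:
            rotated[:, k] = -rotated[:, k]
    return rotated


def nmds(
    d: DistanceMatrix,
    dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Minimizes stress-1 by iterative majorization with monotone
    regression over ``n_starts`` random starts; the best configuration
    is centered and rotated to principal axes so repeated runs with the
    same seed are identical.
    """
    if d.n < dims + 1:
        raise DegenerateInputError(f"NMDS in {dims}-D needs at least {dims + 1} points")

    def _fit(n_init: int, init: str):
        model = _SkMDS(
            n_components=dims,
            metric_mds=False,
            n_init=n_init,
            init=init,
            max_iter=max_iter,
            eps=1e-9,
            metric="precomputed",
            random_state=int(seed),
            normalized_stress=True,
        )
        coords = model.fit_transform(d.values)
        return coords, float(model.stress_), int(model.n_iter_)

    # a metric (classical-scaling) start guards against poor random optima
    candidates = [_fit(1, "classical_mds"), _fit(n_starts, "random")]
    coords, stress, n_iter = min(candidates, key=lambda c: c[1])
    coords = _principal_axis_rotation(coords)
    return OrdinationResult(
        labels=list(d.labels),
        coordinates=coords,
        stress=stress,
        seed=int(seed),
        converged=bool(n_iter < max_iter),
    )


def pcoa(d: DistanceMatrix, eig_tol: float = 1e-9) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Eigendecomposes the Gower-centered matrix ``-0.5 J D² J``; axes are
    scaled by the square root of their eigenvalue. Axes with negative
    eigenvalues (non-Euclidean input) are dropped and their summed
    magnitude reported as ``negative_inertia``.
    """
    n = d.n
    if n < 2:
        raise DegenerateInputError("PCoA needs at least 2 points")
    d2 = d.values**2
    if not d2.any():
        raise DegenerateInputError("all-zero distance matrix")
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    pos = eigval > eig_tol * scale
    neg = eigval < -eig_tol * scale
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords = coords - coords.mean(axis=0)
    return OrdinationResult(
        labels=list(d.labels),
        coordinates=coords,
        eigenvalues=eigval[pos],
        negative_inertia=float(-eigval[neg].sum()),
    )


def _unit_configuration(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    ss = np.sqrt((c**2).sum())
    if ss == 0:
        raise DegenerateInputError("all points coincide; Procrustes undefined")
    return c / ss


def procrustes_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Concordance r = Σ singular values of X'Y for unit-scaled X, Y."""
    s = np.linalg.svd(x.T @ y, compute_uv=False)
    return float(s.sum())


def procrustes_test(
    x: OrdinationResult,
    y: OrdinationResult,
    n_perm: int = 4999,
    seed: int = 0,
) -> ProcrustesResult:
    """PROTEST: Procrustes superimposition with a permutation test.

    Both configurations are centered and scaled to unit sum of squares;
    the optimal rotation comes from the singular decomposition of the
    cross-product, giving ``m12² = 1 - (Σ singular values)²``.
    Significance permutes the row labels of ``y``; when ``n! <=``
    :data:`EXHAUSTIVE_LIMIT` all relabelings are enumerated instead.
    """
    if x.labels != y.labels:
        raise LabelMismatchError("ordinations must share point labels in order")
    dims = min(x.coordinates.shape[1], y.coordinates.shape[1])
    xc = _unit_configuration(x.coordinates[:, :dims])
    yc = _unit_configuration(y.coordinates[:, :dims])
    n = xc.shape[0]
    r_obs = min(1.0, procrustes_statistic(xc, yc))
    m12sq = max(0.0, 1.0 - r_obs**2)

    if math.factorial(n) <= EXHAUSTIVE_LIMIT:
        perms = np.array(list(_permutations(range(n))))
        stacked = yc[perms]  # n! x n x d
        cross = np.einsum("ij,pik->pjk", xc, stacked)
        svals = np.linalg.svd(cross, compute_uv=False).sum(axis=1)
        p = float(np.mean(svals >= r_obs - 1e-12))
        return ProcrustesResult(
            m12_squared=m12sq, r=r_obs, p=p, n_perm=len(perms), exhaustive=True
        )

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    stacked = yc[perms]
    cross = np.einsum("ij,pik->pjk", xc, stacked)
    svals = np.linalg.svd(cross, compute_uv=False).sum(axis=1)
    hits = int(np.sum(svals >= r_obs - 1e-12))
    p = (1.0 + hits) / (n_perm + 1.0)
    return ProcrustesResult(m12_squared=m12sq, r=r_obs, p=p, n_perm=n_perm)
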