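"""Jost/Hill diversity partitioning and read-subsampling rarefaction.

The Hill number of order ``q`` is the effective number of species: ``q=0``
counts species equally (richness), ``q=1`` weights by abundance
(exponential Shannon entropy), ``q=2`` emphasizes dominants (inverse
Simpson). Gamma diversity of the pooled assemblage factors
multiplicatively into mean within-sample alpha and among-sample beta,

    D_gamma = D_alpha * D_beta,      1 <= D_beta <= N,

where ``N`` is the number of samples. The normalized pairwise beta,
``(D_beta - 1)/(N - 1)`` with ``N = 2``, is the turnover in [0, 1] used
throughout the cross-method comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .distance import DistanceMatrix
from .errors import DegenerateInputError, EmptySampleError

_WEIGHT_TOL = 1e-9
_PARTITION_TOL = 1e-10


@dataclass(frozen=True)
class DiversityPartition:
    """Multiplicative alpha/beta/gamma partition at one order ``q``.

    All three components are effective numbers of species;
    ``d_gamma == d_alpha * d_beta`` holds to 1e-10 relative by
    construction.
    """

    q: float
    weights: np.ndarray
    d_alpha: float
    d_beta: float
    d_gamma: float

    @property
    def n_samples(self) -> int:
        return len(self.weights)

    def turnover(self) -> float:
        """Normalized beta, (D_beta - 1)/(N - 1), in [0, 1]."""
        if self.n_samples < 2:
            raise DegenerateInputError("turnover needs at least 2 samples")
        return (self.d_beta - 1.0) / (self.n_samples - 1.0)


def _validate_weights(weights: Sequence[float] | None, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {w.shape}")
    if (w <= 0).any():
        raise ValueError("sample weights must be positive")
    if abs(w.sum() - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"weights sum to {w.sum():.12g}, not 1")
    return w


def _hill_gamma(pbar: np.ndarray, q: float) -> float:
    p = pbar[pbar > 0]
    if q == 1.0:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def _hill_alpha(p: np.ndarray, w: np.ndarray, q: float) -> float:
    # p: samples x species relative abundances; terms with p == 0 drop out
    if q == 1.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        return float(np.exp(-np.sum(w[:, None] * plogp)))
    wp = w[:, None] * p
    num = np.sum(np.where(wp > 0, wp**q, 0.0))
    den = np.sum(w**q)
    return float((num / den) ** (1.0 / (1.0 - q)))


def partition_diversity(
    cm: CommunityMatrix,
    q: float,
    weights: Sequence[float] | None = None,
) -> DiversityPartition:
    """Partition community diversity of order ``q`` into alpha, beta, gamma.

    With row compositions ``p_ij`` and sample weights ``w_j`` (default
    equal, ``1/N``), gamma is the Hill number of the weighted pooled
    assemblage ``pbar_i = sum_j w_j p_ij``, alpha the weighted mean
    within-sample Hill number, and ``beta = gamma / alpha``.

    Parameters
    ----------
    cm:
        Community matrix; every row must have a positive total.
    q:
        Non-negative diversity order. ``q=0`` gives richness-based
        components; ``q=1`` the Shannon limit (computed exactly).
    weights:
        Per-sample weights summing to 1. Equal weights make beta
        independent of alpha at every order.
    """
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    p = cm.relative_abundances()
    n = p.shape[0]
    w = _validate_weights(weights, n)
    pbar = w @ p
    d_gamma = _hill_gamma(pbar, float(q))
    d_alpha = _hill_alpha(p, w, float(q))
    d_beta = d_gamma / d_alpha
    return DiversityPartition(
        q=float(q), weights=w, d_alpha=d_alpha, d_beta=d_beta, d_gamma=d_gamma
    )


def pairwise_turnover_matrix(cm: CommunityMatrix, q: float = 1.0) -> DistanceMatrix:
    """Pairwise turnover (normalized two-sample effective beta) matrix.

    Entry (j, k) is ``D_beta(j, k) - 1`` from the equal-weight two-sample
    partition of rows j and k: 0 for identical compositions, 1 for
    disjoint ones.
    """
    if cm.n_samples < 2:
        raise DegenerateInputError("need at least 2 samples for turnover")
    p = cm.relative_abundances()
    n = p.shape[0]
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            sub = p[[j, k]]
            pbar = sub.mean(axis=0)
            d_gamma = _hill_gamma(pbar, float(q))
            d_alpha = _hill_alpha(sub, np.array([0.5, 0.5]), float(q))
            t = d_gamma / d_alpha - 1.0
            out[j, k] = out[k, j] = min(1.0, max(0.0, t))
    return DistanceMatrix(
        labels=cm.sample_ids, values=out, metric=f"turnover-q{q:g}"
    )


@dataclass
class RarefactionCurve:
    """Read-rarefied diversity components across depths and replicates.

    ``table`` is tidy: columns (depth, replicate, component, value) with
    component in {alpha, beta, gamma}. ``summary()`` aggregates to
    per-depth mean and standard deviation.
    """

    q: float
    depths: list[int]
    replicates: int
    seed: int
    table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby(["depth", "component"])["value"]
        out = g.agg(["mean", "std"]).reset_index()
        return out


def rarefy_diversity(
    cm: CommunityMatrix,
    depths: Sequence[int],
    replicates: int,
    q: float = 1.0,
    seed: int = 0,
    per_sample: bool = False,
) -> RarefactionCurve:
    """Subsample reads without replacement and re-partition diversity.

    Each replicate draws the requested number of reads from the pooled
    read multiset (every read tagged with its sample and OTU), rebuilds
    the matrix, and recomputes the equal-weight alpha/beta/gamma
    partition at order ``q``. Samples emptied by a shallow draw are
    dropped for that replicate (N shrinks accordingly). With
    ``per_sample=True`` the depth is instead drawn from every sample
    separately (classical per-sample rarefaction).

    Reproducible from ``seed``: replicate ``r`` uses an independent
    child stream spawned from the seed, so it can be regenerated in
    isolation.
    """
    counts = cm.counts
    if not np.all(counts == np.floor(counts)):
        raise ValueError("rarefaction requires integer read counts")
    counts = counts.astype(np.int64)
    depths = [int(d) for d in depths]
    if sorted(set(depths)) != depths:
        raise ValueError("depths must be strictly increasing")
    total = int(counts.sum())
    row_totals = counts.sum(axis=1)
    for d in depths:
        if d < 1:
            raise ValueError("depths must be >= 1")
        if per_sample and d > row_totals.min():
            raise ValueError(
                f"depth {d} exceeds the shallowest sample ({row_totals.min()} reads)"
            )
        if not per_sample and d > total:
            raise ValueError(f"depth {d} exceeds total reads ({total})")

    flat = counts.ravel()
    n, s = counts.shape
    root = np.random.SeedSequence(seed)
    children = root.spawn(replicates)
    rows = []
    for r in range(replicates):
        rng = np.random.default_rng(children[r])
        for d in depths:
            if per_sample:
                sub = np.vstack(
                    [rng.multivariate_hypergeometric(counts[j], d) for j in range(n)]
                )
            else:
                drawn = rng.multivariate_hypergeometric(flat, d)
                sub = drawn.reshape(n, s)
            keep = sub.sum(axis=1) > 0
            sub = sub[keep]
            part = _partition_array(sub.astype(float), float(q))
            for comp, val in zip(("alpha", "beta", "gamma"), part):
                rows.append((d, r, comp, val))
    table = pd.DataFrame(rows, columns=["depth", "replicate", "component", "value"])
    return RarefactionCurve(
        q=float(q), depths=depths, replicates=replicates, seed=seed, table=table
    )


def _partition_array(counts: np.ndarray, q: float) -> tuple[float, float, float]:
    """Equal-weight (alpha, beta, gamma) for a raw count array."""
    p = counts / counts.sum(axis=1, keepdims=True)
    n = p.shape[0]
    w = np.full(n, 1.0 / n)
    d_gamma = _hill_gamma(w @ p, q)
    d_alpha = _hill_alpha(p, w, q)
    return d_alpha, d_gamma / d_alpha, d_gamma
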