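"""Independent oracles used by the test suite.

Everything here evaluates the target quantities directly from their
closed forms (sympy high-precision arithmetic, plain-Python loops,
exhaustive enumeration), sharing no code with the package
implementations they check.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from mpmath import mp


def hill_partition_oracle(counts, q, digits: int = 50):
    """(alpha, beta, gamma) by direct 50-digit evaluation of the closed forms.

    Counts must be integers; every intermediate value is an ``mpmath``
    multiprecision float built from exact integer ratios.
    """
    with mp.workdps(digits):
        rows = [[mp.mpf(int(c)) for c in row] for row in counts]
        n = len(rows)
        w = mp.mpf(1) / n
        p = []
        for row in rows:
            tot = mp.fsum(row)
            p.append([c / tot for c in row])
        s = len(rows[0])
        pbar = [mp.fsum(w * p[j][i] for j in range(n)) for i in range(s)]
        qm = mp.mpf(q)
        if qm == 1:
            gamma = mp.exp(-mp.fsum(x * mp.log(x) for x in pbar if x > 0))
            alpha = mp.exp(-mp.fsum(w * p[j][i] * mp.log(p[j][i])
                                    for j in range(n) for i in range(s)
                                    if p[j][i] > 0))
        else:
            g_sum = mp.fsum(x**qm for x in pbar if x > 0)
            gamma = g_sum ** (1 / (1 - qm))
            num = mp.fsum((w * p[j][i]) ** qm
                          for j in range(n) for i in range(s) if p[j][i] > 0)
            den = n * w**qm
            alpha = (num / den) ** (1 / (1 - qm))
        return float(alpha), float(gamma / alpha), float(gamma)


def mantel_r_oracle(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson r of off-diagonal pairs via plain loops."""
    n = m1.shape[0]
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            xs.append(m1[i, j])
            ys.append(m2[i, j])
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def mantel_exhaustive_p(m1: np.ndarray, m2: np.ndarray) -> float:
    """Exact one-tailed Mantel p by enumerating every relabeling of m2."""
    n = m1.shape[0]
    r_obs = mantel_r_oracle(m1, m2)
    count = total = 0
    for perm in permutations(range(n)):
        mp = m2[np.ix_(perm, perm)]
        if mantel_r_oracle(m1, mp) >= r_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def procrustes_r_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Best-fit concordance r after centering/unit-scaling, via SVD."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xc /= math.sqrt((xc**2).sum())
    yc /= math.sqrt((yc**2).sum())
    return float(np.linalg.svd(xc.T @ yc, compute_uv=False).sum())


def procrustes_exhaustive_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact PROTEST p by enumerating row permutations of y."""
    n = x.shape[0]
    r_obs = procrustes_r_oracle(x, y)
    hits = total = 0
    for perm in permutations(range(n)):
        if procrustes_r_oracle(x, y[list(perm)]) >= r_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def beta_q_oracle(counts: np.ndarray, q: float) -> float:
    """Equal-weight effective beta via the sympy partition oracle."""
    a, b, g = hill_partition_oracle(counts, q)
    return b


def greedy_ranking_oracle(counts: np.ndarray, plot_ids, q: float = 1.0):
    """Greedy removal order by exhaustive search over single removals.

    Uses the sympy-based beta oracle, so both the search and the
    diversity arithmetic are independent of the package.
    """
    remaining = list(range(len(plot_ids)))
    order = []
    while len(remaining) > 2:
        best = None
        for i in sorted(remaining, key=lambda k: plot_ids[k]):
            cand = [k for k in remaining if k != i]
            beta = beta_q_oracle(counts[cand], q)
            if best is None or beta > best[0] + 1e-12:
                best = (beta, i)
        order.append(plot_ids[best[1]])
        remaining.remove(best[1])
    order.extend(sorted(plot_ids[k] for k in remaining))
    return order


def vif_oracle(x: np.ndarray) -> np.ndarray:
    """VIF of each column by explicit OLS of that column on the rest."""
    n, m = x.shape
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    out = np.empty(m)
    for k in range(m):
        yk = x[:, k]
        others = np.column_stack([np.ones(n), np.delete(x, k, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ coef
        ss_res = float((resid**2).sum())
        ss_tot = float(((yk - yk.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def spearman_exhaustive_p(r1: np.ndarray, r2: np.ndarray) -> float:
    """Exact two-sided Spearman p over all permutations of one ranking."""
    def rho(a, b):
        am, bm = a - a.mean(), b - b.mean()
        return float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))

    obs = abs(rho(r1, r2))
    hits = total = 0
    for perm in permutations(range(len(r2))):
        if abs(rho(r1, r2[list(perm)])) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total
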