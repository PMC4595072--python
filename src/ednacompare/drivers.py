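"""Environmental covariate preparation and distance-based RDA.

Covariates (elevation, soil temperature, slope, aspect, soil chemistry)
are prepared by log-transforming skewed chemistry variables and
decomposing circular aspect into sin/cos components (how east- and
north-facing a plot is). Collinearity is screened by stepwise exclusion
of the highest variance inflation factor (VIF) until all remaining
VIF < 10. Community structure is then related to the surviving
predictors by distance-based redundancy analysis: principal coordinates
of the community distance matrix are regressed on the predictors, and
the explained ("constrained") fraction of inertia is tested by
permuting sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor as _sm_vif

from .community import CommunityMatrix
from .distance import DistanceMatrix
from .errors import DegenerateInputError, LabelMismatchError
from .ordination import community_distance, pcoa

#: chemistry variables log-transformed by default (right-skewed concentrations)
DEFAULT_LOG_VARS = ("Olsen.P", "EC", "NO3.N", "NH4.N")


@dataclass
class EnvTable:
    """Plot-level environmental variables.

    ``data`` is indexed by plot id; ``transforms`` records what was
    applied to each column (``"log"``, ``"sin-of-aspect"``, ...).
    Values stay on their natural scales — modeling entry points
    standardize internally, so VIFs and inertia fractions are
    scale-free while ``sin.aspect``/``cos.aspect`` remain in [-1, 1].
    """

    data: pd.DataFrame
    transforms: dict[str, str] = field(default_factory=dict)

    @property
    def plots(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def model_matrix(self, variables: Sequence[str]) -> np.ndarray:
        """Z-scored predictor matrix (plots x variables)."""
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise LabelMismatchError(f"unknown environment variables: {missing}")
        x = self.data[list(variables)].to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [v for v, s in zip(variables, sd) if s == 0]
            raise DegenerateInputError(f"constant variables: {bad}")
        return (x - x.mean(axis=0)) / sd

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.data.copy()
        out.index.name = "plot_id"
        out.to_csv(path)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnvTable":
        df = pd.read_csv(path, index_col=0, comment="#")
        df.index = df.index.astype(str)
        return cls(data=df)


def prepare_environment(
    raw: EnvTable,
    log_vars: Sequence[str] = DEFAULT_LOG_VARS,
    aspect_col: str = "aspect",
) -> EnvTable:
    """Derive sin/cos aspect components and log-transform skewed variables.

    ``sin.aspect = sin(aspect°)`` measures how east-facing a plot is and
    ``cos.aspect = cos(aspect°)`` how north-facing; both are added
    alongside the raw aspect. Variables in ``log_vars`` are replaced by
    their natural logarithm (all values must be strictly positive).
    """
    df = raw.data.copy()
    transforms = dict(raw.transforms)
    if aspect_col in df.columns:
        rad = np.deg2rad(df[aspect_col].to_numpy(dtype=float))
        df["sin.aspect"] = np.sin(rad)
        df["cos.aspect"] = np.cos(rad)
        transforms["sin.aspect"] = "sin-of-aspect"
        transforms["cos.aspect"] = "cos-of-aspect"
    for v in log_vars:
        if v not in df.columns:
            continue
        col = df[v].to_numpy(dtype=float)
        if (col <= 0).any():
            plot = df.index[(col <= 0).argmax()]
            raise ValueError(
                f"cannot log-transform {v!r}: non-positive value at plot {plot!r}"
            )
        df[v] = np.log(col)
        transforms[v] = "log"
    return EnvTable(data=df, transforms=transforms)


@dataclass
class VIFReport:
    """Round-by-round VIFs, the exclusion order, and survivors."""

    rounds: list[dict[str, float]]
    excluded: list[str]
    surviving: list[str]
    threshold: float


def _vif_all(x: np.ndarray) -> np.ndarray:
    """VIF of every column of a standardized design matrix."""
    n, m = x.shape
    design = np.column_stack([np.ones(n), x])
    out = np.empty(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in range(m):
            try:
                v = _sm_vif(design, k + 1)
            except Exception:
                v = np.inf
            out[k] = np.inf if (not np.isfinite(v) or v < 0 or v > 1e12) else v
    return out


def stepwise_vif_exclusion(env: EnvTable, threshold: float = 10.0,
                           variables: Sequence[str] | None = None) -> VIFReport:
    """Iteratively drop the highest-VIF variable until all VIF < threshold.

    Each round regresses every remaining variable on all the others;
    ``VIF_k = 1/(1 - R_k²)``, with exact singularities treated as
    infinite. The variable with the largest VIF >= threshold is
    excluded and VIFs are recomputed, repeating until every surviving
    variable has VIF below the threshold.
    """
    current = list(variables) if variables is not None else env.variables
    if len(current) < 2:
        raise DegenerateInputError("need at least 2 variables for VIF screening")
    if len(env.plots) < 3:
        raise DegenerateInputError("need at least 3 plots for VIF screening")
    rounds: list[dict[str, float]] = []
    excluded: list[str] = []
    while True:
        x = env.model_matrix(current)
        vifs = _vif_all(x)
        rounds.append(dict(zip(current, (float(v) for v in vifs))))
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold or len(current) == 1:
            break
        excluded.append(current.pop(worst))
    return VIFReport(rounds=rounds, excluded=excluded, surviving=current,
                     threshold=threshold)


@dataclass
class DbRDAResult:
    """Distance-based RDA decomposition and permutation significance.

    ``proportion_explained = constrained_inertia / total_inertia`` of
    the positive-eigenvalue PCoA space; ``marginal`` holds the
    proportion explained by each variable fitted alone.
    """

    variables: list[str]
    total_inertia: float
    constrained_inertia: float
    proportion_explained: float
    pseudo_f: float
    p: float
    n_perm: int
    marginal: dict[str, dict[str, float]] = field(default_factory=dict)
    metric: str = "jaccard"
    #: summed magnitude of dropped negative PCoA eigenvalues. The
    #: proportion here divides by total *positive* inertia; conventions
    #: that net this imaginary part out of the denominator yield
    #: slightly larger proportions on non-Euclidean distances.
    negative_inertia: float = 0.0

    @property
    def unconstrained_inertia(self) -> float:
        return self.total_inertia - self.constrained_inertia


def _env_matrix(env: EnvTable, labels: Sequence[str], variables: Sequence[str]) -> np.ndarray:
    """Z-scored predictors over exactly the rows ``labels``, in order."""
    missing = [v for v in variables if v not in env.data.columns]
    if missing:
        raise LabelMismatchError(f"unknown environment variables: {missing}")
    x = env.data.loc[list(labels), list(variables)].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise DegenerateInputError(f"constant variables: {bad}")
    return (x - x.mean(axis=0)) / sd


def _dbrda_core(
    y: np.ndarray, x: np.ndarray, total: float, n_perm: int, rng: np.random.Generator
) -> tuple[float, float, float]:
    """(constrained inertia, pseudo-F, permutation p) for site scores y."""
    n, m = x.shape
    x = x - x.mean(axis=0)
    if m >= n - 1:
        raise DegenerateInputError(f"saturated model: {m} variables for {n} sites")
    q, rmat = np.linalg.qr(x)
    if np.abs(np.diag(rmat)).min() < 1e-10 * np.abs(np.diag(rmat)).max():
        raise DegenerateInputError("collinear variable set (singular projection)")
    hat = q @ q.T
    fitted = hat @ y
    constrained = float((fitted**2).sum())
    residual = total - constrained
    f_obs = (constrained / m) / (residual / (n - m - 1))
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = y[perms]  # n_perm x n x k
    cp = np.einsum("ij,pjk->pik", hat, yp)
    cons_star = (cp**2).sum(axis=(1, 2))
    f_star = (cons_star / m) / ((total - cons_star) / (n - m - 1))
    hits = int(np.sum(f_star >= f_obs - 1e-12))
    p = (1.0 + hits) / (n_perm + 1.0)
    return constrained, float(f_obs), float(p)


def dbrda(
    cm: CommunityMatrix,
    env: EnvTable,
    variables: Sequence[str] | None = None,
    metric: str = "jaccard",
    n_perm: int = 999,
    seed: int = 0,
    marginal: bool = True,
) -> DbRDAResult:
    """Distance-based redundancy analysis of a community matrix.

    The community distance matrix (Jaccard by default) is embedded by
    PCoA (positive axes, sqrt-eigenvalue scaling); site scores are then
    projected onto the standardized predictor space by least squares.
    Constrained inertia is the sum of squared fitted values; its
    proportion of total positive inertia is the variance explained.
    Significance permutes site rows; ``marginal=True`` additionally
    fits each variable alone.
    """
    if variables is None:
        variables = env.variables
    variables = list(variables)
    labels = cm.sample_ids
    missing = [lab for lab in labels if lab not in env.data.index]
    if missing:
        raise LabelMismatchError(f"plots without environment data: {missing}")
    if cm.n_samples < 3:
        raise DegenerateInputError("db-RDA needs at least 3 plots")
    d = community_distance(cm, metric=metric)
    ord_res = pcoa(d)
    y = ord_res.coordinates  # n x k, columns centered, sum of squares = eigenvalues
    total = float(ord_res.eigenvalues.sum())
    x_full = _env_matrix(env, labels, variables)
    rng = np.random.default_rng(seed)
    constrained, f_obs, p = _dbrda_core(y, x_full, total, n_perm, rng)
    marg: dict[str, dict[str, float]] = {}
    if marginal:
        for v in variables:
            xv = _env_matrix(env, labels, [v])
            c_v, f_v, p_v = _dbrda_core(y, xv, total, n_perm, np.random.default_rng(seed))
            marg[v] = {
                "proportion": c_v / total,
                "pseudo_f": f_v,
                "p": p_v,
            }
    return DbRDAResult(
        variables=variables,
        total_inertia=total,
        constrained_inertia=constrained,
        proportion_explained=constrained / total,
        pseudo_f=f_obs,
        p=p,
        n_perm=n_perm,
        marginal=marg,
        metric=metric,
        negative_inertia=ord_res.negative_inertia,
    )


def stepwise_model_selection(
    cm: CommunityMatrix,
    env: EnvTable,
    candidates: Sequence[str],
    mode: str = "forward",
    alpha: float = 0.05,
    metric: str = "jaccard",
    n_perm: int = 999,
    seed: int = 0,
) -> DbRDAResult:
    """Forward or backward permutation-test model building for db-RDA.

    Forward: starting empty, repeatedly add the candidate with the
    smallest permutation p-value while that p < ``alpha``. Backward:
    starting from the full candidate set, repeatedly drop the variable
    with the largest p >= ``alpha``. The returned model carries
    per-variable marginal statistics for the selected set.
    """
    candidates = list(candidates)
    if mode not in ("forward", "backward"):
        raise ValueError("mode must be 'forward' or 'backward'")

    def conditional_p(selected: list[str], extra: str) -> float:
        """p-value of `extra` added to `selected` (by added-F permutation)."""
        d = community_distance(cm, metric=metric)
        ord_res = pcoa(d)
        y = ord_res.coordinates
        total = float(ord_res.eigenvalues.sum())
        rng = np.random.default_rng(seed)
        labels = cm.sample_ids
        if not selected:
            _, _, p = _dbrda_core(y, _env_matrix(env, labels, [extra]), total, n_perm, rng)
            return p
        x0 = _env_matrix(env, labels, selected)
        q0, _ = np.linalg.qr(x0)
        resid = y - q0 @ (q0.T @ y)
        x1 = _env_matrix(env, labels, [extra])
        x1 = x1 - q0 @ (q0.T @ x1)
        if float((x1**2).sum()) < 1e-12:
            return 1.0
        total_resid = float((resid**2).sum())
        _, _, p = _dbrda_core(resid, x1, total_resid, n_perm, rng)
        return p

    if mode == "forward":
        selected: list[str] = []
        pool = list(candidates)
        while pool:
            pvals = {v: conditional_p(selected, v) for v in pool}
            best = min(pvals, key=lambda v: (pvals[v], v))
            if pvals[best] >= alpha:
                break
            selected.append(best)
            pool.remove(best)
        if not selected:
            d = community_distance(cm, metric=metric)
            ord_res = pcoa(d)
            total = float(ord_res.eigenvalues.sum())
            return DbRDAResult(
                variables=[], total_inertia=total, constrained_inertia=0.0,
                proportion_explained=0.0, pseudo_f=np.nan, p=1.0,
                n_perm=n_perm, metric=metric,
            )
        return dbrda(cm, env, selected, metric=metric, n_perm=n_perm, seed=seed)

    # backward
    selected = list(candidates)
    while len(selected) > 1:
        pvals = {}
        for v in selected:
            rest = [u for u in selected if u != v]
            pvals[v] = conditional_p(rest, v)
        worst = max(pvals, key=lambda v: (pvals[v], v))
        if pvals[worst] < alpha:
            break
        selected.remove(worst)
    # final single-variable check
    if len(selected) == 1 and conditional_p([], selected[0]) >= alpha:
        selected = []
    if not selected:
        d = community_distance(cm, metric=metric)
        ord_res = pcoa(d)
        total = float(ord_res.eigenvalues.sum())
        return DbRDAResult(
            variables=[], total_inertia=total, constrained_inertia=0.0,
            proportion_explained=0.0, pseudo_f=np.nan, p=1.0,
            n_perm=n_perm, metric=metric,
        )
    return dbrda(cm, env, selected, metric=metric, n_perm=n_perm, seed=seed)
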