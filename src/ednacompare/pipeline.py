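"""Orchestration: run every comparison stage from one configuration.

``run_full_comparison`` takes per-method community matrices plus an
environment table and emits the full report bundle: diversity summaries,
rarefaction, within/between turnover, distance decay vs elevation, the
method correlation matrix with its second-stage MDS, per-method NMDS,
Procrustes concordance, greedy plot prioritization with Spearman rank
agreement, and the VIF/db-RDA driver models. One master seed governs the
run; each stage derives its own stream by stable hashing of the stage
name, so adding a stage never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .community import (
    CommunityMatrix,
    pool_to_plots,
    read_community_matrix,
    remove_singleton_otus,
)
from .comparison import (
    distance_decay_regression,
    elevation_distance_matrix,
    mantel_test,
    method_correlation_matrix,
    second_stage_mds,
    within_between_turnover,
)
from .drivers import EnvTable, dbrda, stepwise_model_selection, stepwise_vif_exclusion
from .errors import DegenerateInputError, EdnaCompareError
from .hill import pairwise_turnover_matrix, partition_diversity, rarefy_diversity
from .ordination import OrdinationResult, nmds, procrustes_test
from .prioritization import greedy_beta_ranking, spearman_rank_correlation


def stage_seed(master: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2**31 from the master seed."""
    return (int(master) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Inputs and knobs for a full comparison run.

    ``matrices`` maps method name -> community matrix CSV path;
    ``label_pattern`` parses subplot labels (None = plot-level CSVs).
    """

    matrices: dict[str, str]
    env_path: str | None = None
    label_pattern: str | None = None
    q_orders: tuple[float, ...] = (0.0, 1.0)
    n_perm: int = 999
    seed: int = 0
    out_dir: str = "ednacompare_out"
    remove_singletons: bool = False
    rarefaction_depths: tuple[int, ...] = (100, 500, 1000, 5000)
    rarefaction_replicates: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("q_orders", "rarefaction_depths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(report: dict, name: str, fn):
    try:
        report[name] = fn()
    except EdnaCompareError as exc:
        raise EdnaCompareError(f"stage {name!r} failed: {exc}") from exc


def run_full_comparison(
    config: RunConfig,
    matrices: Mapping[str, CommunityMatrix] | None = None,
    env: EnvTable | None = None,
) -> dict[str, Any]:
    """Run every analysis stage and write the report bundle to disk.

    ``matrices``/``env`` may be passed in memory (e.g. straight from the
    synthetic generator); otherwise they are read from the paths in
    ``config``. Returns the report dictionary; numeric outputs are also
    written as CSV/JSON under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrices is None:
        matrices = {
            name: read_community_matrix(path, label_pattern=config.label_pattern,
                                        marker=name)
            for name, path in config.matrices.items()
        }
    matrices = dict(matrices)
    if env is None and config.env_path:
        env = EnvTable.from_csv(config.env_path)
    if config.remove_singletons:
        matrices = {m: remove_singleton_otus(cm) for m, cm in matrices.items()}
    plot_level = {m: pool_to_plots(cm) for m, cm in matrices.items()}
    report: dict[str, Any] = {"config": {
        "methods": list(matrices), "q_orders": list(config.q_orders),
        "n_perm": config.n_perm, "seed": config.seed,
        "remove_singletons": config.remove_singletons,
    }}

    # (a) per-method diversity summary
    def _summary():
        rows = []
        for m, cm in plot_level.items():
            entry = {
                "method": m,
                "n_plots": cm.n_samples,
                "n_otus": len(cm.otu_ids),
                "total_count": float(cm.counts.sum()),
            }
            for q in config.q_orders:
                part = partition_diversity(cm, q=q)
                entry[f"alpha_q{q:g}"] = part.d_alpha
                entry[f"beta_q{q:g}"] = part.d_beta
                entry[f"gamma_q{q:g}"] = part.d_gamma
            rows.append(entry)
        df = pd.DataFrame(rows).set_index("method")
        df.to_csv(out / "diversity_summary.csv")
        return df

    _stage(report, "diversity_summary", _summary)

    # (b) rarefaction curves (integer-count methods only)
    def _rarefaction():
        frames = []
        for m, cm in matrices.items():
            counts = cm.counts
            if not np.all(counts == np.floor(counts)):
                continue
            total = int(counts.sum())
            depths = [d for d in config.rarefaction_depths if d <= total]
            if not depths:
                continue
            curve = rarefy_diversity(
                cm, depths, replicates=config.rarefaction_replicates,
                q=1.0, seed=stage_seed(config.seed, f"rarefy:{m}"),
            )
            t = curve.table.copy()
            t.insert(0, "method", m)
            frames.append(t)
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        df.to_csv(out / "rarefaction.csv", index=False)
        return df

    _stage(report, "rarefaction", _rarefaction)

    # (c) within/between-plot turnover
    def _turnover():
        rows = []
        for m, cm in matrices.items():
            if cm.is_plot_level():
                continue
            try:
                split = within_between_turnover(cm, q=1.0)
            except DegenerateInputError:
                continue
            rows.append({"method": m, "within_mean": split.within_mean,
                         "between_mean": split.between_mean,
                         "n_within": len(split.within),
                         "n_between": len(split.between)})
        df = pd.DataFrame(rows)
        df.to_csv(out / "turnover_within_between.csv", index=False)
        return df

    _stage(report, "within_between_turnover", _turnover)

    turnover_mats = {
        m: pairwise_turnover_matrix(cm, q=1.0) for m, cm in plot_level.items()
    }

    # (d) distance decay vs elevation
    def _decay():
        if env is None or "elevation" not in env.data.columns:
            return pd.DataFrame()
        elevations = {p: float(env.data.loc[p, "elevation"]) for p in env.plots}
        elev_d = elevation_distance_matrix(elevations)
        rows = []
        for m, t in turnover_mats.items():
            common = [lab for lab in t.labels if lab in elevations]
            tt = t.restrict(common)
            mr = mantel_test(tt, elev_d.restrict(common),
                             n_perm=config.n_perm,
                             seed=stage_seed(config.seed, f"mantel-elev:{m}"))
            reg = distance_decay_regression(tt, elevations)
            rows.append({"method": m, "mantel_r": mr.r, "mantel_p": mr.p,
                         "slope": reg.slope, "r_squared": reg.r_squared,
                         "lm_p": reg.p})
        df = pd.DataFrame(rows).set_index("method")
        df.to_csv(out / "distance_decay.csv")
        return df

    _stage(report, "distance_decay", _decay)

    # (e) method correlation matrix + second-stage MDS
    def _method_corr():
        if len(turnover_mats) < 2:
            return None
        corr = method_correlation_matrix(
            turnover_mats, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "method-correlation"),
        )
        corr.r.to_csv(out / "method_correlation_r.csv")
        corr.p.to_csv(out / "method_correlation_p.csv")
        corr.long_format().to_csv(out / "method_correlation_long.csv", index=False)
        return corr

    _stage(report, "method_correlation", _method_corr)

    def _stage2():
        corr = report.get("method_correlation")
        if corr is None or len(corr.methods) < 4:
            return None
        ordn = second_stage_mds(corr, seed=stage_seed(config.seed, "second-stage-mds"))
        df = pd.DataFrame(ordn.coordinates,
                          index=ordn.labels,
                          columns=[f"axis{i+1}" for i in range(ordn.coordinates.shape[1])])
        df.to_csv(out / "second_stage_mds.csv")
        (out / "second_stage_mds.json").write_text(
            json.dumps({"stress": ordn.stress, "converged": ordn.converged}))
        return ordn

    _stage(report, "second_stage_mds", _stage2)

    # (f) NMDS per method
    def _nmds_all():
        results = {}
        for m, t in turnover_mats.items():
            ordn = nmds(t, seed=stage_seed(config.seed, f"nmds:{m}"))
            df = pd.DataFrame(ordn.coordinates, index=ordn.labels,
                              columns=["axis1", "axis2"])
            df.to_csv(out / f"nmds_{m}.csv")
            results[m] = ordn
        return results

    _stage(report, "nmds", _nmds_all)

    # (g) Procrustes concordance between method ordinations
    def _procrustes():
        ords = report.get("nmds") or {}
        methods = list(ords)
        rows = []
        for i, m1 in enumerate(methods):
            for m2 in methods[i + 1:]:
                common = [lab for lab in ords[m1].labels if lab in ords[m2].labels]
                if len(common) < 3:
                    continue
                idx1 = [ords[m1].labels.index(c) for c in common]
                idx2 = [ords[m2].labels.index(c) for c in common]
                res = procrustes_test(
                    OrdinationResult(common, ords[m1].coordinates[idx1]),
                    OrdinationResult(common, ords[m2].coordinates[idx2]),
                    n_perm=config.n_perm,
                    seed=stage_seed(config.seed, f"protest:{m1}:{m2}"),
                )
                rows.append({"method1": m1, "method2": m2,
                             "m12_squared": res.m12_squared, "r": res.r, "p": res.p})
        df = pd.DataFrame(rows)
        df.to_csv(out / "procrustes.csv", index=False)
        return df

    _stage(report, "procrustes", _procrustes)

    # (h) greedy prioritization + Spearman rank agreement
    def _ranking():
        rankings = {}
        for m, cm in plot_level.items():
            if cm.n_samples < 3:
                continue
            rk = greedy_beta_ranking(cm, q=1.0)
            df = pd.DataFrame({
                "rank": [rk.rank_of[p] for p in rk.removal_order],
                "plot_id": rk.removal_order,
                "retained_beta": rk.retained_beta + [np.nan, np.nan],
            })
            # rank 1 = highest priority (last removed)
            df.sort_values("rank").to_csv(out / f"ranking_{m}.csv", index=False)
            rankings[m] = rk
        methods = list(rankings)
        rho = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
        pmat = pd.DataFrame(np.zeros((len(methods),) * 2), index=methods, columns=methods)
        for i, m1 in enumerate(methods):
            for m2 in methods[i + 1:]:
                r, p = spearman_rank_correlation(rankings[m1], rankings[m2])
                rho.loc[m1, m2] = rho.loc[m2, m1] = r
                pmat.loc[m1, m2] = pmat.loc[m2, m1] = p
        rho.to_csv(out / "spearman_rho.csv")
        pmat.to_csv(out / "spearman_p.csv")
        return {"rankings": rankings, "rho": rho, "p": pmat}

    _stage(report, "prioritization", _ranking)

    # (i) VIF screening and db-RDA driver models
    def _drivers():
        if env is None:
            return None
        model_vars = [v for v in env.variables
                      if v not in ("latitude", "longitude", "aspect")]
        vif = stepwise_vif_exclusion(env, threshold=10.0, variables=model_vars)
        (out / "vif_report.json").write_text(json.dumps({
            "excluded": vif.excluded, "surviving": vif.surviving,
            "rounds": vif.rounds, "threshold": vif.threshold,
        }, indent=2, default=float))
        results = {}
        for m, cm in plot_level.items():
            usable = [p for p in cm.sample_ids if p in env.plots]
            if len(usable) < 4:
                continue
            cmr = cm.subset_samples(usable)
            sd = stage_seed(config.seed, f"dbrda:{m}")
            full = dbrda(cmr, env, vif.surviving, n_perm=config.n_perm, seed=sd)
            fwd = stepwise_model_selection(
                cmr, env, vif.surviving, mode="forward",
                n_perm=config.n_perm, seed=sd)
            bwd = stepwise_model_selection(
                cmr, env, vif.surviving, mode="backward",
                n_perm=config.n_perm, seed=sd)
            results[m] = {
                "marginal": full.marginal,
                "full": {"variables": full.variables,
                         "proportion_explained": full.proportion_explained,
                         "pseudo_f": full.pseudo_f, "p": full.p},
                "forward": {"variables": fwd.variables,
                            "proportion_explained": fwd.proportion_explained,
                            "p": fwd.p},
                "backward": {"variables": bwd.variables,
                             "proportion_explained": bwd.proportion_explained,
                             "p": bwd.p},
            }
        (out / "dbrda.json").write_text(json.dumps(results, indent=2, default=float))
        return {"vif": vif, "models": results}

    _stage(report, "drivers", _drivers)

    (out / "run_log.json").write_text(json.dumps(report["config"], indent=2))
    return report
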