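"""Environment preparation, VIF exclusion, and distance-based RDA."""

import numpy as np
import pandas as pd
import pytest

from ednacompare import (
    EnvTable,
    dbrda,
    pcoa,
    prepare_environment,
    stepwise_model_selection,
    stepwise_vif_exclusion,
)
from ednacompare.errors import DegenerateInputError
from ednacompare.ordination import community_distance
from ednacompare.distance import DistanceMatrix

from conftest import make_cm, random_cm
from oracles import vif_oracle


def env_from(df):
    return EnvTable(data=df)


class TestPrepareEnvironment:
    @pytest.mark.parametrize("deg,sin_c,cos_c", [
        (90.0, 1.0, 0.0),       # east-facing
        (0.0, 0.0, 1.0),        # north-facing
        (225.0, -np.sqrt(2) / 2, -np.sqrt(2) / 2),
    ])
    def test_aspect_decomposition(self, deg, sin_c, cos_c):
        df = pd.DataFrame({"aspect": [deg, 10.0]}, index=["P1", "P2"])
        env = prepare_environment(env_from(df), log_vars=())
        assert env.data.loc["P1", "sin.aspect"] == pytest.approx(sin_c, abs=1e-12)
        assert env.data.loc["P1", "cos.aspect"] == pytest.approx(cos_c, abs=1e-12)

    def test_sin_cos_unit_circle_identity(self, rng):
        df = pd.DataFrame({"aspect": rng.uniform(0, 360, 10)},
                          index=[f"P{i}" for i in range(10)])
        env = prepare_environment(env_from(df), log_vars=())
        s2c2 = env.data["sin.aspect"]**2 + env.data["cos.aspect"]**2
        np.testing.assert_allclose(s2c2, 1.0, atol=1e-12)

    def test_log_transform_applied_and_recorded(self):
        df = pd.DataFrame({"EC": [10.0, 100.0], "pH": [5.0, 6.0]},
                          index=["P1", "P2"])
        env = prepare_environment(env_from(df), log_vars=("EC",))
        assert env.data.loc["P2", "EC"] == pytest.approx(np.log(100.0))
        assert env.data.loc["P1", "pH"] == 5.0
        assert env.transforms["EC"] == "log"

    def test_log_of_nonpositive_names_variable_and_plot(self):
        df = pd.DataFrame({"EC": [10.0, 0.0]}, index=["P1", "P2"])
        with pytest.raises(ValueError, match="EC.*P2"):
            prepare_environment(env_from(df), log_vars=("EC",))


class TestVIF:
    def test_orthogonal_variables_all_vif_one(self):
        # exactly orthogonal columns after standardization
        x = np.array([[1, 1, -1, -1], [1, -1, 1, -1], [1, -1, -1, 1]]).T.astype(float)
        df = pd.DataFrame(x, columns=["a", "b", "c"],
                          index=[f"P{i}" for i in range(4)])
        rep = stepwise_vif_exclusion(env_from(df), threshold=10.0)
        assert rep.excluded == []
        assert all(v == pytest.approx(1.0) for v in rep.rounds[0].values())

    def test_duplicated_variable_has_infinite_vif_and_goes_first(self, rng):
        base = rng.normal(size=12)
        df = pd.DataFrame({
            "x": base, "x_copy": base, "y": rng.normal(size=12),
        }, index=[f"P{i}" for i in range(12)])
        rep = stepwise_vif_exclusion(env_from(df), threshold=10.0)
        assert rep.excluded[0] in ("x", "x_copy")
        assert np.isinf(rep.rounds[0]["x"])

    def test_planted_collinear_blocks_match_regression_oracle(self, rng):
        # 15 variables over 40 plots with two planted collinear blocks
        n = 40
        latent1 = rng.normal(size=n)
        latent2 = rng.normal(size=n)
        cols = {}
        for i in range(4):  # block 1: tied to latent1
            cols[f"b1_{i}"] = latent1 + rng.normal(0, 0.05, n)
        for i in range(3):  # block 2: tied to latent2
            cols[f"b2_{i}"] = latent2 + rng.normal(0, 0.05, n)
        for i in range(8):  # independent noise variables
            cols[f"z{i}"] = rng.normal(size=n)
        df = pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])
        env = env_from(df)
        rep = stepwise_vif_exclusion(env, threshold=10.0)
        # replay the loop with the independent per-round oracle
        current = list(df.columns)
        for k, excluded in enumerate(rep.excluded):
            vifs = vif_oracle(df[current].to_numpy())
            assert np.allclose(
                [rep.rounds[k][v] for v in current], vifs, rtol=1e-8), k
            assert current[int(np.argmax(vifs))] == excluded
            current.remove(excluded)
        final = vif_oracle(df[rep.surviving].to_numpy())
        assert (final < 10.0).all()

    def test_terminates_with_all_vif_below_threshold(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 6)),
                          columns=list("abcdef"),
                          index=[f"P{i}" for i in range(15)])
        rep = stepwise_vif_exclusion(env_from(df), threshold=10.0)
        assert len(rep.rounds) <= 6
        assert max(rep.rounds[-1].values()) < 10.0


class TestDbRDA:
    def _toy(self, rng, n=8, s=12):
        return random_cm(rng, n_samples=n, n_otus=s)

    def test_axis1_scores_as_constraint_explain_lambda1_fraction(self, rng):
        cm = self._toy(rng)
        d = community_distance(cm, metric="jaccard")
        ord_res = pcoa(d)
        df = pd.DataFrame({"ax1": ord_res.coordinates[:, 0]},
                          index=cm.sample_ids)
        res = dbrda(cm, env_from(df), ["ax1"], n_perm=99, seed=0)
        expected = ord_res.eigenvalues[0] / ord_res.eigenvalues.sum()
        assert res.proportion_explained == pytest.approx(expected, rel=1e-9)

    def test_inertia_decomposition_conserved(self, rng):
        cm = self._toy(rng)
        df = pd.DataFrame(rng.normal(size=(8, 2)), columns=["u", "v"],
                          index=cm.sample_ids)
        res = dbrda(cm, env_from(df), ["u", "v"], n_perm=99, seed=0)
        assert 0.0 <= res.proportion_explained <= 1.0
        assert res.constrained_inertia + res.unconstrained_inertia == \
            pytest.approx(res.total_inertia, rel=1e-9)

    def test_orthogonal_constraint_explains_nothing(self, rng):
        cm = self._toy(rng)
        d = community_distance(cm, metric="jaccard")
        y = pcoa(d).coordinates
        # build a predictor orthogonal to every site-score axis
        q, _ = np.linalg.qr(np.column_stack([np.ones(8), y]))
        v = rng.normal(size=8)
        v = v - q @ (q.T @ v)
        df = pd.DataFrame({"orth": v}, index=cm.sample_ids)
        res = dbrda(cm, env_from(df), ["orth"], n_perm=199, seed=0)
        assert res.proportion_explained < 1e-9
        assert res.p > 0.5

    def test_planted_elevation_driver_beats_noise(self, rng):
        # composition driven by elevation; elevation should dominate a
        # random covariate in marginal inertia for most seeds
        wins = 0
        for trial in range(20):
            trng = np.random.default_rng(1000 + trial)
            elev = np.linspace(0, 1, 10)
            optima = trng.uniform(0, 1, 15)
            lam = np.exp(-((elev[:, None] - optima[None, :])**2) / 0.02)
            counts = trng.poisson(60 * lam / lam.sum(1, keepdims=True)) + \
                (lam > lam.mean())
            counts[counts.sum(axis=1) == 0, 0] = 1
            cm = make_cm(counts)
            df = pd.DataFrame({"elevation": elev,
                               "noise": trng.normal(size=10)},
                              index=cm.sample_ids)
            res = dbrda(cm, env_from(df), ["elevation", "noise"],
                        n_perm=49, seed=trial)
            if res.marginal["elevation"]["proportion"] > \
               res.marginal["noise"]["proportion"]:
                wins += 1
        assert wins >= 18

    def test_saturated_model_rejected(self, rng):
        cm = self._toy(rng, n=4)
        df = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"),
                          index=cm.sample_ids)
        with pytest.raises(DegenerateInputError):
            dbrda(cm, env_from(df), ["a", "b", "c"], n_perm=9, seed=0)


class TestStepwiseSelection:
    def _driven(self, seed, n=10, s=20):
        rng = np.random.default_rng(seed)
        grad = np.linspace(0, 1, n)
        optima = rng.uniform(0, 1, s)
        lam = np.exp(-((grad[:, None] - optima[None, :])**2) / 0.02)
        counts = rng.poisson(80 * lam / lam.sum(1, keepdims=True)) + (lam > 0.5)
        counts[counts.sum(axis=1) == 0, 0] = 1
        cm = make_cm(counts)
        df = pd.DataFrame({
            "driver": grad,
            "n1": rng.normal(size=n),
            "n2": rng.normal(size=n),
        }, index=cm.sample_ids)
        return cm, env_from(df)

    def test_forward_selects_planted_driver(self):
        hits = 0
        for seed in range(10):
            cm, env = self._driven(seed)
            res = stepwise_model_selection(cm, env, ["driver", "n1", "n2"],
                                           mode="forward", n_perm=199, seed=seed)
            if "driver" in res.variables:
                hits += 1
        assert hits >= 9

    def test_forward_selects_nothing_without_signal(self):
        empty = 0
        for seed in range(10):
            rng = np.random.default_rng(50 + seed)
            cm = random_cm(rng, n_samples=10, n_otus=15)
            df = pd.DataFrame(rng.normal(size=(10, 3)),
                              columns=["a", "b", "c"], index=cm.sample_ids)
            res = stepwise_model_selection(cm, env_from(df), ["a", "b", "c"],
                                           mode="forward", n_perm=199, seed=seed)
            if not res.variables:
                empty += 1
        assert empty >= 8

    def test_backward_keeps_planted_driver(self):
        cm, env = self._driven(3)
        res = stepwise_model_selection(cm, env, ["driver", "n1", "n2"],
                                       mode="backward", n_perm=199, seed=3)
        assert "driver" in res.variables
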