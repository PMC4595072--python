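"""Mantel tests, method correlation matrix, second-stage MDS, distance
decay, and within/between-plot turnover."""

import numpy as np
import pytest

from ednacompare import (
    DistanceMatrix,
    mantel_test,
    method_correlation_matrix,
    second_stage_mds,
    distance_decay_regression,
    within_between_turnover,
    table1_fixture,
    pairwise_turnover_matrix,
)
from ednacompare.comparison import elevation_distance_matrix
from ednacompare.errors import DegenerateInputError, LabelMismatchError

from conftest import make_cm
from oracles import mantel_exhaustive_p, mantel_r_oracle


def random_distance(rng, n, labels=None):
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return DistanceMatrix(labels=labels or [f"P{i}" for i in range(n)], values=d)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        d = random_distance(rng, 6)
        res = mantel_test(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_r_matches_plain_loop_oracle(self, rng):
        d1, d2 = random_distance(rng, 8), random_distance(rng, 8)
        res = mantel_test(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(mantel_r_oracle(d1.values, d2.values),
                                      rel=1e-12)

    def test_exhaustive_p_at_n4_equals_enumeration(self, rng):
        for _ in range(5):
            d1, d2 = random_distance(rng, 4), random_distance(rng, 4)
            res = mantel_test(d1, d2)
            assert res.exhaustive
            assert res.p == pytest.approx(
                mantel_exhaustive_p(d1.values, d2.values), abs=1e-12)

    def test_symmetric_in_arguments_exhaustively(self, rng):
        d1, d2 = random_distance(rng, 5), random_distance(rng, 5)
        a = mantel_test(d1, d2)
        b = mantel_test(d2, d1)
        assert a.r == pytest.approx(b.r, rel=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)  # exhaustive: exact equality

    def test_p_invariant_under_joint_relabeling(self, rng):
        d1, d2 = random_distance(rng, 5), random_distance(rng, 5)
        perm = rng.permutation(5)
        labels = [d1.labels[i] for i in perm]
        d1p = d1.restrict(labels)
        d2p = d2.restrict(labels)
        assert mantel_test(d1, d2).p == pytest.approx(
            mantel_test(d1p, d2p).p, abs=1e-12)

    def test_p_has_permutation_floor(self, rng):
        d = random_distance(rng, 10)
        res = mantel_test(d, d, n_perm=99, seed=0)
        assert res.p >= 1.0 / 100.0

    def test_zero_variance_matrix_rejected(self):
        ones = 1.0 - np.eye(4)
        d1 = DistanceMatrix(labels=list("abcd"), values=ones)
        with pytest.raises(DegenerateInputError):
            mantel_test(d1, d1)

    def test_label_mismatch_rejected(self, rng):
        d1 = random_distance(rng, 5)
        d2 = random_distance(rng, 5, labels=list("vwxyz"))
        with pytest.raises(LabelMismatchError):
            mantel_test(d1, d2)


class TestMethodCorrelation:
    def test_identical_methods_have_r_one(self, rng):
        d = random_distance(rng, 6)
        other = random_distance(rng, 6)
        corr = method_correlation_matrix({"A": d, "A2": d, "B": other},
                                         n_perm=99, seed=0)
        assert corr.r.loc["A", "A2"] == pytest.approx(1.0)
        assert corr.r.loc["A", "A"] == 1.0

    def test_matrix_equals_pairwise_calls(self, rng):
        mats = {m: random_distance(rng, 6) for m in ("x", "y", "z")}
        corr = method_correlation_matrix(mats, n_perm=199, seed=3)
        for m1 in mats:
            for m2 in mats:
                if m1 >= m2:
                    continue
                ref = mantel_test(mats[m1], mats[m2], n_perm=199, seed=3)
                assert corr.r.loc[m1, m2] == pytest.approx(ref.r, rel=1e-12)
                assert corr.p.loc[m1, m2] == pytest.approx(ref.p, abs=1e-12)

    def test_restriction_to_common_plots_matches_prerestricted(self, rng):
        full = random_distance(rng, 8)
        sub_labels = full.labels[:6]
        partial = random_distance(rng, 6, labels=sub_labels)
        corr = method_correlation_matrix({"full": full, "part": partial},
                                         n_perm=99, seed=1)
        ref = mantel_test(full.restrict(sub_labels), partial, n_perm=99, seed=1)
        assert corr.r.loc["full", "part"] == pytest.approx(ref.r, rel=1e-12)

    def test_shared_gradient_gives_positive_correlations(self, rng):
        # methods driven by a common 1-D gradient plus small noise
        grad = np.linspace(0, 1, 8)
        mats = {}
        for m in range(5):
            vals = np.abs(grad[:, None] - grad[None, :])
            vals = vals + rng.uniform(0, 0.05, vals.shape)
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0)
            mats[f"m{m}"] = DistanceMatrix(labels=[f"P{i}" for i in range(8)],
                                           values=vals)
        corr = method_correlation_matrix(mats, n_perm=99, seed=0)
        off = corr.r.to_numpy()[~np.eye(5, dtype=bool)]
        assert (off > 0).all()

    def test_fewer_than_four_common_plots_rejected(self, rng):
        d1 = random_distance(rng, 5)
        d2 = random_distance(rng, 5, labels=d1.labels[:3] + ["Q1", "Q2"])
        with pytest.raises(DegenerateInputError):
            method_correlation_matrix({"a": d1, "b": d2})


class TestSecondStageMDS:
    def test_identical_methods_are_the_closest_pair(self, rng):
        # a zero dissimilarity cannot force exact coincidence in
        # non-metric scaling (isotonic regression leaves the smallest
        # rank's disparity free), but the pair must end up closest
        import pandas as pd
        methods = ["a", "b", "c", "d", "e"]
        r = pd.DataFrame(rng.uniform(0.2, 0.6, (5, 5)), index=methods,
                         columns=methods)
        r = (r + r.T) / 2
        np.fill_diagonal(r.values, 1.0)
        r.loc["a", "b"] = r.loc["b", "a"] = 1.0  # a and b perfectly correlated
        ordn = second_stage_mds(r, seed=0)
        c = ordn.coordinates
        gaps = {(m1, m2): np.linalg.norm(c[i] - c[j])
                for i, m1 in enumerate(methods)
                for j, m2 in enumerate(methods) if i < j}
        assert min(gaps, key=gaps.get) == ("a", "b")

    def test_equal_pairwise_r_gives_equilateral_configuration(self):
        import pandas as pd
        methods = ["a", "b", "c"]
        r = pd.DataFrame(0.5, index=methods, columns=methods)
        np.fill_diagonal(r.values, 1.0)
        ordn = second_stage_mds(r, seed=0)
        d01 = np.linalg.norm(ordn.coordinates[0] - ordn.coordinates[1])
        d02 = np.linalg.norm(ordn.coordinates[0] - ordn.coordinates[2])
        d12 = np.linalg.norm(ordn.coordinates[1] - ordn.coordinates[2])
        assert d01 == pytest.approx(d02, abs=1e-6)
        assert d01 == pytest.approx(d12, abs=1e-6)

    def test_table5_like_matrix_has_low_stress(self, rng):
        import pandas as pd
        # 9 methods whose correlations decay with distance along a latent axis
        pos = np.sort(rng.uniform(0, 1, 9))
        r = np.clip(1.0 - 1.2 * np.abs(pos[:, None] - pos[None, :]), -0.2, 1.0)
        r += rng.normal(0, 0.03, r.shape)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        methods = [f"m{i}" for i in range(9)]
        ordn = second_stage_mds(pd.DataFrame(r, index=methods, columns=methods),
                                seed=1)
        assert ordn.stress < 0.2


class TestDistanceDecay:
    def test_perfectly_linear_beta_gives_r2_one(self):
        elev = {"P1": 100.0, "P2": 200.0, "P3": 400.0, "P4": 700.0}
        e = np.array(list(elev.values()))
        vals = 0.001 * np.abs(e[:, None] - e[None, :])
        beta = DistanceMatrix(labels=list(elev), values=vals)
        res = distance_decay_regression(beta, elev)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.001)

    def test_r_squared_equals_r_squared_identity(self, rng):
        elev = {f"P{i}": float(v) for i, v in enumerate(rng.uniform(0, 600, 7))}
        beta = random_distance(rng, 7, labels=list(elev))
        res = distance_decay_regression(beta, elev)
        assert res.r_squared == pytest.approx(res.r**2, rel=1e-12)

    def test_transect_extreme_plot_separation_is_590m(self):
        env = table1_fixture()
        elevations = {p: float(env.data.loc[p, "elevation"]) for p in env.plots}
        d = elevation_distance_matrix(elevations)
        i, j = d.labels.index("Plot1"), d.labels.index("Plot10")
        assert d.values[i, j] == pytest.approx(590.0)

    def test_constant_elevation_rejected(self, rng):
        beta = random_distance(rng, 5)
        with pytest.raises(DegenerateInputError):
            distance_decay_regression(beta, {lab: 100.0 for lab in beta.labels})


class TestWithinBetweenTurnover:
    def _structured_cm(self):
        # identical subplots within plots, distinct across plots
        rows = [[10, 0, 0], [10, 0, 0], [0, 10, 0], [0, 10, 0],
                [0, 0, 10], [0, 0, 10]]
        ids = ["P1-A", "P1-B", "P2-A", "P2-B", "P3-A", "P3-B"]
        return make_cm(rows, sample_ids=ids,
                       plot_of={i: i.split("-")[0] for i in ids},
                       subplot_of={i: i.split("-")[1] for i in ids})

    def test_duplicate_subplots_give_zero_within_positive_between(self):
        split = within_between_turnover(self._structured_cm(), q=1.0)
        assert split.within_mean == pytest.approx(0.0, abs=1e-12)
        assert split.between_mean > 0.5

    def test_all_identical_subplots_give_zero_both(self):
        ids = ["P1-A", "P1-B", "P2-A", "P2-B"]
        cm = make_cm([[3, 1]] * 4, sample_ids=ids,
                     plot_of={i: i.split("-")[0] for i in ids},
                     subplot_of={i: i.split("-")[1] for i in ids})
        split = within_between_turnover(cm, q=1.0)
        assert split.within_mean == pytest.approx(0.0, abs=1e-12)
        assert split.between_mean == pytest.approx(0.0, abs=1e-12)

    def test_pair_counts_partition_all_pairs(self):
        split = within_between_turnover(self._structured_cm(), q=1.0)
        assert len(split.within) + len(split.between) == 15  # C(6,2)
        assert len(split.within) == 3

    def test_plot_level_matrix_rejected(self):
        cm = make_cm([[1, 2], [3, 4]])
        with pytest.raises(DegenerateInputError):
            within_between_turnover(cm)

    def test_plot_structured_simulation_orders_means(self, small_gradient_bundle):
        mats, _, _ = small_gradient_bundle
        split = within_between_turnover(mats["eDNA"], q=1.0)
        assert split.within_mean < split.between_mean
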