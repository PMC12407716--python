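"""PERMANOVA, PCA, moderated differential abundance, FDR and Venn partitioning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phytometab.chemospace import DistanceMatrix
from phytometab.comparative_stats import (
    bh_fdr,
    distance,
    fit_variance_prior,
    moderated_diff,
    pca,
    permanova,
    permanova_two_factor,
    presence_partition,
    trigamma_inverse,
)
from phytometab.curation import curate
from phytometab.synthetic_data import SimConfig, simulate

from .conftest import build_table, design_2x2


def _euclid_dm(points):
    from scipy.spatial.distance import pdist, squareform

    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return DistanceMatrix(labels=[f"s{i}" for i in range(len(pts))],
                          values=squareform(pdist(pts)))


class TestPermanova:
    def test_hand_example_r2(self):
        # groups {0,1} and {10,11}: SS_total = (1+100+121+81+100+1)/4 = 101,
        # SS_within = 1/2 + 1/2 = 1, so R^2 = 100/101
        dm = _euclid_dm([0, 1, 10, 11])
        res = permanova(dm, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.r2 == pytest.approx(100 / 101, abs=1e-12)
        assert res.pseudo_f == pytest.approx((100 / 1) / (1 / 2), abs=1e-9)

    def test_matches_scikit_bio(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 5))
        pts[:6] += 1.5
        dm = _euclid_dm(pts)
        groups = ["g1"] * 6 + ["g2"] * 6
        res = permanova(dm, groups, n_perm=999, seed=0)
        import skbio

        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, ids=dm.labels), groups,
            permutations=999)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-9)
        assert abs(res.p_value - sk["p-value"]) < 0.05

    def test_exact_enumeration_is_rank_statistic(self):
        rng = np.random.default_rng(4)
        dm = _euclid_dm(rng.normal(size=(6, 2)))
        groups = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dm, groups, method="exact")
        assert res.n_perm == math.factorial(6)
        # independent brute force over label reassignments
        labels = np.array(groups)
        d2 = dm.values**2
        def f_of(lab):
            iu = np.triu_indices(6, 1)
            sst = d2[iu].sum() / 6
            ssw = 0.0
            for g in np.unique(lab):
                idx = np.flatnonzero(lab == g)
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            return ((sst - ssw) / 1) / (ssw / 4)
        f_obs = f_of(labels)
        count = sum(f_of(labels[list(p)]) >= f_obs - 1e-12
                    for p in itertools.permutations(range(6)))
        assert res.p_value == pytest.approx(count / math.factorial(6), abs=1e-12)

    def test_montecarlo_converges_to_exact(self):
        rng = np.random.default_rng(10)
        dm = _euclid_dm(rng.normal(size=(6, 2)))
        groups = ["a"] * 3 + ["b"] * 3
        exact = permanova(dm, groups, method="exact").p_value
        mc = permanova(dm, groups, n_perm=719, seed=5).p_value
        # binomial sampling band around the exact p
        se = math.sqrt(exact * (1 - exact) / 720)
        assert abs(mc - exact) < 4 * se + 2 / 720

    def test_r2_invariant_under_relabeling_and_scaling(self):
        rng = np.random.default_rng(3)
        dm = _euclid_dm(rng.normal(size=(8, 3)))
        groups = ["x"] * 4 + ["y"] * 4
        r1 = permanova(dm, groups, n_perm=49, seed=0).r2
        swapped = ["y" if g == "x" else "x" for g in groups]
        r2 = permanova(dm, swapped, n_perm=49, seed=0).r2
        scaled = DistanceMatrix(dm.labels, dm.values * 7.3)
        r3 = permanova(scaled, groups, n_perm=49, seed=0).r2
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-12)

    def test_type_one_error_near_nominal(self):
        # null data: p should be ~Uniform, rejection rate ~5% at alpha=0.05
        rng = np.random.default_rng(123)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            dm = _euclid_dm(rng.normal(size=(10, 4)))
            groups = ["a"] * 5 + ["b"] * 5
            p = permanova(dm, groups, n_perm=99,
                          seed=int(rng.integers(2**31))).p_value
            rejections += p <= 0.05
        rate = rejections / n_sims
        assert 0.01 <= rate <= 0.10

    def test_p_floor_and_seed_reproducibility(self):
        dm = _euclid_dm([0, 1, 10, 11, 20, 21])
        groups = ["a", "a", "b", "b", "c", "c"]
        r1 = permanova(dm, groups, n_perm=199, seed=7)
        r2 = permanova(dm, groups, n_perm=199, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / (199 + 1)

    def test_degenerate_within_zero(self):
        dm = _euclid_dm([0, 0, 5, 5])
        res = permanova(dm, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert math.isinf(res.pseudo_f)
        assert 0 < res.p_value <= 1


class TestPermanovaTwoFactor:
    def test_orthogonal_design_matches_one_way_terms(self):
        # balanced 2x2 with euclidean distances: sequential SS of the first
        # term equals its one-way SS
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 4))
        organs = (["root"] * 6) + (["seed"] * 6)
        procs = (["extract"] * 3 + ["juice"] * 3) * 2
        pts[:6] += 2.0
        dm = _euclid_dm(pts)
        one = permanova(dm, organs, n_perm=99, seed=0)
        two = permanova_two_factor(dm, organs, procs, n_perm=99, seed=0,
                                   names=("organ", "processing"))
        assert two["terms"][0].r2 == pytest.approx(one.r2, abs=1e-9)
        assert two["model_r2"] >= two["terms"][0].r2

    def test_matches_vegan_style_trace_decomposition(self):
        # independent check: SS from explicit Gower-centred trace algebra
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        a = ["x"] * 4 + ["y"] * 4
        b = (["u", "v"] * 4)
        dm = _euclid_dm(pts)
        res = permanova_two_factor(dm, a, b, n_perm=49, seed=0)
        n = 8
        d2 = dm.values**2
        J = np.eye(n) - 1 / n
        G = -0.5 * J @ d2 @ J
        ss_total = np.trace(G)
        assert res["total_ss"] == pytest.approx(ss_total, rel=1e-9)
        assert (res["terms"][0].r2 * ss_total + res["terms"][1].r2 * ss_total
                + res["residual_ss"]) == pytest.approx(ss_total, rel=1e-9)


class TestDistance:
    def test_identical_samples_zero(self):
        t = build_table({"A": [5.0, 5.0, 1.0, 1.0], "B": [2.0, 2.0, 3.0, 3.0]},
                        design_2x2(1, 0))
        dm = distance(t, "bray-curtis")
        assert dm.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_bray_curtis_is_one(self):
        t = build_table({"A": [1.0, 0.0, 1.0, 1.0], "B": [0.0, 1.0, 1.0, 1.0]},
                        design_2x2(1, 0))
        assert distance(t, "bray-curtis").values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_arithmetic(self):
        t = build_table({"A": [2.0, 1.0, 9.0, 9.0], "B": [2.0, 1.0, 9.0, 9.0]},
                        design_2x2(1, 0))
        assert distance(t, "bray-curtis").values[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_sample_errors(self):
        t = build_table({"A": [0.0, 1.0, 1.0, 1.0]}, design_2x2(1, 0))
        with pytest.raises(ValueError, match="all-zero"):
            distance(t, "bray-curtis")

    def test_matches_scipy_braycurtis(self):
        rng = np.random.default_rng(2)
        data = {f"F{i}": rng.uniform(0, 1e5, 4).tolist() for i in range(30)}
        t = build_table(data, design_2x2(1, 0))
        dm = distance(t, "bray-curtis")
        from scipy.spatial.distance import braycurtis

        X = t.intensities.to_numpy().T
        assert dm.values[1, 3] == pytest.approx(braycurtis(X[1], X[3]), rel=1e-12)


class TestPca:
    def test_two_samples_single_component(self):
        t = build_table({"A": [1.0, 100.0, 1.0, 100.0], "B": [2.0, 50.0, 2.0, 50.0]},
                        design_2x2(1, 0))
        res = pca(t)
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_duplicated_sample_coincides_in_score_space(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(1e3, 1e6, 20)
        data = {f"F{i}": [col[i], col[i], rng.uniform(1e3, 1e6),
                          rng.uniform(1e3, 1e6)] for i in range(20)}
        t = build_table(data, design_2x2(1, 0))
        res = pca(t)
        s = res.scores.to_numpy()
        assert np.linalg.norm(s[0] - s[1]) < 1e-8

    def test_matches_sklearn_reference(self):
        rng = np.random.default_rng(42)
        data = {f"F{i}": rng.uniform(1e3, 1e6, 8).tolist() for i in range(50)}
        t = build_table(data, design_2x2(2, 0))
        res = pca(t)
        X = np.log2(t.intensities.to_numpy().T + 1)
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        from sklearn.decomposition import PCA as SkPCA

        sk = SkPCA(n_components=res.scores.shape[1]).fit(X)
        ours = res.scores.to_numpy()
        theirs = sk.transform(X)
        for j in range(ours.shape[1]):
            assert (np.allclose(ours[:, j], theirs[:, j], atol=1e-8)
                    or np.allclose(ours[:, j], -theirs[:, j], atol=1e-8))
        assert np.allclose(
            res.explained_pct, 100 * sk.explained_variance_ratio_, atol=1e-6)

    def test_components_orthogonal(self):
        rng = np.random.default_rng(5)
        data = {f"F{i}": rng.uniform(1e3, 1e6, 12).tolist() for i in range(40)}
        t = build_table(data, design_2x2(3, 0))
        L = pca(t).loadings.to_numpy()
        gram = L.T @ L
        assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-8)

    def test_fewer_than_two_samples_errors(self):
        from phytometab.feature_table_io import SampleMeta
        t = build_table({"A": [1.0]}, [SampleMeta("s1", "root", "extract", 1)])
        with pytest.raises(ValueError, match="at least 2"):
            pca(t)


class TestVariancePrior:
    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for x in (0.1, 0.5, 2.0, 10.0, 100.0):
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_recovers_simulated_hyperparameters(self):
        # scaled-inverse-chi-square truth: d0=4, s0^2=0.25
        d0_true, s0_true, df = 4.0, 0.25, 4
        rng = np.random.default_rng(0)
        d0s, s0s = [], []
        for _ in range(10):
            sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=2000)
            s2 = sigma2 * rng.chisquare(df, size=2000) / df
            d0_hat, s0_hat = fit_variance_prior(s2, df)
            d0s.append(d0_hat)
            s0s.append(s0_hat)
        assert abs(np.mean(d0s) - d0_true) / d0_true < 0.30
        assert abs(np.mean(s0s) - s0_true) / s0_true < 0.15

    def test_underdispersed_variances_give_infinite_d0(self):
        s2 = np.full(500, 0.3)
        d0, s0 = fit_variance_prior(s2, 4)
        assert math.isinf(d0)
        assert s0 > 0


class TestModeratedDiff:
    def _table(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        data = {f"F{i}": np.exp(rng.normal(11, 1)) *
                np.exp(rng.normal(0, 0.15, 14)) for i in range(n)}
        return build_table({k: v.tolist() for k, v in data.items()},
                           design_2x2(3, 2)).drop_blank_columns()

    def test_no_moderation_limit_equals_pooled_t(self):
        t = self._table()
        res = moderated_diff(t, ("root", "seed"), d0_override=0.0)
        X = np.log2(t.intensities.to_numpy() + 1)
        g1 = [i for i, s in enumerate(t.samples) if s.organ == "root"]
        g2 = [i for i, s in enumerate(t.samples) if s.organ == "seed"]
        from scipy import stats as sps

        tt = sps.ttest_ind(X[:, g2], X[:, g1], axis=1, equal_var=True)
        assert np.allclose(res.table["mod_t"], tt.statistic, atol=1e-9)
        assert np.allclose(res.table["p"], tt.pvalue, atol=1e-9)

    def test_complete_shrinkage_limit_constant_variance(self):
        t = self._table()
        res = moderated_diff(t, ("root", "seed"), d0_override=math.inf)
        assert np.allclose(res.table["s2_post"], res.s0_sq)
        # t proportional to log2fc with a constant standard error
        n1 = sum(s.organ == "root" for s in t.samples)
        n2 = sum(s.organ == "seed" for s in t.samples)
        se = math.sqrt(res.s0_sq * (1 / n1 + 1 / n2))
        assert np.allclose(res.table["mod_t"], res.table["log2fc"] / se, atol=1e-9)

    def test_posterior_variance_between_limits(self):
        t = self._table()
        res = moderated_diff(t, ("root", "seed"))
        lo = np.minimum(res.table["s2"], res.s0_sq)
        hi = np.maximum(res.table["s2"], res.s0_sq)
        assert ((res.table["s2_post"] >= lo - 1e-12)
                & (res.table["s2_post"] <= hi + 1e-12)).all()

    def test_planted_effects_recovered(self):
        cfg = SimConfig(n_features=200, seed=77)
        table, truth, _ = simulate(cfg)
        curated, _ = curate(table)
        res = moderated_diff(curated, ("root", "seed"))
        truth = truth.set_index("feature_id")
        called = set(res.enriched["feature_id"])
        planted = {f for f in curated.feature_ids
                   if truth.at[f, "role"].startswith("organ_")}
        tp = len(called & planted)
        precision = tp / len(called) if called else 0.0
        recall = tp / len(planted)
        assert precision >= 0.9
        assert recall >= 0.9
        # direction: seed-enriched features called in seed
        for f in called & planted:
            want = ("seed" if truth.at[f, "role"] == "organ_enriched_seed"
                    else "root")
            got = res.table.set_index("feature_id").at[f, "enriched_in"]
            assert got == want

    def test_group_with_single_replicate_errors(self):
        from phytometab.feature_table_io import SampleMeta

        samples = [SampleMeta("root_extract_1", "root", "extract", 1),
                   SampleMeta("seed_extract_1", "seed", "extract", 1),
                   SampleMeta("seed_juice_1", "seed", "juice", 1)]
        t = build_table({"A": [1.0, 2.0, 3.0]}, samples)
        with pytest.raises(ValueError, match="fewer than 2"):
            moderated_diff(t, ("root", "seed"))

    def test_all_zero_variance_handled(self):
        data = {f"F{i}": [100.0] * 6 + [200.0] * 6 for i in range(5)}
        t = build_table(data, design_2x2(3, 0))
        res = moderated_diff(t, ("root", "seed"))
        assert math.isinf(res.d0)
        assert np.isfinite(res.table["log2fc"]).all()


class TestBhFdr:
    def test_hand_stepup_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_fdr([0.2] * 6), 0.2)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=200)
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=50)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestPresencePartition:
    def test_inclusive_detection_boundary(self):
        t = build_table(
            {"A": [10_000.0, 0.0, 0.0, 0.0], "B": [9_999.0] * 4},
            design_2x2(1, 0),
        )
        pp = presence_partition(t, "organ", 10_000.0)
        assert pp.detected["root"] == {"A"}
        assert pp.exclusive["root"] == {"A"}
        assert pp.detected["seed"] == set()
        assert "B" not in pp.detected["root"]

    def test_shared_feature(self):
        t = build_table({"A": [50_000.0] * 4}, design_2x2(1, 0))
        pp = presence_partition(t, "organ")
        assert pp.shared == {"A"}
        assert pp.exclusive["root"] == set() == pp.exclusive["seed"]

    def test_partition_identity(self, fixture_table):
        curated, _ = curate(fixture_table)
        for factor in ("organ", "processing"):
            pp = presence_partition(curated, factor)
            union = set().union(*pp.detected.values())
            excl_union = set().union(*pp.exclusive.values())
            assert excl_union | pp.shared == union
            assert excl_union & pp.shared == set()
            levels = list(pp.exclusive)
            assert pp.exclusive[levels[0]] & pp.exclusive[levels[1]] == set()

    def test_unknown_factor_errors(self, fixture_table):
        with pytest.raises(ValueError):
            presence_partition(fixture_table, "cultivar")
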