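import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from rhizonet.core_io import FeatureTable
from rhizonet.multivariate import (
    alpha_diversity,
    bray_curtis,
    mantel,
    pcoa,
    permanova,
    variation_partition,
)


def _dist(points: np.ndarray, ids=None) -> pd.DataFrame:
    d = squareform(pdist(points))
    ids = ids or [f"s{i}" for i in range(len(points))]
    return pd.DataFrame(d, index=ids, columns=ids)


class TestAlphaDiversity:
    def test_uniform_profile_shannon_ln_s(self):
        t = FeatureTable(pd.DataFrame([[5, 5, 5, 5]], index=["s"],
                                      columns=list("abcd")))
        out = alpha_diversity(t)
        assert out.loc["s", "shannon"] == pytest.approx(np.log(4))

    def test_chao1_formula(self):
        # S_obs=10, F1=4 singletons, F2=2 doubletons -> 10 + 4*3/(2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 5, 7, 9, 11]
        t = FeatureTable(pd.DataFrame([counts], index=["s"],
                                      columns=[f"t{i}" for i in range(10)]))
        out = alpha_diversity(t)
        assert out.loc["s", "chao1"] == pytest.approx(12.0)

    def test_chao1_no_singletons_equals_richness(self):
        counts = [3, 4, 5, 2, 2]
        t = FeatureTable(pd.DataFrame([counts], index=["s"],
                                      columns=[f"t{i}" for i in range(5)]))
        out = alpha_diversity(t)
        assert out.loc["s", "chao1"] == pytest.approx(5.0)

    def test_chao1_at_least_observed_richness(self, rng):
        vals = rng.integers(0, 10, size=(6, 20))
        vals[:, 0] = 1  # guarantee non-empty samples
        t = FeatureTable(pd.DataFrame(vals.astype(float),
                                      columns=[f"t{i}" for i in range(20)]))
        out = alpha_diversity(t)
        sobs = (t.data > 0).sum(axis=1)
        assert (out["chao1"] >= sobs - 1e-9).all()


class TestBrayCurtis:
    def test_fixture_values(self):
        df = pd.DataFrame([[1.0, 1.0], [0.0, 2.0], [1.0, 1.0], [5.0, 0.0]],
                          index=list("abcd"), columns=["t1", "t2"])
        d = bray_curtis(FeatureTable(df))
        assert d.loc["a", "c"] == pytest.approx(0.0)
        assert d.loc["a", "b"] == pytest.approx(0.5)
        assert d.loc["b", "d"] == pytest.approx(1.0)  # disjoint supports
        assert np.allclose(d, d.T)
        assert (d.to_numpy() >= 0).all() and (d.to_numpy() <= 1 + 1e-12).all()


class TestPcoa:
    def test_recovers_euclidean_configuration(self, rng):
        pts = rng.random((10, 2))
        coords, eigvals, prop = pcoa(_dist(pts))
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, coords.iloc[:, :2].to_numpy())
        assert disparity < 1e-6

    def test_equilateral_triangle_equal_eigenvalues(self):
        d = pd.DataFrame(1 - np.eye(3), index=list("abc"), columns=list("abc"))
        coords, eigvals, _ = pcoa(d)
        positive = eigvals[eigvals > 1e-10]
        assert len(positive) == 2
        assert positive.iloc[0] == pytest.approx(positive.iloc[1])

    def test_duplicate_sample_same_coordinates(self, rng):
        pts = rng.random((6, 3))
        pts[5] = pts[0]
        coords, _, _ = pcoa(_dist(pts))
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[5], atol=1e-8)


class TestPermanova:
    def _meta(self, labels, ids):
        return pd.DataFrame({"group": labels}, index=ids)

    def test_strong_separation_minimum_p(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (9, 2)), rng.normal(5, 0.1, (9, 2))])
        d = _dist(pts)
        meta = self._meta(["A"] * 9 + ["B"] * 9, d.index)
        res = permanova(d, meta, terms=("group",), n_perm=999, seed=0)
        assert res.table.loc["group", "p"] == pytest.approx(0.001)

    def test_r2_partition_sums_to_one(self, default_dataset):
        table, meta = default_dataset[0], default_dataset[1]
        d = bray_curtis(table)
        res = permanova(d, meta, n_perm=49, seed=1)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)

    def test_euclidean_univariate_matches_anova_f(self, rng):
        y = rng.normal(size=18)
        labels = ["A"] * 6 + ["B"] * 6 + ["C"] * 6
        d = _dist(y[:, None])
        meta = self._meta(labels, d.index)
        res = permanova(d, meta, terms=("group",), n_perm=9, seed=0)
        f_classic = stats.f_oneway(y[:6], y[6:12], y[12:]).statistic
        assert res.table.loc["group", "F"] == pytest.approx(f_classic, abs=1e-9)

    def test_one_way_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

        pts = rng.random((12, 4))
        d = _dist(pts)
        labels = ["A", "B", "C"] * 4
        meta = self._meta(labels, d.index)
        res = permanova(d, meta, terms=("group",), n_perm=99, seed=0)
        sk = sk_permanova(DistanceMatrix(d.to_numpy(), ids=list(d.index)),
                          grouping=labels, permutations=0)
        assert res.table.loc["group", "F"] == pytest.approx(sk["test statistic"],
                                                            rel=1e-9)

    def test_type_i_error_calibrated(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            vals = rng.random((18, 5))
            d = _dist(vals)
            labels = list(rng.permutation(["A"] * 9 + ["B"] * 9))
            meta = self._meta(labels, d.index)
            res = permanova(d, meta, terms=("group",), n_perm=99,
                            seed=int(rng.integers(2**31)))
            hits += res.table.loc["group", "p"] < 0.05
        assert abs(hits / reps - 0.05) <= 0.04


class TestMantel:
    def test_identity_and_scale_invariance(self, rng):
        d = _dist(rng.random((8, 3)))
        assert mantel(d, d, n_perm=99, seed=0)["r"] == pytest.approx(1.0)
        assert mantel(d, 2 * d, n_perm=99, seed=0)["r"] == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        d = _dist(rng.random((8, 3)))
        d2 = 0.3 * d + 0.7 * (1 - np.eye(8))
        d2 = pd.DataFrame(d2.to_numpy(), index=d.index, columns=d.columns)
        assert mantel(d, d2, n_perm=99, seed=0)["r"] == pytest.approx(1.0)

    def test_r_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        d1 = _dist(rng.random((9, 3)))
        d2 = _dist(rng.random((9, 3)))
        mine = mantel(d1, d2, n_perm=99, seed=0)
        sk_r = sk_mantel(DistanceMatrix(d1.to_numpy()), DistanceMatrix(d2.to_numpy()),
                         permutations=0)
        assert mine["r"] == pytest.approx(float(sk_r[0]), rel=1e-9)

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            d1 = _dist(rng.random((10, 3)))
            d2 = _dist(rng.random((10, 3)))
            ps.append(mantel(d1, d2, n_perm=49, seed=int(rng.integers(2**31)))["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestVpa:
    def test_single_set_exact_fit(self, rng):
        x = pd.DataFrame(rng.random((30, 2)), columns=["a", "b"])
        y = pd.DataFrame({"y1": x["a"] + x["b"], "y2": 2 * x["a"] - x["b"]})
        res = variation_partition(y, {"X1": x})
        assert res.total_adj_r2 == pytest.approx(1.0)
        assert res.residual == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_halves(self, rng):
        n = 200
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        # orthogonalise in-sample so each set generates exactly half the variance
        a = a - a.mean()
        b = b - b.mean()
        b = b - (a @ b) / (a @ a) * a
        a, b = a / a.std(), b / b.std()
        x1 = pd.DataFrame({"a": a})
        x2 = pd.DataFrame({"b": b})
        y = pd.DataFrame({"y": x1["a"] + x2["b"]})
        res = variation_partition(y, {"X1": x1, "X2": x2})
        assert res.fractions["X1"] == pytest.approx(0.5, abs=0.05)
        assert res.fractions["X2"] == pytest.approx(0.5, abs=0.05)
        assert res.fractions["X1&X2"] == pytest.approx(0.0, abs=0.05)

    def test_fractions_sum_to_total(self, rng):
        y = pd.DataFrame(rng.random((30, 3)))
        xs = {"A": pd.DataFrame(rng.random((30, 2))),
              "B": pd.DataFrame(rng.random((30, 2))),
              "C": pd.DataFrame(rng.random((30, 2)))}
        res = variation_partition(y, xs)
        assert sum(res.fractions.values()) == pytest.approx(res.total_adj_r2,
                                                            abs=1e-9)

    def test_collinear_predictors_dropped_with_warning(self, rng):
        x = pd.DataFrame(rng.random((20, 2)), columns=["a", "b"])
        x["c"] = x["a"] + x["b"]
        y = pd.DataFrame({"y": rng.random(20)})
        with pytest.warns(UserWarning, match="collinear"):
            variation_partition(y, {"X1": x})
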