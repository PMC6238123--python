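"""Dpw/Dnn, beta SES, spatial distances, Mantel and partial Mantel."""

import numpy as np
import pandas as pd
import pytest

import rangephylo as rp
from conftest import brute_dnn, brute_dpw, random_community, random_tree


class TestBetaMetrics:
    def test_hand_worked_cross_pairs(self, toy_D):
        assert rp.dpw(["A", "B"], ["C"], toy_D) == pytest.approx(4.0)
        # identical assemblages: self pairs contribute zeros
        assert rp.dpw(["A", "B"], ["A", "B"], toy_D) == pytest.approx(1.0)
        assert rp.dnn(["A", "B"], ["A", "B"], toy_D) == pytest.approx(0.0)
        assert rp.dnn(["A"], ["C"], toy_D) == pytest.approx(4.0)
        assert rp.dnn(["A", "B"], ["C"], toy_D) == pytest.approx(4.0)

    def test_empty_side_missing(self, toy_D):
        assert np.isnan(rp.dpw([], ["A"], toy_D))
        assert np.isnan(rp.dnn(["A"], [], toy_D))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        tree = random_tree(10, seed=seed)
        D = rp.patristic_distances(tree)
        rng = np.random.default_rng(seed)
        for _ in range(20):
            c1 = random_community(rng, D.labels, k_min=1)
            c2 = random_community(rng, D.labels, k_min=1)
            assert rp.dpw(c1, c2, D) == pytest.approx(brute_dpw(c1, c2, D))
            assert rp.dnn(c1, c2, D) == pytest.approx(brute_dnn(c1, c2, D))

    def test_symmetric_in_arguments(self, toy_D):
        rng = np.random.default_rng(3)
        tree = random_tree(12, seed=3)
        D = rp.patristic_distances(tree)
        for _ in range(20):
            c1 = random_community(rng, D.labels, k_min=1)
            c2 = random_community(rng, D.labels, k_min=1)
            assert rp.dpw(c1, c2, D) == pytest.approx(rp.dpw(c2, c1, D))
            assert rp.dnn(c1, c2, D) == pytest.approx(rp.dnn(c2, c1, D))


@pytest.fixture(scope="module")
def neutral():
    cfg = rp.ScenarioConfig(
        n_species=40, n_plots=30, process="neutral", mean_richness=10, seed=1
    )
    tree, comm, env, _ = rp.simulate_dataset(cfg)
    D = rp.patristic_distances(tree).reorder(list(comm.columns))
    return comm, env, D


class TestSesBeta:
    def test_neutral_ses_centered(self, neutral):
        comm, _, D = neutral
        bm = rp.ses_beta(comm, D, metric="dpw", n_null=999, seed=2)
        off = bm.ses[np.triu_indices(len(comm), k=1)]
        assert abs(np.nanmean(off)) < 0.2

    def test_sign_convention(self, neutral):
        comm, _, D = neutral
        bm = rp.ses_beta(comm, D, metric="dnn", n_null=199, seed=3)
        iu = np.triu_indices(len(comm), k=1)
        above = bm.observed[iu] > bm.null_mean[iu]
        assert ((bm.ses[iu] > 0) == above).all()

    def test_matrices_symmetric(self, neutral):
        comm, _, D = neutral
        bm = rp.ses_beta(comm, D, metric="dpw", n_null=99, seed=4)
        assert np.allclose(bm.observed, bm.observed.T)
        assert np.allclose(bm.ses, bm.ses.T, equal_nan=True)

    def test_deterministic(self, neutral):
        comm, _, D = neutral
        a = rp.ses_beta(comm.iloc[:8], D, metric="dnn", n_null=99, seed=5)
        b = rp.ses_beta(comm.iloc[:8], D, metric="dnn", n_null=99, seed=5)
        assert np.array_equal(a.ses, b.ses, equal_nan=True)


class TestSpatialDistances:
    def test_identical_coordinates_zero(self):
        env = pd.DataFrame(
            {"elevation": [1500.0, 1500.0], "latitude": [36.8, 36.8],
             "longitude": [59.4, 59.4]},
            index=["p1", "p2"],
        )
        sp = rp.spatial_distances(env)
        assert sp.geographic[0, 1] == pytest.approx(0.0)
        assert sp.elevation[0, 1] == pytest.approx(0.0)

    def test_one_degree_meridian_arc(self):
        env = pd.DataFrame(
            {"elevation": [1200.0, 2200.0], "latitude": [36.0, 37.0],
             "longitude": [59.4, 59.4]},
            index=["p1", "p2"],
        )
        sp = rp.spatial_distances(env)
        assert sp.geographic[0, 1] == pytest.approx(111.19, rel=0.005)
        assert sp.elevation[0, 1] == pytest.approx(1000.0)

    def test_latitude_only_fallback(self):
        env = pd.DataFrame(
            {"elevation": [1200.0, 2200.0], "latitude": [36.0, 37.0]},
            index=["p1", "p2"],
        )
        sp = rp.spatial_distances(env)
        assert sp.geographic[0, 1] == pytest.approx(111.19, rel=0.005)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(0)
        env = pd.DataFrame(
            {"elevation": rng.uniform(1200, 2200, 8),
             "latitude": rng.uniform(36, 37, 8),
             "longitude": rng.uniform(59, 60, 8)},
            index=[f"p{i}" for i in range(8)],
        )
        g = rp.spatial_distances(env).geographic
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert g[i, j] <= g[i, k] + g[k, j] + 1e-9


class TestMantel:
    @staticmethod
    def _random_distance(rng, n):
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(rng.random((n, 2))))

    def test_self_correlation_is_one(self):
        X = self._random_distance(np.random.default_rng(0), 10)
        res = rp.mantel(X, X, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_linear_triangles_hand_example(self):
        def fold(tri):
            M = np.zeros((4, 4))
            M[np.triu_indices(4, k=1)] = tri
            return M + M.T

        X = fold([1, 2, 3, 4, 5, 6])
        Y = fold([2, 4, 6, 8, 10, 12])
        assert rp.mantel(X, Y, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        X = self._random_distance(rng, 12)
        Y = self._random_distance(rng, 12)
        r1 = rp.mantel(X, Y, n_perm=99, seed=1).r
        r2 = rp.mantel(3.0 * X + 7.0, 0.5 * Y + 2.0, n_perm=99, seed=1).r
        assert r1 == pytest.approx(r2)

    def test_statistic_matches_scikit_bio(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(2)
        X = self._random_distance(rng, 15)
        Y = X * 0.5 + self._random_distance(rng, 15)
        r_skbio, _, _ = skbio_mantel(X, Y, method="pearson", permutations=0)
        assert rp.mantel(X, Y, n_perm=99, seed=0).r == pytest.approx(
            float(r_skbio), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        X = np.ones((5, 5)) - np.eye(5)
        Y = self._random_distance(np.random.default_rng(3), 5)
        with pytest.raises(ValueError, match="zero variance"):
            rp.mantel(X, Y, n_perm=99, seed=0)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X = self._random_distance(rng, 10)
        Y = self._random_distance(rng, 10)
        assert (
            rp.mantel(X, Y, n_perm=199, seed=5).p_value
            == rp.mantel(X, Y, n_perm=199, seed=5).p_value
        )


class TestPartialMantel:
    @staticmethod
    def _fold(tri, n):
        M = np.zeros((n, n))
        M[np.triu_indices(n, k=1)] = tri
        return M + M.T

    def test_collapses_to_simple_when_z_orthogonal(self):
        # Z's triangle is residualised against X's and Y's, so r_XZ = r_YZ = 0
        rng = np.random.default_rng(0)
        n = 15
        m = n * (n - 1) // 2
        x = rng.random(m)
        y = 0.6 * x + 0.4 * rng.random(m)
        z0 = rng.random(m)
        A = np.column_stack([np.ones(m), x, y])
        z = z0 - A @ np.linalg.lstsq(A, z0, rcond=None)[0]
        X, Y, Z = self._fold(x, n), self._fold(y, n), self._fold(z, n)
        simple = rp.mantel(X, Y, n_perm=99, seed=1)
        partial = rp.partial_mantel(X, Y, Z, n_perm=99, seed=1)
        assert partial.r == pytest.approx(simple.r, abs=1e-10)

    def test_association_through_z_vanishes(self):
        rng = np.random.default_rng(1)
        n = 20
        m = n * (n - 1) // 2
        z = rng.random(m)
        x = z + 0.05 * rng.random(m)
        y = z + 0.05 * rng.random(m)
        partial = rp.partial_mantel(
            self._fold(x, n), self._fold(y, n), self._fold(z, n),
            n_perm=99, seed=2,
        )
        simple = rp.mantel(self._fold(x, n), self._fold(y, n), n_perm=99, seed=2)
        assert simple.r > 0.9
        assert abs(partial.r) < 0.2

    def test_collinear_conditioning_rejected(self):
        rng = np.random.default_rng(2)
        m = 10 * 9 // 2
        y = rng.random(m)
        x = rng.random(m)
        Y = self._fold(y, 10)
        with pytest.raises(ValueError, match="collinear"):
            rp.partial_mantel(self._fold(x, 10), Y, Y, n_perm=99, seed=0)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        m = 12 * 11 // 2
        X = self._fold(rng.random(m), 12)
        Y = self._fold(rng.random(m), 12)
        Z = self._fold(rng.random(m), 12)
        p1 = rp.partial_mantel(X, Y, Z, n_perm=199, seed=7).p_value
        p2 = rp.partial_mantel(X, Y, Z, n_perm=199, seed=7).p_value
        assert p1 == p2
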