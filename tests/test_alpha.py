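"""MPD/MNTD, the pool-randomisation null, SES and gradient regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rangephylo as rp
from conftest import brute_mntd, brute_mpd, random_community, random_tree


class TestMetrics:
    def test_hand_worked_three_tip_tree(self, toy_D):
        assert rp.mpd(["A", "B", "C"], toy_D) == pytest.approx(10 / 3)
        assert rp.mpd(["A", "B"], toy_D) == pytest.approx(2.0)
        assert rp.mntd(["A", "B", "C"], toy_D) == pytest.approx(8 / 3)
        assert rp.mntd(["A", "B"], toy_D) == pytest.approx(2.0)

    def test_weighted_equals_unweighted_for_equal_abundances(self, toy_D):
        comm = pd.Series({"A": 3, "B": 3, "C": 3})
        assert rp.mpd(comm, toy_D, weighted=True) == pytest.approx(
            rp.mpd(comm, toy_D, weighted=False)
        )
        assert rp.mntd(comm, toy_D, weighted=True) == pytest.approx(
            rp.mntd(comm, toy_D, weighted=False)
        )

    def test_single_species_undefined(self, toy_D):
        assert np.isnan(rp.mpd(["A"], toy_D))
        assert np.isnan(rp.mntd(["A"], toy_D))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        tree = random_tree(10, seed=seed)
        D = rp.patristic_distances(tree)
        rng = np.random.default_rng(seed)
        for _ in range(20):
            comm = random_community(rng, D.labels)
            assert rp.mpd(comm, D) == pytest.approx(brute_mpd(comm, D))
            assert rp.mntd(comm, D) == pytest.approx(brute_mntd(comm, D))
            abund = {s: int(rng.integers(1, 6)) for s in comm}
            assert rp.mpd(pd.Series(abund), D, weighted=True) == pytest.approx(
                brute_mpd(comm, D, abund)
            )
            assert rp.mntd(pd.Series(abund), D, weighted=True) == pytest.approx(
                brute_mntd(comm, D, abund)
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_mntd_never_exceeds_mpd(self, data):
        tree = random_tree(10, seed=data.draw(st.integers(0, 20)))
        D = rp.patristic_distances(tree)
        k = data.draw(st.integers(2, 10))
        comm = data.draw(
            st.lists(st.sampled_from(D.labels), min_size=k, max_size=k, unique=True)
        )
        assert rp.mntd(comm, D) <= rp.mpd(comm, D) + 1e-12


class TestNullCommunities:
    @pytest.fixture()
    def comm(self):
        return pd.DataFrame(
            {"s1": [3, 0, 1], "s2": [1, 2, 0], "s3": [0, 5, 0]},
            index=["p1", "p2", "p3"],
        )

    def test_preserves_richness_and_abundance_multiset(self, comm):
        pool = [f"s{i}" for i in range(1, 9)]
        for null in rp.null_communities(comm, pool, n_null=20, seed=0):
            assert ((null > 0).sum(axis=1) == (comm > 0).sum(axis=1)).all()
            for plot in comm.index:
                a = sorted(null.loc[plot][null.loc[plot] > 0])
                b = sorted(comm.loc[plot][comm.loc[plot] > 0])
                assert a == b

    def test_full_pool_plot_keeps_identity_set(self, comm):
        # richness equals pool size: identities forced, pairing varies
        for null in rp.null_communities(
            comm.iloc[[0]], ["s1", "s2"], n_null=10, seed=1
        ):
            assert set(null.columns[(null > 0).any()]) == {"s1", "s2"}

    def test_inclusion_frequency_uniform(self):
        plot = pd.DataFrame({f"s{i}": [1 if i < 5 else 0] for i in range(20)},
                            index=["p1"])
        pool = [f"s{i}" for i in range(20)]
        count = np.zeros(20)
        for null in rp.null_communities(plot, pool, n_null=1000, seed=2):
            count += (null.to_numpy()[0] > 0)
        freq = count / 1000
        p = 5 / 20
        se = np.sqrt(p * (1 - p) / 1000)
        assert (np.abs(freq - p) < 4.5 * se).all()

    def test_deterministic(self, comm):
        a = [df.copy() for df in rp.null_communities(comm, n_null=5, seed=3)]
        b = [df.copy() for df in rp.null_communities(comm, n_null=5, seed=3)]
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_plot_richer_than_pool_rejected(self, comm):
        with pytest.raises(ValueError):
            list(rp.null_communities(comm, ["s1", "s2", "s3"][:2], n_null=2))


class TestSES:
    def test_branch_rescaling_invariance(self):
        cfg = rp.ScenarioConfig(n_species=20, n_plots=12, mean_richness=6, seed=4)
        tree, comm, _, _ = rp.simulate_dataset(cfg)
        D = rp.patristic_distances(tree).reorder(list(comm.columns))
        D10 = rp.PatristicMatrix(D.labels, D.values * 10.0)
        a = rp.ses("mpd", comm, D, n_null=199, seed=5)
        b = rp.ses("mpd", comm, D10, n_null=199, seed=5)
        pd.testing.assert_series_equal(a["ses"], b["ses"])

    def test_neutral_calibration_small(self):
        cfg = rp.ScenarioConfig(
            n_species=40, n_plots=60, process="neutral", mean_richness=10, seed=6
        )
        tree, comm, _, _ = rp.simulate_dataset(cfg)
        D = rp.patristic_distances(tree).reorder(list(comm.columns))
        t = rp.ses("mntd", comm, D, n_null=499, seed=7)
        z = t["ses"].dropna()
        assert abs(z.mean()) < 0.3
        assert 0.7 < z.std() < 1.3

    def test_depauperate_plot_reported_missing(self, toy_D):
        comm = pd.DataFrame({"A": [1, 1], "B": [1, 0], "C": [1, 0]},
                            index=["p1", "p2"])
        t = rp.ses("mpd", comm, toy_D, n_null=99, seed=0)
        assert np.isnan(t.loc["p2", "ses"])
        assert np.isfinite(t.loc["p1", "ses"])

    def test_shuffle_null_flag(self):
        cfg = rp.ScenarioConfig(n_species=20, n_plots=10, mean_richness=6, seed=8)
        tree, comm, _, _ = rp.simulate_dataset(cfg)
        D = rp.patristic_distances(tree).reorder(list(comm.columns))
        t = rp.ses("mpd", comm, D, n_null=199, seed=9, null_model="shuffle")
        assert t["ses"].notna().sum() > 0

    def test_deterministic(self):
        cfg = rp.ScenarioConfig(n_species=20, n_plots=10, mean_richness=6, seed=8)
        tree, comm, _, _ = rp.simulate_dataset(cfg)
        D = rp.patristic_distances(tree).reorder(list(comm.columns))
        a = rp.ses("mntd", comm, D, n_null=199, seed=10)
        b = rp.ses("mntd", comm, D, n_null=199, seed=10)
        pd.testing.assert_frame_equal(a, b)


class TestHabitatAssemblage:
    def test_one_plot_per_habitat_identity(self):
        comm = pd.DataFrame({"s1": [1, 2], "s2": [0, 3]}, index=["p1", "p2"])
        habitats = pd.Series(["H1", "H2"], index=comm.index)
        pooled = rp.habitat_assemblage(comm, habitats)
        assert (pooled.loc["H1"] == comm.loc["p1"]).all()
        assert (pooled.loc["H2"] == comm.loc["p2"]).all()

    def test_rows_sum_within_habitat(self):
        comm = pd.DataFrame({"s1": [1, 0], "s2": [0, 2]}, index=["p1", "p2"])
        habitats = pd.Series(["H1", "H1"], index=comm.index)
        pooled = rp.habitat_assemblage(comm, habitats)
        assert list(pooled.loc["H1"]) == [1, 2]

    def test_total_abundance_conserved(self):
        rng = np.random.default_rng(0)
        comm = pd.DataFrame(rng.poisson(2.0, size=(10, 5)),
                            index=[f"p{i}" for i in range(10)])
        habitats = pd.Series(rng.choice(["H1", "H2", "H3"], size=10),
                             index=comm.index)
        pooled = rp.habitat_assemblage(comm, habitats)
        assert pooled.to_numpy().sum() == comm.to_numpy().sum()


class TestGradientRegression:
    def test_exact_linear_fit(self):
        x = np.linspace(0, 10, 20)
        ses_table = pd.DataFrame(
            {"metric": "mpd", "ses": 2 * x + 1},
            index=pd.Index([f"p{i}" for i in range(20)], name="unit"),
        )
        env = pd.DataFrame({"elevation": x}, index=ses_table.index)
        fit = rp.regress_ses(ses_table, env, "elevation")
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_null_slope_p_uniform(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=30)
            ses_table = pd.DataFrame(
                {"metric": "mpd", "ses": rng.normal(size=30)},
                index=pd.Index([f"p{i}" for i in range(30)], name="unit"),
            )
            env = pd.DataFrame({"elevation": x}, index=ses_table.index)
            pvals.append(rp.regress_ses(ses_table, env, "elevation").p_value)
        assert 0.02 <= np.mean(np.array(pvals) <= 0.05) <= 0.10

    def test_zero_variance_predictor_rejected(self):
        ses_table = pd.DataFrame(
            {"metric": "mpd", "ses": [0.1, 0.2, 0.3]},
            index=pd.Index(["p1", "p2", "p3"], name="unit"),
        )
        env = pd.DataFrame({"elevation": [1500.0] * 3}, index=ses_table.index)
        with pytest.raises(ValueError, match="zero variance"):
            rp.regress_ses(ses_table, env, "elevation")
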