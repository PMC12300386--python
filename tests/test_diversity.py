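import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from hydrobiome.io import CountTable, DistanceMatrix, SampleMetadata
from hydrobiome import diversity as dv

from conftest import random_count_table


class TestRarefy:
    def test_identity_at_own_depth(self, small_table):
        # columns sum to 6 and 9; rarefying to the minimum keeps the shallow one
        out = dv.rarefy(small_table, 6, seed=0)
        assert (out.sample_sums() == 6).all()
        np.testing.assert_array_equal(out.counts[:, 0], small_table.counts[:, 0])

    def test_forced_draw(self):
        t = CountTable(["A", "B"], ["s1", "s2"], np.array([[5, 10], [5, 10]]))
        out = dv.rarefy(t, 10, seed=1)
        np.testing.assert_array_equal(out.counts[:, 0], [5, 5])

    def test_shallow_samples_listed(self, small_table):
        with pytest.raises(ValueError, match="s1"):
            dv.rarefy(small_table, 8)

    def test_hypergeometric_expectation(self):
        # 30/70 composition subsampled to 1e4: mean proportion ~ 0.30
        t = CountTable(
            ["A", "B"], ["s1", "s2"],
            np.array([[300000, 30000], [700000, 70000]]),
        )
        props = [
            dv.rarefy(t, 10000, seed=s).counts[0, 0] / 10000 for s in range(200)
        ]
        assert np.mean(props) == pytest.approx(0.30, abs=0.01)


class TestShannon:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([10, 10], np.log(2)),
            ([7, 0, 0], 0.0),
            ([1, 1, 1, 1], np.log(4)),
        ],
    )
    def test_known_values(self, column, expected):
        assert dv.shannon(np.array(column)) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dv.shannon(np.zeros(3))


class TestFaithPD:
    # worked tree ((A:1,B:1):1,C:2); root path included.
    # {A,B} -> 3; {C} -> 2; {A,B,C} -> sum of all branches = 1+1+1+2 = 5
    @pytest.mark.parametrize(
        "column,expected",
        [([1, 1, 0], 3.0), ([0, 0, 1], 2.0), ([1, 1, 1], 5.0)],
    )
    def test_worked_tree(self, worked_tree, column, expected):
        got = dv.faith_pd(np.array(column), ["A", "B", "C"], worked_tree)
        assert got == pytest.approx(expected)

    def test_missing_taxon_named(self, worked_tree):
        with pytest.raises(ValueError, match="Z"):
            dv.faith_pd(np.array([1, 1]), ["A", "Z"], worked_tree)


class TestBrayCurtis:
    def test_known_values(self):
        t = CountTable(
            ["x", "y"], ["a", "b", "c"], np.array([[2, 1, 2], [2, 3, 2]])
        )
        d = dv.bray_curtis(t)
        assert d.values[0, 1] == pytest.approx(0.25)
        assert d.values[0, 2] == pytest.approx(0.0)

    def test_disjoint_is_one(self):
        t = CountTable(["x", "y"], ["a", "b"], np.array([[1, 0], [0, 1]]))
        assert dv.bray_curtis(t).values[0, 1] == pytest.approx(1.0)


class TestBetaMNTD:
    def test_identical_communities_zero(self, worked_tree):
        t = CountTable(["A", "B", "C"], ["k", "l"], np.array([[3, 3], [1, 1], [2, 2]]))
        assert dv.beta_mntd(t, worked_tree).values[0, 1] == pytest.approx(0.0)

    def test_single_taxon_pair_is_patristic_distance(self, worked_tree):
        t = CountTable(["A", "B", "C"], ["k", "l"], np.array([[5, 0], [0, 0], [0, 7]]))
        # d(A,C) = 1 + 1 + 2 = 4
        assert dv.beta_mntd(t, worked_tree).values[0, 1] == pytest.approx(4.0)

    def test_unweighted_equals_weighted_for_equal_abundances(self, worked_tree):
        t = CountTable(["A", "B", "C"], ["k", "l"], np.array([[2, 0], [2, 2], [0, 2]]))
        w = dv.beta_mntd(t, worked_tree, weighted=True).values[0, 1]
        u = dv.beta_mntd(t, worked_tree, weighted=False).values[0, 1]
        assert w == pytest.approx(u)


class TestPCoA:
    def test_equilateral_triangle_eigenvalues(self):
        d = DistanceMatrix(list("abc"), np.ones((3, 3)) - np.eye(3))
        res = dv.pcoa(d, k=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.eigenvalues[2] == pytest.approx(0.0, abs=1e-12)

    def test_collinear_points_rank_one(self):
        vals = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        res = dv.pcoa(DistanceMatrix(list("abc"), vals), k=2)
        assert (res.eigenvalues > 1e-10).sum() == 1

    def test_reconstruction_of_euclidean_configuration(self, rng):
        pts = rng.normal(size=(7, 3))
        d = DistanceMatrix([f"s{i}" for i in range(7)], squareform(pdist(pts)))
        res = dv.pcoa(d, k=6)
        rec = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(rec, d.values, atol=1e-9)

    def test_k_bound(self):
        d = DistanceMatrix(list("abc"), np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError):
            dv.pcoa(d, k=3)


class TestPermanova:
    def test_exhaustive_two_by_two(self):
        vals = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float
        )
        d = DistanceMatrix(list("abcd"), vals)
        res = dv.permanova(d, ["g1", "g1", "g2", "g2"], n_perm=999)
        assert res.exhaustive
        assert res.p == pytest.approx(1 / 3)

    def test_equal_distances_r2_identity(self):
        # all pairwise distances equal -> R^2 = (g-1)/(n-1) exactly
        n = 6
        d = DistanceMatrix([f"s{i}" for i in range(n)], np.ones((n, n)) - np.eye(n))
        res = dv.permanova(d, ["a", "a", "b", "b", "c", "c"], n_perm=99, seed=0)
        assert res.r2 == pytest.approx((3 - 1) / (n - 1))

    def test_matches_skbio_pseudo_f(self, rng):
        import skbio

        pts = rng.normal(size=(9, 3))
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(9)]
        labels = ["a"] * 4 + ["b"] * 5
        mine = dv.permanova(DistanceMatrix(ids, d), labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d, ids), grouping=labels, permutations=99
        )
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_no_residual_df_rejected(self):
        d = DistanceMatrix(list("ab"), np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            dv.permanova(d, ["x", "y"], n_perm=9)


class TestMantel:
    def test_identity_gives_r_one_min_p(self, rng):
        pts = rng.normal(size=(8, 2))
        d = DistanceMatrix([f"s{i}" for i in range(8)], squareform(pdist(pts)))
        res = dv.mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_partial_self_control_kills_r(self, rng):
        pts = rng.normal(size=(10, 2))
        d = DistanceMatrix([f"s{i}" for i in range(10)], squareform(pdist(pts)))
        res = dv.mantel(d, d, n_perm=99, seed=0, partial_control=d)
        assert abs(res.r) < 1e-6

    def test_matches_skbio_spearman_r(self, rng):
        import skbio

        ids = [f"s{i}" for i in range(9)]
        d1 = squareform(pdist(rng.normal(size=(9, 2))))
        d2 = squareform(pdist(rng.normal(size=(9, 2))))
        mine = dv.mantel(
            DistanceMatrix(ids, d1), DistanceMatrix(ids, d2), n_perm=99, seed=0
        )
        r_ref, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(d1, ids),
            skbio.DistanceMatrix(d2, ids),
            method="spearman",
            permutations=0,
        )
        assert mine.r == pytest.approx(r_ref, rel=1e-10)

    def test_constant_triangle_rejected(self):
        d1 = DistanceMatrix(list("abcd"), np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError, match="constant"):
            dv.mantel(d1, d1, n_perm=9)


class TestDistanceDecay:
    def test_haversine_one_degree_latitude(self):
        assert dv.haversine_km(39.0, 117.0, 40.0, 117.0) == pytest.approx(
            111.19, abs=0.01
        )

    def test_identical_coordinates_degenerate(self, rng):
        t = random_count_table(rng, n_taxa=8, n_samples=5)
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "group": ["g"] * 5,
                    "latitude": [39.0] * 5,
                    "longitude": [117.5] * 5,
                },
                index=pd.Index(t.sample_ids, name="sample_id"),
            )
        )
        with pytest.raises(ValueError, match="constant"):
            dv.distance_decay(t, meta, n_perm=9)


class TestSimper:
    def test_single_pair_equal_split(self):
        t = CountTable(["x", "y"], ["a", "b"], np.array([[1, 0], [0, 1]]))
        res = dv.simper(t, {"a": "g1", "b": "g2"}, ("g1", "g2"))
        np.testing.assert_allclose(res["contribution"], [0.5, 0.5])
        np.testing.assert_allclose(res["percent"], [50, 50])

    def test_absent_taxon_contributes_zero(self):
        t = CountTable(["x", "y", "z"], ["a", "b"], np.array([[1, 0], [0, 1], [0, 0]]))
        res = dv.simper(t, {"a": "g1", "b": "g2"}, ("g1", "g2"))
        assert res.loc["z", "contribution"] == 0.0

    def test_conservation_identity_random_tables(self, rng):
        # SIMPER contributions must sum to mean between-group Bray-Curtis
        for _ in range(100):
            t = random_count_table(rng, n_taxa=10, n_samples=6, depth=200)
            groups = {s: ("g1" if i < 3 else "g2") for i, s in enumerate(t.sample_ids)}
            res = dv.simper(t, groups, ("g1", "g2"))
            bc = dv.bray_curtis(t).values
            between = bc[:3, 3:].mean()
            assert res["contribution"].sum() == pytest.approx(between, abs=1e-9)

    def test_unknown_group_rejected(self, rng):
        t = random_count_table(rng, n_taxa=5, n_samples=4)
        with pytest.raises(ValueError):
            dv.simper(t, {s: "g1" for s in t.sample_ids}, ("g1", "nope"))


class TestOverlap:
    def test_identical_groups_share_everything(self, rng):
        t = random_count_table(rng, n_taxa=8, n_samples=4, depth=1000)
        t.counts[:, :] = np.maximum(t.counts, 1)
        t = CountTable(t.taxon_ids, t.sample_ids, t.counts)
        res = dv.community_overlap(t, ["a", "a", "b", "b"])
        assert res["shared_fraction"] == pytest.approx(1.0)

    def test_partial_overlap_counts(self):
        # group1 sees {A,B}, group2 sees {B,C}: union 3, intersection {B}
        t = CountTable(
            ["A", "B", "C"],
            ["s1", "s2"],
            np.array([[4, 0], [3, 2], [0, 5]]),
        )
        res = dv.community_overlap(t, ["g1", "g2"])
        assert res["intersections"]["g1&g2"] == 1
        assert res["union_size"] == 3
        assert res["shared_fraction"] == pytest.approx(1 / 3)

    def test_disjoint_groups(self):
        t = CountTable(["A", "B"], ["s1", "s2"], np.array([[4, 0], [0, 5]]))
        res = dv.community_overlap(t, ["g1", "g2"])
        assert res["shared_fraction"] == 0.0


class TestTaxonEnvCorrelation:
    def _meta(self, sample_ids, env):
        return SampleMetadata(
            pd.DataFrame(
                {"group": ["g"] * len(sample_ids), "TDS": env},
                index=pd.Index(sample_ids, name="sample_id"),
            )
        )

    def test_monotone_identity(self):
        env = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        counts = np.vstack([(env * 10).astype(int), np.full(5, 50)])
        t = CountTable(["up", "flat"], [f"s{i}" for i in range(5)], counts)
        res = dv.taxon_env_correlation(t, self._meta(t.sample_ids, env), taxa=["up"])
        assert res["rho"].iloc[0] == pytest.approx(1.0)
        assert res["r2"].iloc[0] > 0.9

    def test_anticorrelated(self):
        env = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        counts = np.vstack([(60 - env * 10).astype(int), np.full(5, 50)])
        t = CountTable(["down", "flat"], [f"s{i}" for i in range(5)], counts)
        res = dv.taxon_env_correlation(t, self._meta(t.sample_ids, env), taxa=["down"])
        assert res["rho"].iloc[0] == pytest.approx(-1.0)

    def test_constant_vector_flagged_not_fatal(self):
        env = np.array([1.0, 2.0, 3.0, 4.0])
        t = CountTable(
            ["flat1", "flat2"], [f"s{i}" for i in range(4)],
            np.vstack([[1, 2, 3, 4], [1, 2, 3, 4]]),
        )
        res = dv.taxon_env_correlation(t, self._meta(t.sample_ids, env))
        flat = res[res["taxon_id"] == "flat1"]
        assert flat["undefined"].all()
        assert np.isnan(flat["rho"]).all()
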