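import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import swabpartition as sp
from swabpartition.stats import DistanceMatrix, enumerate_anosim_p
from swabpartition.tables_io import ValidationError

from conftest import random_count_table


def table_from(values, samples=None, taxa=None, mode="counts"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"S{i}" for i in range(values.shape[0])]
    taxa = taxa or [f"T{j}" for j in range(values.shape[1])]
    return sp.FeatureTable(pd.DataFrame(values, index=samples, columns=taxa), mode)


class TestShannon:
    def test_uniform_is_log_k(self):
        for k in (2, 4, 16):
            assert sp.shannon(np.ones(k)) == pytest.approx(np.log(k))

    def test_single_taxon_zero(self):
        assert sp.shannon([7, 0, 0]) == 0.0

    def test_closed_form_mixture(self):
        assert sp.shannon([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_base_conversion(self):
        assert sp.shannon(np.ones(8), base=2) == pytest.approx(3.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            sp.shannon([0, 0])


class TestBrayCurtis:
    def test_worked_values(self):
        dm = sp.bray_curtis(table_from([[1, 0], [0, 1]]))
        assert dm.values[0, 1] == pytest.approx(1.0)
        dm = sp.bray_curtis(table_from([[3, 4], [3, 4]]))
        assert dm.values[0, 1] == pytest.approx(0.0)
        dm = sp.bray_curtis(table_from([[2, 2], [1, 3]]))
        assert dm.values[0, 1] == pytest.approx(0.25)

    def test_properties_and_taxon_order_invariance(self):
        rng = np.random.default_rng(41)
        table = random_count_table(rng, 6, 12)
        dm = sp.bray_curtis(table)
        assert (dm.values >= 0).all() and (dm.values <= 1).all()
        perm = rng.permutation(table.n_taxa)
        shuffled = sp.FeatureTable(table.data.iloc[:, perm], "counts")
        np.testing.assert_allclose(sp.bray_curtis(shuffled).values, dm.values)

    def test_matches_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.diversity")
        rng = np.random.default_rng(42)
        table = random_count_table(rng, 7, 20)
        ours = sp.bray_curtis(table)
        theirs = skbio_distance.beta_diversity(
            "braycurtis", table.data.to_numpy(), ids=table.sample_ids
        )
        np.testing.assert_allclose(ours.values, theirs.data, atol=1e-12)

    def test_two_all_zero_samples_rejected(self):
        df = pd.DataFrame([[0, 0], [0, 0], [1, 2]],
                          index=["a", "b", "c"], columns=["T1", "T2"])
        with pytest.raises(ValidationError, match="all-zero"):
            sp.bray_curtis(sp.FeatureTable(df, "counts"))


class TestPcoa:
    def test_equilateral_geometry(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        res = sp.pcoa(dm)
        assert len(res.eigenvalues) == 2
        np.testing.assert_allclose(res.eigenvalues[0], res.eigenvalues[1], atol=1e-9)
        coords = res.coordinates.to_numpy()
        for i, j in itertools.combinations(range(3), 2):
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0, abs=1e-9)

    def test_line_reconstruction(self):
        pts = np.array([0.0, 3.0, 4.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = sp.pcoa(DistanceMatrix(["a", "b", "c"], d))
        coords = res.coordinates.to_numpy()
        assert coords.shape[1] == 1
        rec = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_duplicated_sample_coincides(self):
        rng = np.random.default_rng(43)
        table = random_count_table(rng, 5, 8)
        dup = sp.FeatureTable(
            pd.concat([table.data, table.data.iloc[[2]].set_axis(["dup"])]),
            "counts",
        )
        res = sp.pcoa(sp.bray_curtis(dup))
        np.testing.assert_allclose(
            res.coordinates.loc["S2"], res.coordinates.loc["dup"], atol=1e-9
        )

    def test_euclidean_reconstruction_property(self):
        rng = np.random.default_rng(44)
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = sp.pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d))
        coords = res.coordinates.to_numpy()
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(rec, d, atol=1e-6)
        assert res.n_negative_eigenvalues == 0

    def test_matches_scikit_bio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_dm = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(45)
        table = random_count_table(rng, 8, 15)
        dm = sp.bray_curtis(table)
        ours = sp.pcoa(dm)
        theirs = skbio_ord.pcoa(skbio_dm.DistanceMatrix(dm.values, ids=dm.ids))
        k = len(ours.eigenvalues)
        np.testing.assert_allclose(
            ours.eigenvalues, theirs.eigvals.to_numpy()[:k], atol=1e-9
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()[:, :2]),
            np.abs(theirs.samples.to_numpy()[:, :2]),
            atol=1e-6,
        )


class TestWithinGroupSimilarity:
    def test_identical_samples_100(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        out = sp.within_group_similarity(dm, {"a": "g", "b": "g", "c": "g"})
        assert out.loc["g", "mean_pct"] == pytest.approx(100.0)

    def test_fully_dissimilar_zero(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(["a", "b", "c"], d)
        out = sp.within_group_similarity(dm, {"a": "g", "b": "g", "c": "g"})
        assert out.loc["g", "mean_pct"] == pytest.approx(0.0)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(46)
        table = random_count_table(rng, 9, 10)
        dm = sp.bray_curtis(table)
        groups = {s: f"g{i % 3}" for i, s in enumerate(dm.ids)}
        out = sp.within_group_similarity(dm, groups)
        for g in ("g0", "g1", "g2"):
            members = [s for s in dm.ids if groups[s] == g]
            sims = [
                (1 - dm.values[dm.ids.index(a), dm.ids.index(b)]) * 100
                for a, b in itertools.combinations(members, 2)
            ]
            assert out.loc[g, "mean_pct"] == pytest.approx(np.mean(sims))
            assert out.loc[g, "n_pairs"] == len(sims)


class TestAnosim:
    def test_equal_distances_r_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        groups = {f"s{i}": "a" if i < 3 else "b" for i in range(6)}
        res = sp.anosim(dm, groups, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation_r_one(self):
        # between-group distances all exceed within-group distances
        d = np.full((6, 6), 0.2)
        d[:3, 3:] = 0.9
        d[3:, :3] = 0.9
        rng = np.random.default_rng(0)
        jitter = rng.uniform(0, 0.01, size=(6, 6))
        d = d + (jitter + jitter.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        groups = {f"s{i}": "a" if i < 3 else "b" for i in range(6)}
        res = sp.anosim(dm, groups, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_permutation_p_matches_enumeration(self):
        rng = np.random.default_rng(47)
        table = random_count_table(rng, 6, 8)
        dm = sp.bray_curtis(table)
        groups = {s: "a" if i < 3 else "b" for i, s in enumerate(dm.ids)}
        p_exact = enumerate_anosim_p(dm, groups)
        res = sp.anosim(dm, groups, n_permutations=10_000, seed=1)
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p_value - p_exact) < 3 * mc_se + 2e-4

    def test_statistic_matches_scikit_bio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(48)
        table = random_count_table(rng, 8, 10)
        dm = sp.bray_curtis(table)
        grouping = ["a", "a", "a", "a", "b", "b", "b", "b"]
        ours = sp.anosim(dm, dict(zip(dm.ids, grouping)), 99, seed=0)
        theirs = skbio_dist.anosim(
            skbio_dist.DistanceMatrix(dm.values, ids=dm.ids),
            grouping=grouping, permutations=99,
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_single_group_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("abcd"), d)
        with pytest.raises(ValidationError, match="2 groups"):
            sp.anosim(dm, {s: "g" for s in "abcd"}, 99, 0)


class TestMantel:
    def _random_dm(self, rng, n=5):
        table = random_count_table(rng, n, 10)
        return sp.bray_curtis(table)

    def test_identity_r_one(self):
        dm = self._random_dm(np.random.default_rng(49))
        res = sp.mantel(dm, dm, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_affine_invariance_pearson(self):
        dm1 = self._random_dm(np.random.default_rng(50))
        v = 0.05 + 0.5 * dm1.values
        np.fill_diagonal(v, 0.0)
        dm2 = DistanceMatrix(dm1.ids, v)
        res = sp.mantel(dm1, dm2, "pearson", 99, 0)
        assert res.statistic == pytest.approx(1.0)

    def test_permutation_p_matches_full_enumeration(self):
        rng = np.random.default_rng(51)
        dm1 = self._random_dm(rng, n=5)
        dm2 = self._random_dm(rng, n=5)
        dm2 = DistanceMatrix(dm1.ids, dm2.values)
        iu = np.triu_indices(5, k=1)
        x = dm1.values[iu]

        def corr(y):
            return np.corrcoef(x, y)[0, 1]

        r_obs = corr(dm2.values[iu])
        hits = total = 0
        for perm in itertools.permutations(range(5)):
            y = dm2.values[np.ix_(perm, perm)][iu]
            total += 1
            if corr(y) >= r_obs - 1e-12:
                hits += 1
        p_exact = hits / total
        res = sp.mantel(dm1, dm2, "pearson", 10_000, seed=2)
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p_value - p_exact) < 3 * mc_se + 2e-3

    def test_statistic_matches_scikit_bio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(52)
        dm1 = self._random_dm(rng, n=8)
        dm2 = DistanceMatrix(dm1.ids, self._random_dm(rng, n=8).values)
        ours = sp.mantel(dm1, dm2, "pearson", 99, 0)
        r_skbio, _, _ = skbio_dist.mantel(
            skbio_dist.DistanceMatrix(dm1.values, ids=dm1.ids),
            skbio_dist.DistanceMatrix(dm2.values, ids=dm2.ids),
            method="pearson", permutations=0,
        )
        assert ours.statistic == pytest.approx(float(r_skbio), abs=1e-12)

    def test_id_mismatch_rejected(self):
        dm1 = self._random_dm(np.random.default_rng(53))
        dm2 = DistanceMatrix([f"x{i}" for i in range(5)], dm1.values)
        with pytest.raises(ValidationError, match="different sample sets"):
            sp.mantel(dm1, dm2)


class TestMatchedSpearman:
    def _pair(self):
        a = table_from(
            [[0.5, 0.2, 0.2, 0.1], [0.4, 0.3, 0.2, 0.1], [0.25, 0.25, 0.25, 0.25]],
            samples=["a1", "a2", "a3"], mode="relative",
        )
        return a

    def test_identity_r_one(self):
        a = self._pair()
        r, _ = sp.matched_abundance_spearman(a, a, {s: s for s in a.sample_ids})
        assert r == pytest.approx(1.0)

    def test_monotone_transform_r_one(self):
        a = self._pair()
        b = sp.FeatureTable(a.data * 0.5 + 0.01, "counts")  # monotone map
        r, _ = sp.matched_abundance_spearman(a, b, {s: s for s in a.sample_ids})
        assert r == pytest.approx(1.0)

    def test_matches_hand_ranked_oracle(self):
        rng = np.random.default_rng(54)
        a_vals = rng.uniform(size=(3, 4))
        b_vals = rng.uniform(size=(3, 4))
        a = table_from(a_vals, samples=["a1", "a2", "a3"], mode="counts")
        b = table_from(b_vals, samples=["b1", "b2", "b3"], mode="counts")
        pairing = {"a1": "b2", "a2": "b3", "a3": "b1"}
        r, _ = sp.matched_abundance_spearman(a, b, pairing)
        x = a.data.loc[["a1", "a2", "a3"]].to_numpy().ravel()
        y = b.data.loc[["b2", "b3", "b1"]].to_numpy().ravel()
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(expected)

    def test_no_matches_rejected(self):
        a = self._pair()
        with pytest.raises(ValidationError, match="no matched samples"):
            sp.matched_abundance_spearman(a, a, {"zz": "yy"})


class TestPerTaxonSpearman:
    def test_constant_taxon_undefined(self):
        a = table_from([[1, 5], [1, 7], [1, 2]], mode="counts")
        b = table_from([[2, 1], [3, 6], [4, 3]], mode="counts")
        pairing = {s: s for s in a.sample_ids}
        per, mean_r = sp.per_taxon_spearman(a, b, pairing)
        assert np.isnan(per["T0"])
        assert not np.isnan(per["T1"])

    def test_identity_all_one(self):
        rng = np.random.default_rng(55)
        a = random_count_table(rng, 5, 6)
        per, mean_r = sp.per_taxon_spearman(a, a, {s: s for s in a.sample_ids})
        defined = per.dropna()
        np.testing.assert_allclose(defined, 1.0)
        assert mean_r == pytest.approx(1.0)

    def test_matches_per_taxon_loop(self):
        rng = np.random.default_rng(56)
        a = random_count_table(rng, 6, 8)
        b = random_count_table(rng, 6, 8)
        pairing = {s: s for s in a.sample_ids}
        per, _ = sp.per_taxon_spearman(a, b, pairing)
        for t in a.taxon_ids:
            x, y = a.data[t].to_numpy(), b.data[t].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                assert np.isnan(per[t])
            else:
                assert per[t] == pytest.approx(sps.spearmanr(x, y)[0])


class TestKruskalWallisDunn:
    def test_maximal_separation_closed_form(self):
        res = sp.kruskal_wallis_dunn([1, 2, 3, 10, 11, 12], list("aaabbb"))
        # ranks 1..6, mean ranks 2 and 5, no ties:
        # H = 12/(6*7) * (3*4 + 3*25) - 3*7 = 12/42*87 - 21
        assert res.h_statistic == pytest.approx(12 / 42 * 87 - 21)

    def test_h_matches_scipy_with_ties(self):
        rng = np.random.default_rng(57)
        values = rng.integers(0, 6, size=24).astype(float)
        groups = np.repeat(["a", "b", "c"], 8)
        res = sp.kruskal_wallis_dunn(values, groups)
        h_scipy, p_scipy = sps.kruskal(*(values[groups == g] for g in "abc"))
        assert res.h_statistic == pytest.approx(h_scipy)
        assert res.p_value == pytest.approx(p_scipy)

    def test_pairwise_adjustment_properties(self):
        rng = np.random.default_rng(58)
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        res = sp.kruskal_wallis_dunn(values, groups)
        assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-15).all()
        assert (res.pairwise["p_adj"] <= 1.0).all()

    def test_all_tied_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            sp.kruskal_wallis_dunn([1, 1, 1, 1], ["a", "a", "b", "b"])


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            sp.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_monotone_in_raw_p_order(self):
        rng = np.random.default_rng(59)
        p = rng.uniform(size=40)
        adj = sp.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(60)
        p = rng.uniform(size=25)
        np.testing.assert_allclose(
            sp.bh_adjust(p), sm.multipletests(p, method="fdr_bh")[1]
        )


class TestDiversityGrowthCorrelation:
    def test_monotone_relation_r_one(self):
        h = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                      index=[f"A{i}" for i in range(5)])
        growth = pd.DataFrame({"weight": np.exp(h.to_numpy())}, index=h.index)
        r, p = sp.diversity_growth_correlation(h, growth)
        assert r.loc["shannon", "weight"] == pytest.approx(1.0)

    def test_matches_hand_ranked_instance(self):
        h = pd.Series([0.3, 0.9, 0.1, 0.7, 0.5],
                      index=[f"A{i}" for i in range(5)])
        growth = pd.DataFrame(
            {"weight": [2.0, 1.0, 5.0, 3.0, 4.0]}, index=h.index
        )
        r, p = sp.diversity_growth_correlation(h, growth)
        expected = sps.spearmanr(h, growth["weight"])
        assert r.loc["shannon", "weight"] == pytest.approx(expected[0])
        assert p.loc["shannon", "weight"] == pytest.approx(expected[1])

    def test_insufficient_pairs_missing(self):
        h = pd.Series([1.0, 2.0, 3.0], index=["A0", "A1", "A2"])
        growth = pd.DataFrame({"weight": [1.0, 2.0, 3.0]}, index=h.index)
        r, _ = sp.diversity_growth_correlation(h, growth, min_pairs=4)
        assert np.isnan(r.loc["shannon", "weight"])
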