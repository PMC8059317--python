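import numpy as np
import pandas as pd
import pytest

import swabpartition as sp
from swabpartition.partition import PartitionParams
from swabpartition.tables_io import ValidationError


def rel_table(values, samples, taxa) -> sp.FeatureTable:
    df = pd.DataFrame(values, index=samples, columns=taxa, dtype=float)
    df = df.div(df.sum(axis=1), axis=0)
    return sp.FeatureTable(df, "relative")


def meta_for(samples, methods) -> sp.SampleMetadata:
    return sp.SampleMetadata(
        pd.DataFrame(
            {
                "animal_id": [f"A{i}" for i in range(len(samples))],
                "day": [140] * len(samples),
                "method": methods,
                "weaning_group": ["earlyC"] * len(samples),
            },
            index=samples,
        )
    )


def brute_force_labels(pct: pd.DataFrame, methods: pd.Series,
                       oral_pp=1.0, rare_pct=1.0, rule="max_difference"):
    """Independent re-evaluation of the filtering rule, taxon by taxon."""
    labels = {}
    for taxon in pct.columns:
        col = pct[taxon]
        max_bs = col[methods == "BS"].max()
        max_r = col[methods == "R"].max()
        if col.max() < rare_pct:
            labels[taxon] = "rare"
        elif rule == "max_difference" and max_bs - max_r >= oral_pp:
            labels[taxon] = "oral_specific"
        elif rule == "bs_exceeds_any_r" and max_bs >= oral_pp and max_bs > max_r:
            labels[taxon] = "oral_specific"
        else:
            labels[taxon] = "rumen_specific"
    return labels


class TestClassifyTaxa:
    def _three_genus_case(self):
        # g_rare: < 1% everywhere; g_oral: 5% BS vs 0% R; g_rumen: 0.5% BS, 30% R
        samples = ["B1", "B2", "R1"]
        values = pd.DataFrame(
            {
                "g_rare": [0.008, 0.005, 0.002],
                "g_oral": [0.05, 0.03, 0.0],
                "g_rumen": [0.005, 0.004, 0.30],
                "filler": [0.937, 0.961, 0.698],
            },
            index=samples,
        )
        table = sp.FeatureTable(values, "relative")
        return table, meta_for(samples, ["BS", "BS", "R"])

    def test_rule_forced_labels(self):
        table, meta = self._three_genus_case()
        part = sp.classify_taxa(table, meta)
        assert part.genus.loc["g_rare", "label"] == "rare"
        assert part.genus.loc["g_oral", "label"] == "oral_specific"
        assert part.genus.loc["g_rumen", "label"] == "rumen_specific"

    def test_no_r_samples_rejected(self):
        table, _ = self._three_genus_case()
        meta = meta_for(table.sample_ids, ["BS", "BS", "BS"])
        with pytest.raises(ValidationError, match="stomach-tube"):
            sp.classify_taxa(table, meta)

    @pytest.mark.parametrize("rule", ["max_difference", "bs_exceeds_any_r"])
    def test_matches_brute_force_on_random_tables(self, rule):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n_s, n_t = int(rng.integers(4, 9)), int(rng.integers(3, 10))
            samples = [f"S{i}" for i in range(n_s)]
            methods = ["R" if i < 2 else "BS" for i in range(n_s)]
            raw = rng.dirichlet(np.full(n_t, 0.3), size=n_s)
            table = sp.FeatureTable(
                pd.DataFrame(raw, index=samples,
                             columns=[f"G{j}" for j in range(n_t)]),
                "relative",
            )
            part = sp.classify_taxa(
                table, meta_for(samples, methods),
                PartitionParams(oral_rule=rule),
            )
            expected = brute_force_labels(
                table.data * 100,
                pd.Series(methods, index=samples), rule=rule,
            )
            assert part.genus["label"].to_dict() == expected

    def test_sample_order_and_duplication_invariance(self):
        table, meta = self._three_genus_case()
        base = sp.classify_taxa(table, meta).genus["label"]
        shuffled = sp.FeatureTable(table.data.iloc[[2, 0, 1]], "relative")
        assert sp.classify_taxa(shuffled, meta).genus["label"].equals(base)
        dup = sp.FeatureTable(
            pd.concat([table.data, table.data.iloc[[0]].set_axis(["B1b"])]),
            "relative",
        )
        meta_dup = meta_for(dup.sample_ids, ["BS", "BS", "R", "BS"])
        assert sp.classify_taxa(dup, meta_dup).genus["label"].equals(base)

    def test_oral_cutoff_monotonicity(self):
        rng = np.random.default_rng(32)
        samples = [f"S{i}" for i in range(6)]
        methods = ["R", "R", "BS", "BS", "BS", "BS"]
        raw = rng.dirichlet(np.full(8, 0.5), size=6)
        table = sp.FeatureTable(
            pd.DataFrame(raw, index=samples, columns=[f"G{j}" for j in range(8)]),
            "relative",
        )
        meta = meta_for(samples, methods)
        previous = None
        for cutoff in (0.5, 1.0, 2.0, 5.0):
            part = sp.classify_taxa(table, meta, PartitionParams(oral_cutoff_pp=cutoff))
            oral = set(part.genera_with("oral_specific"))
            if previous is not None:
                assert oral <= previous
            previous = oral


class TestPropagateToOtus:
    def test_counts_partition_all_otus(self, small_partitioned):
        part = small_partitioned["partition"]
        s = part.summary
        assert (
            s["n_oral_otus"] + s["n_rumen_otus"] + s["n_rare_otus"]
            == len(part.otu)
        )
        # labels inherited from the genus
        for otu, row in part.otu.sample(20, random_state=0).iterrows():
            assert row["label"] == part.genus.loc[row["genus"], "label"]

    def test_missing_genus_rejected(self, small_partitioned):
        part = small_partitioned["partition"]
        tax = small_partitioned["tax"]
        orphan = tax.data.iloc[[0]].copy()
        orphan["genus"] = "g_not_in_partition"
        with pytest.raises(ValidationError, match="absent from the partition"):
            sp.propagate_to_otus(part, sp.TaxonomyTable(orphan))


class TestSubsetRenormalize:
    def test_worked_example(self):
        samples = ["B1", "R1"]
        table = sp.FeatureTable(
            pd.DataFrame(
                {"g1": [0.2, 0.3], "g2": [0.3, 0.4], "g3": [0.5, 0.3]},
                index=samples,
            ),
            "relative",
        )
        part = sp.classify_taxa(table, meta_for(samples, ["BS", "R"]))
        part.genus.loc[:, "label"] = ["rumen_specific", "rumen_specific", "oral_specific"]
        out = sp.subset_renormalize(table, part, "rumen_specific")
        np.testing.assert_allclose(out.data.loc["B1"], [0.4, 0.6])

    def test_rows_sum_to_one_random(self, small_partitioned):
        out = sp.subset_renormalize(
            small_partitioned["genus_rel"],
            small_partitioned["partition"],
            "rumen_specific",
        )
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_label_rejected(self, small_partitioned):
        with pytest.raises(ValidationError, match="unknown label"):
            sp.subset_renormalize(
                small_partitioned["genus_rel"],
                small_partitioned["partition"],
                "bogus",
            )


class TestOralFraction:
    def test_zero_when_no_oral_taxa_in_sample(self):
        samples = ["B1", "R1"]
        table = sp.FeatureTable(
            pd.DataFrame({"g1": [0.5, 0.5], "g2": [0.5, 0.5]}, index=samples),
            "relative",
        )
        part = sp.classify_taxa(table, meta_for(samples, ["BS", "R"]))
        part.genus.loc[:, "label"] = "rumen_specific"
        frac = sp.oral_fraction_per_sample(table, part)
        assert (frac == 0).all()

    def test_summation_example(self):
        samples = ["B1", "R1"]
        table = sp.FeatureTable(
            pd.DataFrame(
                {"o1": [0.30, 0.0], "o2": [0.06, 0.0], "r1": [0.64, 1.0]},
                index=samples,
            ),
            "relative",
        )
        part = sp.classify_taxa(table, meta_for(samples, ["BS", "R"]))
        part.genus.loc[:, "label"] = ["oral_specific", "oral_specific", "rumen_specific"]
        frac = sp.oral_fraction_per_sample(table, part)
        assert frac["B1"] == pytest.approx(36.0)

    def test_tracks_true_carryover(self, small_partitioned):
        from scipy.stats import spearmanr

        genus_rel = small_partitioned["genus_rel"]
        meta = small_partitioned["meta"]
        truth = small_partitioned["truth"]
        frac = sp.oral_fraction_per_sample(genus_rel, small_partitioned["partition"])
        bs = meta.data.loc[frac.index, "method"] == "BS"
        lam = truth.sample_lambda.reindex(frac.index)
        rho = spearmanr(frac[bs], 1.0 - lam[bs])[0]
        assert rho > 0.9


class TestCoreOtus:
    def _presence_table(self, rng, n_samples=12, n_taxa=20):
        values = (rng.uniform(size=(n_samples, n_taxa)) < 0.6).astype(int) * (
            1 + rng.integers(0, 5, size=(n_samples, n_taxa))
        )
        samples = [f"S{i}" for i in range(n_samples)]
        table = sp.FeatureTable(
            pd.DataFrame(values + (values.sum(axis=1, keepdims=True) == 0),
                         index=samples, columns=[f"T{j}" for j in range(n_taxa)]),
            "counts",
        )
        days = [42, 70, 98, 112] * 3
        meta = sp.SampleMetadata(
            pd.DataFrame(
                {
                    "animal_id": [f"A{i}" for i in range(n_samples)],
                    "day": days,
                    "method": ["BS"] * n_samples,
                    "weaning_group": ["earlyC"] * n_samples,
                },
                index=samples,
            )
        )
        return table, meta

    def test_matches_brute_force(self):
        rng = np.random.default_rng(33)
        table, meta = self._presence_table(rng)
        groups = [(42, "BS"), (70, "BS"), (98, "BS"), (112, "BS")]
        core = sp.core_otus(table, meta, groups)
        expected = set(table.taxon_ids)
        for day, method in groups:
            sids = meta.samples_where(day=day, method=method)
            present = {
                t for t in table.taxon_ids if (table.data.loc[sids, t] > 0).any()
            }
            expected &= present
        assert core.core_otus == expected

    def test_absent_from_one_group_not_core(self):
        rng = np.random.default_rng(34)
        table, meta = self._presence_table(rng)
        values = table.data.copy()
        target = values.columns[0]
        values.loc[meta.samples_where(day=98, method="BS"), target] = 0
        values.iloc[:, 1] = 1  # keep a taxon in all groups
        table2 = sp.FeatureTable(values, "counts")
        core = sp.core_otus(table2, meta, [(42, "BS"), (70, "BS"), (98, "BS")])
        assert target not in core.core_otus
        assert values.columns[1] in core.core_otus

    def test_missing_group_named(self):
        rng = np.random.default_rng(35)
        table, meta = self._presence_table(rng)
        with pytest.raises(ValidationError, match="day=140"):
            sp.core_otus(table, meta, [(140, "R")])
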