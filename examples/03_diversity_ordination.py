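"""Alpha and beta diversity of the rumen-specific fraction.

After removing oral-specific taxa and renormalizing, the rumen-specific
(RS) community in buccal swabs shows the age signal of the developing
rumen: Shannon diversity rises with age and animals become more alike
(higher within-group similarity).
"""

import pandas as pd

import swabpartition as sp
from swabpartition.tables_io import TaxonomyTable

table, tax, meta, _ = sp.simulate_study(sp.SimulationDesign(n_animals=12), seed=42)
counts = sp.drop_low_abundance_otus(sp.drop_low_read_samples(table, 5000), 0.002)
tax_f = TaxonomyTable(sp.apply_confidence_thresholds(tax).data.loc[counts.taxon_ids])
rel = sp.tss_normalize(counts)
genus_rel = sp.aggregate_to_rank(rel, tax_f, "genus")
part = sp.propagate_to_otus(sp.classify_taxa(genus_rel, meta), tax_f)

# rarefied Shannon on the RS OTU counts
rs_otus = [t for t in part.otus_with("rumen_specific") if t in counts.data.columns]
rs_counts = sp.FeatureTable(counts.data.loc[:, rs_otus], "counts")
depth = int(rs_counts.sample_totals().min())
rarefied = sp.rarefy(rs_counts, depth, seed=0)
h = pd.Series({s: sp.shannon(row.to_numpy()) for s, row in rarefied.data.iterrows()})
bs = meta.data.loc[h.index, "method"] == "BS"
print(f"rarefaction depth: {depth} reads")
print("mean RS Shannon (nats) by day, buccal swabs:")
print(h[bs].groupby(meta.data.loc[h.index, "day"][bs]).mean().round(2).to_string())

# ordination and within-group similarity of the renormalized RS fraction
rs_rel = sp.subset_renormalize(rel, part, "rumen_specific")
dm = sp.bray_curtis(rs_rel)
ordination = sp.pcoa(dm, k=2)
print("PCoA axes 1-2 explain "
      f"{100 * ordination.proportion_explained[:2].sum():.0f}% "
      "of the positive-eigenvalue variance")

groups = meta.data.loc[dm.ids, "day"].map("day{}".format)
wgs = sp.within_group_similarity(dm, groups)
print("within-day similarity (mean % of 1 - Bray-Curtis):")
print(wgs["mean_pct"].round(1).to_string())
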