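"""Partition genus-level taxa into oral-specific / rumen-specific / rare.

The "mathematical filtering" rule: a genus whose maximum relative
abundance in buccal swabs exceeds its maximum in any stomach-tube sample
by >= 1 percentage point is oral-specific; a genus below 1% everywhere is
rare; everything else is rumen-specific.
"""

import swabpartition as sp
from swabpartition.tables_io import TaxonomyTable

table, tax, meta, truth = sp.simulate_study(sp.SimulationDesign(n_animals=12), seed=42)

# the fixed preprocessing order
counts = sp.drop_low_read_samples(table, 5000)
counts = sp.drop_low_abundance_otus(counts, 0.002)
tax_f = sp.apply_confidence_thresholds(tax)
tax_f = TaxonomyTable(tax_f.data.loc[counts.taxon_ids])
rel = sp.tss_normalize(counts)
genus_rel = sp.aggregate_to_rank(rel, tax_f, "genus")

part = sp.classify_taxa(genus_rel, meta)
part = sp.propagate_to_otus(part, tax_f)
print("partition:", part.summary)

frac = sp.oral_fraction_per_sample(genus_rel, part)
bs = meta.data.loc[frac.index, "method"] == "BS"
by_day = frac[bs].groupby(meta.data.loc[frac.index, "day"][bs]).mean()
print("mean oral fraction of the BS community by day (%):")
print(by_day.round(1).to_string())

labels = part.genus["label"]
named = [g for g in labels.index if g in truth.genus_origin.index
         and truth.genus_detectable.get(g, False)]
oral_ok = sum(labels[g] == "oral_specific" for g in named
              if truth.genus_origin[g] == "oral")
n_oral = sum(truth.genus_origin[g] == "oral" for g in named)
print(f"recovered {oral_ok}/{n_oral} true oral genera as oral-specific")
# A high oral fraction in young calves' swabs is expected: little rumen
# content is regurgitated before the rumen develops.
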