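import numpy as np
import pandas as pd
import pytest

import swabpartition as sp
from swabpartition.tables_io import TaxonomyTable


@pytest.fixture(scope="session")
def small_design() -> sp.SimulationDesign:
    """A scaled-down study: 10 animals, modest genus pools."""
    return sp.SimulationDesign(
        n_animals=10,
        n_oral_genera=25,
        n_rumen_genera=12,
        n_rare_genera=10,
        oral_otus_per_genus_mean=4.0,
        rumen_otus_per_genus_mean=10.0,
        depth_mean=8000.0,
    )


@pytest.fixture(scope="session")
def small_study(small_design):
    return sp.simulate_study(small_design, seed=7)


@pytest.fixture(scope="session")
def small_partitioned(small_study):
    """Preprocessed and partitioned small study, shared across tests."""
    table, tax, meta, truth = small_study
    counts = sp.drop_low_abundance_otus(sp.drop_low_read_samples(table, 5000))
    tax_f = sp.apply_confidence_thresholds(tax)
    tax_f = TaxonomyTable(tax_f.data.loc[counts.taxon_ids])
    rel = sp.tss_normalize(counts)
    genus_rel = sp.aggregate_to_rank(rel, tax_f, "genus")
    part = sp.propagate_to_otus(sp.classify_taxa(genus_rel, meta), tax_f)
    return {
        "counts": counts,
        "tax": tax_f,
        "rel": rel,
        "genus_rel": genus_rel,
        "meta": meta,
        "truth": truth,
        "partition": part,
    }


def random_count_table(rng: np.random.Generator, n_samples=6, n_taxa=12,
                       scale=200) -> sp.FeatureTable:
    values = rng.integers(0, scale, size=(n_samples, n_taxa))
    values[:, 0] += 1  # guard against all-zero samples
    return sp.FeatureTable(
        pd.DataFrame(
            values,
            index=[f"S{i}" for i in range(n_samples)],
            columns=[f"T{j}" for j in range(n_taxa)],
        ),
        "counts",
    )
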