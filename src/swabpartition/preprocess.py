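"""Quality filtering, taxonomy relabelling, normalization and rarefaction.

The fixed preprocessing order for amplicon feature tables is:

1. :func:`drop_low_read_samples` — discard samples with fewer than 5000
   reads (strict ``<``).
2. :func:`drop_low_abundance_otus` — discard OTUs that never exceed 0.2%
   within-sample relative abundance.
3. :func:`apply_confidence_thresholds` — relabel taxonomic assignments whose
   classifier confidence falls below rank-specific cut-offs (genus 94.5%,
   family 86.5%, order 82.0%, class 78.5%, phylum 75.0%) to
   ``unclassified <deepest retained ancestor>``.
4. :func:`tss_normalize` (for composition analyses) or :func:`rarefy`
   (for alpha diversity).

:func:`aggregate_to_rank` collapses OTUs to genus-level (or any rank) taxa
after the taxonomy has been confidence-filtered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import RANKS, FeatureTable, TaxonomyTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessParams",
    "DEFAULT_CONFIDENCE_THRESHOLDS",
    "drop_low_read_samples",
    "drop_low_abundance_otus",
    "apply_confidence_thresholds",
    "tss_normalize",
    "rarefy",
    "aggregate_to_rank",
]

#: Rank-specific classifier confidence cut-offs (retain iff confidence >= cut-off).
DEFAULT_CONFIDENCE_THRESHOLDS = {
    "phylum": 0.750,
    "class": 0.785,
    "order": 0.820,
    "family": 0.865,
    "genus": 0.945,
}


@dataclass
class PreprocessParams:
    """Tunable parameters of the preprocessing stage.

    ``rarefaction_depth`` may be a positive integer or the string
    ``"auto-min"`` (use the smallest sample total after filtering).
    """

    min_sample_reads: int = 5000
    low_abundance_frac: float = 0.002
    rank_confidence_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_CONFIDENCE_THRESHOLDS)
    )
    rarefaction_depth: int | str = "auto-min"
    rarefaction_seed: int = 0
    per_sample_low_abundance: bool = False

    def __post_init__(self) -> None:
        if self.min_sample_reads < 1:
            raise ValidationError("min_sample_reads must be >= 1")
        if not 0 <= self.low_abundance_frac <= 1:
            raise ValidationError("low_abundance_frac must be in [0, 1]")
        for rank, t in self.rank_confidence_thresholds.items():
            if rank not in RANKS:
                raise ValidationError(f"unknown rank {rank!r} in thresholds")
            if not 0 <= t <= 1:
                raise ValidationError(f"threshold for {rank!r} outside [0, 1]")
        if isinstance(self.rarefaction_depth, str):
            if self.rarefaction_depth != "auto-min":
                raise ValidationError(
                    "rarefaction_depth must be a positive integer or 'auto-min'"
                )
        elif self.rarefaction_depth <= 0:
            raise ValidationError("rarefaction_depth must be positive")


def _require_counts(table: FeatureTable, op: str) -> None:
    if table.mode != "counts":
        raise ValidationError(f"{op} requires a counts table, got mode={table.mode!r}")


def drop_low_read_samples(table: FeatureTable, min_sample_reads: int = 5000) -> FeatureTable:
    """Remove samples whose read total is strictly below ``min_sample_reads``."""
    _require_counts(table, "drop_low_read_samples")
    totals = table.sample_totals()
    keep = totals >= min_sample_reads
    if not keep.any():
        raise ValidationError(
            f"all {table.n_samples} samples below {min_sample_reads} reads"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("drop_low_read_samples: removed %d sample(s)", dropped)
    return FeatureTable(table.data.loc[keep], "counts")


def drop_low_abundance_otus(
    table: FeatureTable,
    low_abundance_frac: float = 0.002,
    per_sample: bool = False,
) -> FeatureTable:
    """Remove low-abundance OTUs (<= ``low_abundance_frac`` of sample reads).

    Default semantics (``per_sample=False``): an OTU is removed *globally*
    iff its within-sample relative abundance is <= the threshold in every
    sample; counts of retained OTUs are untouched.  With ``per_sample=True``
    the alternative reading is applied: counts at or below the threshold are
    zeroed sample-by-sample and OTUs left with no reads are dropped.
    """
    _require_counts(table, "drop_low_abundance_otus")
    totals = table.sample_totals().to_numpy()[:, None]
    if (totals == 0).any():
        raise ValidationError("zero-total sample; drop low-read samples first")
    rel = table.data.to_numpy() / totals
    if per_sample:
        values = table.data.to_numpy().copy()
        values[rel <= low_abundance_frac] = 0
        keep = values.sum(axis=0) > 0
        if not keep.any():
            raise ValidationError("no OTUs survive the low-abundance filter")
        df = pd.DataFrame(
            values[:, keep], index=table.data.index, columns=table.data.columns[keep]
        )
        return FeatureTable(df, "counts")
    keep = (rel > low_abundance_frac).any(axis=0)
    if not keep.any():
        raise ValidationError("no OTUs survive the low-abundance filter")
    removed = int((~keep).sum())
    if removed:
        logger.info("drop_low_abundance_otus: removed %d OTU(s)", removed)
    return FeatureTable(table.data.loc[:, keep], "counts")


def apply_confidence_thresholds(
    tax: TaxonomyTable, rank_confidence_thresholds: dict | None = None
) -> TaxonomyTable:
    """Relabel assignments below their rank's confidence cut-off.

    For each taxon the lineage is walked from phylum to genus; the first
    rank whose assignment is missing or has confidence strictly below the
    rank's threshold breaks the lineage, and that rank and all deeper ranks
    are relabelled ``unclassified <deepest retained ancestor>`` (root
    fallback: ``unclassified Bacteria``).  Relabelled entries carry
    confidence 1.0, making the operation idempotent.
    """
    thresholds = dict(DEFAULT_CONFIDENCE_THRESHOLDS)
    if rank_confidence_thresholds:
        thresholds.update(rank_confidence_thresholds)
    df = tax.data.copy()
    names = {r: df[r].to_numpy(dtype=object) for r in RANKS}
    confs = {r: df[f"{r}_conf"].to_numpy(dtype=float) for r in RANKS}
    n = len(df)
    for i in range(n):
        anchor = "Bacteria"
        broken = False
        for rank in RANKS:
            name = names[rank][i]
            conf = confs[rank][i]
            if not broken:
                missing = name is None or (isinstance(name, float) and np.isnan(name))
                if missing or conf < thresholds[rank]:
                    broken = True
                else:
                    anchor = str(name)
                    continue
            names[rank][i] = f"unclassified {anchor}"
            confs[rank][i] = 1.0
    for rank in RANKS:
        df[rank] = names[rank]
        df[f"{rank}_conf"] = confs[rank]
    return TaxonomyTable(df)


def tss_normalize(table: FeatureTable) -> FeatureTable:
    """Total-sum scaling: divide each sample's counts by its read total."""
    _require_counts(table, "tss_normalize")
    totals = table.sample_totals()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(f"zero-total sample {zero.index[0]!r}")
    rel = table.data.div(totals, axis=0)
    return FeatureTable(rel, "relative")


def rarefy(table: FeatureTable, depth: int, seed: int = 0) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    The draw is multivariate hypergeometric (a single draw per sample, no
    averaging over repetitions) and fully reproducible given ``seed``.
    Samples with totals below ``depth`` are dropped with a warning.
    """
    _require_counts(table, "rarefy")
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    counts = np.rint(table.data.to_numpy()).astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    if (~keep).any():
        dropped = list(table.data.index[~keep])
        warnings.warn(
            f"rarefy: dropping {len(dropped)} sample(s) below depth {depth}: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    j = 0
    for i in np.flatnonzero(keep):
        if totals[i] == depth:
            out[j] = counts[i]
        else:
            out[j] = rng.multivariate_hypergeometric(counts[i], depth)
        j += 1
    df = pd.DataFrame(out, index=table.data.index[keep], columns=table.data.columns)
    return FeatureTable(df, "counts")


def aggregate_to_rank(table: FeatureTable, tax: TaxonomyTable, rank: str) -> FeatureTable:
    """Sum OTU abundances sharing the same label at ``rank``.

    Labels may be proper names or ``unclassified <parent>`` placeholders
    produced by :func:`apply_confidence_thresholds`; OTUs with no row in the
    taxonomy are rejected.  Sample totals are conserved.
    """
    labels = tax.labels_at(rank)
    missing = [t for t in table.taxon_ids if t not in labels.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} taxa missing from taxonomy, e.g. {missing[0]!r}"
        )
    grouped = table.data.T.groupby(labels.loc[table.taxon_ids]).sum().T
    grouped.columns.name = None
    return FeatureTable(grouped, table.mode)
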