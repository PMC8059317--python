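"""Oral / rumen compartment partitioning of buccal-swab communities.

Buccal swabs (BS) of ruminants capture a mixture of resident oral microbes
and rumen content carried over by regurgitation.  Given stomach-tube rumen
samples (R) as the reference compartment, genus-level taxa are partitioned
by a deterministic threshold rule ("mathematical filtering"):

* **rare** — maximum relative abundance below 1% in *every* sample (BS and
  R); excluded before the oral/rumen decision.
* **oral-specific (OS)** — non-rare genus whose maximum relative abundance
  in BS samples exceeds its maximum in any R sample by at least 1
  percentage point (default rule ``max_difference``; the alternative
  ``bs_exceeds_any_r`` requires max_BS >= cut-off and max_BS > max_R).
* **rumen-specific (RS)** — everything else.

OTUs inherit the label of their genus.  The RS (or OS) sub-table is then
renormalized to 100% per sample, and the core rumen microbiome is the
intersection of per-group OTU presence sets over chosen day x method
groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import FeatureTable, SampleMetadata, TaxonomyTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PartitionParams",
    "PartitionResult",
    "CoreSet",
    "LABELS",
    "classify_taxa",
    "propagate_to_otus",
    "subset_renormalize",
    "oral_fraction_per_sample",
    "core_otus",
]

LABELS = ("oral_specific", "rumen_specific", "rare")


@dataclass
class PartitionParams:
    """Thresholds of the filtering rule, on the percent scale."""

    oral_cutoff_pp: float = 1.0
    rare_cutoff_pct: float = 1.0
    oral_rule: str = "max_difference"

    def __post_init__(self) -> None:
        if self.oral_cutoff_pp <= 0:
            raise ValidationError("oral_cutoff_pp must be > 0")
        if self.rare_cutoff_pct <= 0:
            raise ValidationError("rare_cutoff_pct must be > 0")
        if self.oral_rule not in ("max_difference", "bs_exceeds_any_r"):
            raise ValidationError(f"unknown oral_rule {self.oral_rule!r}")


@dataclass
class PartitionResult:
    """Genus (and optionally OTU) labels with the evidence behind each call.

    ``genus`` is indexed by genus label and has columns ``label``,
    ``max_abund_bs`` and ``max_abund_r`` (percent).  ``otu`` is indexed by
    OTU id with columns ``genus`` and ``label`` once
    :func:`propagate_to_otus` has run.
    """

    genus: pd.DataFrame
    params: PartitionParams
    otu: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = set(self.genus["label"]) - set(LABELS)
        if bad:
            raise ValidationError(f"unknown partition label(s) {sorted(bad)}")

    def genera_with(self, label: str) -> list[str]:
        return list(self.genus.index[self.genus["label"] == label])

    def otus_with(self, label: str) -> list[str]:
        if self.otu is None:
            raise ValidationError("OTU labels not propagated yet")
        return list(self.otu.index[self.otu["label"] == label])

    @property
    def summary(self) -> dict:
        counts = {
            f"n_{short}_genera": int((self.genus["label"] == label).sum())
            for short, label in (
                ("oral", "oral_specific"),
                ("rumen", "rumen_specific"),
                ("rare", "rare"),
            )
        }
        if self.otu is not None:
            for short, label in (
                ("oral", "oral_specific"),
                ("rumen", "rumen_specific"),
                ("rare", "rare"),
            ):
                counts[f"n_{short}_otus"] = int((self.otu["label"] == label).sum())
        return counts


@dataclass
class CoreSet:
    """Per-group OTU presence sets and their intersection."""

    groups: list[tuple[int, str]]
    group_sets: dict = field(default_factory=dict)
    core_otus: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for g, members in self.group_sets.items():
            if not self.core_otus <= set(members):
                raise ValidationError(f"core set not contained in group {g} presence set")


def _percent_matrix(table: FeatureTable) -> pd.DataFrame:
    if table.mode != "relative":
        raise ValidationError("partitioning expects a TSS-normalized (relative) table")
    return table.data * 100.0


def classify_taxa(
    genus_rel: FeatureTable,
    meta: SampleMetadata,
    params: PartitionParams | None = None,
) -> PartitionResult:
    """Label every genus oral_specific / rumen_specific / rare.

    ``genus_rel`` must be a genus-level relative-abundance table containing
    both BS and R samples; the rule is defined relative to the stomach-tube
    reference, so absent R samples are an error.
    """
    params = params or PartitionParams()
    pct = _percent_matrix(genus_rel)
    methods = meta.data.loc[genus_rel.sample_ids, "method"]
    bs = pct.loc[methods == "BS"]
    r = pct.loc[methods == "R"]
    if r.shape[0] == 0:
        raise ValidationError(
            "no stomach-tube (R) samples present; the oral/rumen rule is defined "
            "relative to R samples"
        )
    if bs.shape[0] == 0:
        raise ValidationError("no buccal-swab (BS) samples present")
    max_bs = bs.max(axis=0)
    max_r = r.max(axis=0)
    max_all = pct.max(axis=0)

    rare = max_all < params.rare_cutoff_pct
    if params.oral_rule == "max_difference":
        oral = ~rare & (max_bs - max_r >= params.oral_cutoff_pp)
    else:  # bs_exceeds_any_r
        oral = ~rare & (max_bs >= params.oral_cutoff_pp) & (max_bs > max_r)
    label = pd.Series("rumen_specific", index=pct.columns, dtype=object)
    label[oral] = "oral_specific"
    label[rare] = "rare"

    genus = pd.DataFrame(
        {"label": label, "max_abund_bs": max_bs, "max_abund_r": max_r}
    )
    return PartitionResult(genus=genus, params=params)


def propagate_to_otus(partition: PartitionResult, tax: TaxonomyTable) -> PartitionResult:
    """Attach each OTU the label of its genus; returns an updated result."""
    genus_labels = tax.labels_at("genus")
    missing = sorted(set(genus_labels) - set(partition.genus.index))
    if missing:
        raise ValidationError(
            f"{len(missing)} genus label(s) absent from the partition, "
            f"e.g. {missing[0]!r}"
        )
    otu = pd.DataFrame(
        {
            "genus": genus_labels,
            "label": partition.genus["label"].reindex(genus_labels.to_numpy()).to_numpy(),
        },
        index=genus_labels.index,
    )
    return PartitionResult(genus=partition.genus, params=partition.params, otu=otu)


def _labels_for(table: FeatureTable, partition: PartitionResult) -> pd.Series:
    """Partition labels for the taxa of ``table`` (genus- or OTU-level)."""
    taxa = pd.Index(table.taxon_ids)
    if taxa.isin(partition.genus.index).all():
        return partition.genus.loc[taxa, "label"]
    if partition.otu is not None and taxa.isin(partition.otu.index).all():
        return partition.otu.loc[taxa, "label"]
    raise ValidationError(
        "table taxa match neither the genus nor the OTU level of the partition"
    )


def subset_renormalize(
    table: FeatureTable, partition: PartitionResult, which: str
) -> FeatureTable:
    """Restrict to taxa labelled ``which`` and re-scale each sample to 1.

    Samples in which the subset has zero total abundance are dropped with a
    warning (they carry no information about that fraction).
    """
    if which not in LABELS:
        raise ValidationError(f"unknown label {which!r}")
    if table.mode != "relative":
        raise ValidationError("subset_renormalize expects a relative table")
    labels = _labels_for(table, partition)
    cols = labels.index[labels == which]
    if len(cols) == 0:
        raise ValidationError(f"no taxa labelled {which!r}")
    sub = table.data.loc[:, cols]
    totals = sub.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        warnings.warn(
            f"subset_renormalize: dropping {int(zero.sum())} sample(s) with zero "
            f"{which} abundance",
            stacklevel=2,
        )
        sub = sub.loc[~zero]
        totals = totals[~zero]
    if sub.shape[0] == 0:
        raise ValidationError(f"no sample has positive {which!r} abundance")
    return FeatureTable(sub.div(totals, axis=0), "relative")


def oral_fraction_per_sample(
    table: FeatureTable, partition: PartitionResult
) -> pd.Series:
    """Percent of each sample's community assigned to oral-specific taxa."""
    if table.mode != "relative":
        raise ValidationError("oral_fraction_per_sample expects a relative table")
    labels = _labels_for(table, partition)
    oral_cols = labels.index[labels == "oral_specific"]
    if len(oral_cols) == 0:
        return pd.Series(0.0, index=table.data.index, name="oral_fraction_pct")
    frac = table.data.loc[:, oral_cols].sum(axis=1) * 100.0
    frac.name = "oral_fraction_pct"
    return frac


def core_otus(
    rs_table: FeatureTable,
    meta: SampleMetadata,
    groups: list[tuple[int, str]],
    min_samples: int = 1,
) -> CoreSet:
    """Core microbiome: OTUs present in every requested (day, method) group.

    An OTU is present in a group iff its abundance is strictly positive in
    at least ``min_samples`` samples of the group.
    """
    group_sets: dict[tuple[int, str], set] = {}
    for day, method in groups:
        sids = meta.samples_where(day=day, method=method)
        sids = [s for s in sids if s in rs_table.data.index]
        if not sids:
            raise ValidationError(f"no samples for group (day={day}, method={method!r})")
        present = (rs_table.data.loc[sids] > 0).sum(axis=0) >= min_samples
        group_sets[(day, method)] = set(rs_table.data.columns[present])
    core = set.intersection(*group_sets.values()) if group_sets else set()
    logger.info("core_otus: %d OTUs common to %d group(s)", len(core), len(groups))
    return CoreSet(groups=list(groups), group_sets=group_sets, core_otus=core)
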