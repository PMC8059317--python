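"""End-to-end orchestration: (simulate |load) -> preprocess -> partition -> stats.

A single :class:`RunConfig` (read from YAML by :func:`validate_config`)
drives the whole analysis.  All stochastic stages draw independent
sub-seeds from one master seed, so a run is reproducible bit-for-bit and
single stages can be re-run in isolation.  Every artifact is written under
``out_dir`` with deterministic filenames, together with a JSON + Markdown
report and a log recording versions, seeds and parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .partition import (
    PartitionParams,
    classify_taxa,
    core_otus,
    oral_fraction_per_sample,
    propagate_to_otus,
    subset_renormalize,
)
from .preprocess import (
    PreprocessParams,
    aggregate_to_rank,
    apply_confidence_thresholds,
    drop_low_abundance_otus,
    drop_low_read_samples,
    rarefy,
    tss_normalize,
)
from .stats import (
    anosim,
    bray_curtis,
    kruskal_wallis_dunn,
    mantel,
    matched_abundance_spearman,
    pcoa,
    per_taxon_spearman,
    shannon,
    within_group_similarity,
    bh_adjust,
    diversity_growth_correlation,
)
from .synthetic import SimulationDesign, simulate_study
from .tables_io import (
    FeatureTable,
    TaxonomyTable,
    ValidationError,
    align_tables,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "validate_config", "dump_config", "run_all"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and entity."""


@dataclass
class RunConfig:
    """Fully-defaulted configuration of one pipeline run."""

    seed: int = 1
    out_dir: str = "swabpartition_run"
    input: dict | None = None  # {"table":…, "taxonomy":…, "metadata":…}
    simulate: SimulationDesign = field(default_factory=SimulationDesign)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    partition: PartitionParams = field(default_factory=PartitionParams)
    n_permutations: int = 9999

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.input is not None:
            missing = {"table", "taxonomy", "metadata"} - set(self.input)
            if missing:
                raise ValidationError(
                    f"input section missing key(s) {sorted(missing)}"
                )

    def non_default_parameters(self) -> dict:
        """Every parameter that differs from its default, as a flat dict."""
        reference = RunConfig()
        diffs: dict[str, object] = {}
        for name in ("seed", "out_dir", "input", "n_permutations"):
            if getattr(self, name) != getattr(reference, name):
                diffs[name] = getattr(self, name)
        for section in ("simulate", "preprocess", "partition"):
            ours, theirs = getattr(self, section), getattr(reference, section)
            for f in dataclasses.fields(ours):
                if getattr(ours, f.name) != getattr(theirs, f.name):
                    diffs[f"{section}.{f.name}"] = getattr(ours, f.name)
        return diffs


_SECTION_TYPES = {
    "simulate": SimulationDesign,
    "preprocess": PreprocessParams,
    "partition": PartitionParams,
}


def _build_section(cls, mapping: dict, section: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(known)
    if unknown:
        raise ValidationError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}"
        )
    coerced = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except TypeError as exc:
        raise ValidationError(f"type mismatch in section {section!r}: {exc}") from exc


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    An empty file yields the all-defaults configuration; unknown keys are
    rejected with the offending key named.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValidationError("configuration must be a YAML mapping")
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> RunConfig:
    top_known = {"seed", "out_dir", "input", "n_permutations", *_SECTION_TYPES}
    unknown = set(doc) - top_known
    if unknown:
        raise ValidationError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs: dict[str, object] = {}
    for key in ("seed", "n_permutations"):
        if key in doc:
            if not isinstance(doc[key], int) or isinstance(doc[key], bool):
                raise ValidationError(f"key {key!r} must be an integer")
            kwargs[key] = doc[key]
    if "out_dir" in doc:
        kwargs["out_dir"] = str(doc["out_dir"])
    if "input" in doc and doc["input"] is not None:
        if not isinstance(doc["input"], dict):
            raise ValidationError("key 'input' must be a mapping")
        kwargs["input"] = dict(doc["input"])
    for section, cls in _SECTION_TYPES.items():
        if section in doc and doc[section] is not None:
            if not isinstance(doc[section], dict):
                raise ValidationError(f"section {section!r} must be a mapping")
            kwargs[section] = _build_section(cls, doc[section], section)
    return RunConfig(**kwargs)


def dump_config(config: RunConfig) -> dict:
    """Configuration as a plain dict; ``config_from_dict`` round-trips it."""
    doc: dict[str, object] = {
        "seed": config.seed,
        "out_dir": config.out_dir,
        "n_permutations": config.n_permutations,
    }
    if config.input is not None:
        doc["input"] = dict(config.input)
    for section in _SECTION_TYPES:
        obj = getattr(config, section)
        doc[section] = {
            f.name: (list(v) if isinstance(v := getattr(obj, f.name), tuple) else v)
            for f in dataclasses.fields(obj)
        }
    return doc


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------


def _sub_seeds(master: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in np.random.SeedSequence(master).generate_state(n)]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ValidationError, ValueError, KeyError) as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written out).

    Stages, in order: input (simulate or load + align), preprocess
    (read filters, taxonomy relabelling, TSS), partition (genus rule, OTU
    propagation, RS/OS renormalization, oral fractions, core OTUs) and
    stats (rarefied Shannon, Bray-Curtis, PCoA, within-group similarity,
    ANOSIM battery, Mantel, Spearman grids, Kruskal-Wallis + Dunn + BH).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("swabpartition")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    seeds = _sub_seeds(config.seed, 8)
    (seed_sim, seed_rarefy_rs, seed_rarefy_os, seed_anosim, seed_mantel,
     seed_anosim_age, seed_anosim_wean, _spare) = seeds
    logger.info(
        "swabpartition %s | master seed %d | sub-seeds %s",
        __version__, config.seed, seeds,
    )
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "sub_seeds": {
            "simulate": seed_sim, "rarefy_rs": seed_rarefy_rs,
            "rarefy_os": seed_rarefy_os, "anosim_method": seed_anosim,
            "mantel": seed_mantel, "anosim_age": seed_anosim_age,
            "anosim_weaning": seed_anosim_wean,
        },
        "parameters": dump_config(config),
        "non_default_parameters": config.non_default_parameters(),
    }

    # ---- input -----------------------------------------------------------
    table, tax, meta, truth = _stage_input(config, seed_sim)
    report["input"] = {
        "n_samples": table.n_samples,
        "n_otus": table.n_taxa,
        "simulated": config.input is None,
    }

    # ---- preprocess ------------------------------------------------------
    pp = config.preprocess
    table_f = _stage_preprocess_counts(table, pp)
    tax_f = _stage("preprocess")(apply_confidence_thresholds)(
        tax, pp.rank_confidence_thresholds
    )
    # restrict taxonomy to OTUs that survived the count filters
    tax_f = TaxonomyTable(tax_f.data.loc[table_f.taxon_ids])
    rel = _stage("preprocess")(tss_normalize)(table_f)
    genus_rel = _stage("preprocess")(aggregate_to_rank)(rel, tax_f, "genus")
    report["preprocess"] = {
        "n_samples_retained": table_f.n_samples,
        "n_otus_retained": table_f.n_taxa,
        "n_genus_level_taxa": genus_rel.n_taxa,
    }
    write_feature_table(table_f, out / "filtered_counts.tsv")
    write_taxonomy(tax_f, out / "taxonomy_filtered.tsv")
    write_feature_table(genus_rel, out / "genus_relative.tsv")
    write_metadata(meta, out / "metadata_aligned.tsv")

    # ---- partition -------------------------------------------------------
    part = _stage("partition")(classify_taxa)(genus_rel, meta, config.partition)
    part = _stage("partition")(propagate_to_otus)(part, tax_f)
    part.genus.to_csv(out / "partition_genus.tsv", sep="\t")
    part.otu.to_csv(out / "partition_otus.tsv", sep="\t")
    report["partition"] = part.summary

    oral_frac = _stage("partition")(oral_fraction_per_sample)(genus_rel, part)
    bs_ids = meta.samples_where(method="BS")
    oral_bs = oral_frac[oral_frac.index.isin(bs_ids)]
    by_day = oral_bs.groupby(meta.data.loc[oral_bs.index, "day"]).mean()
    oral_frac.to_frame().to_csv(out / "oral_fraction.tsv", sep="\t")
    report["oral_fraction_pct_by_day"] = {int(d): float(v) for d, v in by_day.items()}

    rs_rel = _stage("partition")(subset_renormalize)(rel, part, "rumen_specific")
    os_rel = _stage("partition")(subset_renormalize)(rel, part, "oral_specific")
    rs_genus_rel = _stage("partition")(subset_renormalize)(
        genus_rel, part, "rumen_specific"
    )
    write_feature_table(rs_rel, out / "rs_relative_otus.tsv")
    write_feature_table(os_rel, out / "os_relative_otus.tsv")

    days = sorted(meta.data["day"].unique())
    final_day = days[-1]
    core_groups = [(d, "BS") for d in days[1:]] + [(final_day, "R")]
    core = _stage("partition")(core_otus)(rs_rel, meta, core_groups)
    pd.Series(sorted(core.core_otus), name="core_otu").to_csv(
        out / "core_otus.tsv", sep="\t", index=False
    )
    report["core"] = {
        "groups": [f"day{d}{m}" for d, m in core_groups],
        "n_core_otus": len(core.core_otus),
        "per_group_otus": {
            f"day{d}{m}": len(s) for (d, m), s in core.group_sets.items()
        },
    }

    # ---- alpha diversity on rarefied RS / OS datasets --------------------
    report["alpha"] = {}
    shannon_frames = {}
    for name, labelled, seed_r in (
        ("rs", "rumen_specific", seed_rarefy_rs),
        ("os", "oral_specific", seed_rarefy_os),
    ):
        taxa = part.otus_with(labelled)
        taxa = [t for t in taxa if t in table_f.data.columns]
        sub = table_f.data.loc[:, taxa]
        if name == "os":
            # the oral-specific dataset exists only for buccal swabs; tube
            # samples carry no oral fraction
            sub = sub.loc[[s for s in sub.index if s in bs_ids]]
        sub = sub.loc[sub.sum(axis=1) > 0]
        sub_counts = FeatureTable(sub, "counts")
        totals = sub_counts.sample_totals()
        depth = int(totals.min()) if pp.rarefaction_depth == "auto-min" else int(
            pp.rarefaction_depth
        )
        rare_tab = _stage("alpha")(rarefy)(sub_counts, depth, seed_r)
        h = pd.Series(
            {sid: shannon(row.to_numpy()) for sid, row in rare_tab.data.iterrows()},
            name="shannon",
        )
        frame = h.to_frame()
        frame["day"] = meta.data.loc[frame.index, "day"]
        frame["method"] = meta.data.loc[frame.index, "method"]
        frame["weaning_group"] = meta.data.loc[frame.index, "weaning_group"]
        frame.to_csv(out / f"shannon_{name}.tsv", sep="\t")
        shannon_frames[name] = frame
        bs_frame = frame[frame["method"] == "BS"]
        report["alpha"][name] = {
            "rarefaction_depth": depth,
            "mean_shannon_by_day": {
                int(d): float(v)
                for d, v in bs_frame.groupby("day")["shannon"].mean().items()
            },
        }
    rs_sh = shannon_frames["rs"]
    bs_sh = rs_sh[rs_sh["method"] == "BS"]
    kw_age = _stage("alpha")(kruskal_wallis_dunn)(
        bs_sh["shannon"], bs_sh["day"].astype(str)
    )
    report["alpha"]["rs_age_effect"] = {
        "H": kw_age.h_statistic,
        "p": kw_age.p_value,
        "pairwise": kw_age.pairwise.to_dict(orient="records"),
    }

    # ---- beta diversity and permutation tests ----------------------------
    dm_full = _stage("beta")(bray_curtis)(rel)
    dm_rs = _stage("beta")(bray_curtis)(rs_rel)
    ord_full = pcoa(dm_full, k=2)
    ord_rs = pcoa(dm_rs, k=2)
    ord_full.coordinates.to_csv(out / "pcoa_full.tsv", sep="\t")
    ord_rs.coordinates.to_csv(out / "pcoa_rs.tsv", sep="\t")

    method_groups = meta.data["method"]
    res_full = _stage("beta")(anosim)(
        dm_full, method_groups, config.n_permutations, seed_anosim
    )
    res_rs = _stage("beta")(anosim)(
        dm_rs, method_groups, config.n_permutations, seed_anosim
    )
    day_groups = meta.data.loc[
        [s for s in rs_rel.sample_ids if s in bs_ids], "day"
    ].astype(str)
    dm_rs_bs = dm_rs.filter(list(day_groups.index))
    res_age = _stage("beta")(anosim)(
        dm_rs_bs, day_groups, config.n_permutations, seed_anosim_age
    )
    report["anosim"] = {
        "method_full_community": _perm_dict(res_full),
        "method_rs_renormalized": _perm_dict(res_rs),
        "age_rs_bs": _perm_dict(res_age),
    }

    wean = {}
    for d in days:
        sids = [s for s in meta.samples_where(day=d, method="BS") if s in dm_rs.ids]
        groups_d = meta.data.loc[sids, "weaning_group"]
        if groups_d.nunique() < 2 or (groups_d.value_counts() < 2).any():
            continue
        res = _stage("beta")(anosim)(
            dm_rs.filter(sids), groups_d, config.n_permutations, seed_anosim_wean
        )
        wean[int(d)] = _perm_dict(res)
    report["anosim"]["weaning_by_day_rs_bs"] = wean

    sim_groups = meta.data.loc[
        [s for s in dm_rs_bs.ids], "day"
    ].map(lambda d: f"day{d}")
    wgs = _stage("beta")(within_group_similarity)(dm_rs_bs, sim_groups)
    wgs.to_csv(out / "within_group_similarity.tsv", sep="\t")
    report["within_group_similarity_pct"] = {
        g: float(v) for g, v in wgs["mean_pct"].items()
    }

    # ---- Mantel: final-day R vs final-day BS (RS portion) ----------------
    r_ids = [s for s in meta.samples_where(day=final_day, method="R")
             if s in rs_rel.data.index]
    bs_final = [s for s in meta.samples_where(day=final_day, method="BS")
                if s in rs_rel.data.index]
    animal_of = meta.data["animal_id"]
    shared_animals = sorted(
        set(animal_of[r_ids]) & set(animal_of[bs_final])
    )
    if len(shared_animals) >= 3:
        r_by_animal = {animal_of[s]: s for s in r_ids}
        bs_by_animal = {animal_of[s]: s for s in bs_final}
        r_sel = [r_by_animal[a] for a in shared_animals]
        bs_sel = [bs_by_animal[a] for a in shared_animals]
        dm_r = bray_curtis(_renorm(rs_rel, r_sel))
        dm_bs = bray_curtis(_renorm(rs_rel, bs_sel))
        # relabel both by animal so ids match
        dm_r = type(dm_r)(shared_animals, dm_r.values)
        dm_bs = type(dm_bs)(shared_animals, dm_bs.values)
        res_mantel = _stage("mantel")(mantel)(
            dm_r, dm_bs, "pearson", config.n_permutations, seed_mantel
        )
        report["mantel_final_day"] = {
            **_perm_dict(res_mantel), "n_animals": len(shared_animals)
        }
        # per-OTU correspondence between R and the RS portion of BS
        pairing = dict(zip(bs_sel, r_sel))
        per_r, mean_r = _stage("spearman")(per_taxon_spearman)(
            _renorm(rs_rel, bs_sel), _renorm(rs_rel, r_sel), pairing
        )
        per_r.to_frame("spearman_r").to_csv(out / "per_otu_spearman.tsv", sep="\t")
        report["per_otu_spearman_mean_r"] = mean_r

    # ---- matched-abundance Spearman grid (each BS day vs final-day R) ----
    grid = {}
    for d in days:
        bs_d = [s for s in meta.samples_where(day=d, method="BS")
                if s in rs_genus_rel.data.index]
        animals_d = sorted(set(animal_of[bs_d]) & set(animal_of[r_ids]))
        if len(animals_d) < 3:
            continue
        bs_by_animal = {animal_of[s]: s for s in bs_d}
        r_by_animal = {animal_of[s]: s for s in r_ids}
        pairing = {bs_by_animal[a]: r_by_animal[a] for a in animals_d}
        r_val, _p = _stage("spearman")(matched_abundance_spearman)(
            rs_genus_rel, rs_genus_rel, pairing
        )
        grid[int(d)] = float(r_val)
    report["matched_spearman_bs_vs_final_r"] = grid

    # ---- per-genus Kruskal-Wallis by age with tablewide BH ---------------
    kw_rows = []
    rs_genus_bs = rs_genus_rel.data.loc[
        [s for s in rs_genus_rel.data.index if s in bs_ids]
    ]
    day_of = meta.data.loc[rs_genus_bs.index, "day"].astype(str)
    for genus in rs_genus_bs.columns:
        vals = rs_genus_bs[genus]
        if np.ptp(vals.to_numpy()) == 0:
            continue
        res = kruskal_wallis_dunn(vals, day_of)
        kw_rows.append({"taxon": genus, "H": res.h_statistic, "p_raw": res.p_value})
    if kw_rows:
        kw_table = pd.DataFrame(kw_rows).set_index("taxon")
        kw_table["p_adj"] = bh_adjust(kw_table["p_raw"].to_numpy())
        kw_table.to_csv(out / "kw_genus_by_age.tsv", sep="\t")
        report["kw_genus_by_age"] = {
            "n_taxa_tested": len(kw_table),
            "n_significant_fdr05": int((kw_table["p_adj"] < 0.05).sum()),
        }

    # ---- diversity vs growth ---------------------------------------------
    if meta.growth_columns:
        alpha_by_animal = bs_sh.join(meta.data["animal_id"]).groupby(
            "animal_id"
        )["shannon"].mean()
        growth = meta.data.groupby("animal_id")[meta.growth_columns].first()
        r_mat, p_mat = _stage("growth")(diversity_growth_correlation)(
            alpha_by_animal, growth
        )
        r_mat.to_csv(out / "diversity_growth_spearman.tsv", sep="\t")
        report["diversity_growth"] = {
            v: float(r_mat.loc["shannon", v]) for v in meta.growth_columns
        }

    # ---- ground-truth comparison (simulated inputs only) ------------------
    if truth is not None:
        report["truth_recovery"] = _truth_recovery(part, oral_bs, truth)

    _write_report(report, out)
    root.removeHandler(log_handler)
    log_handler.close()
    return report


@_stage("input")
def _stage_input(config: RunConfig, seed_sim: int):
    if config.input is not None:
        table = read_feature_table(config.input["table"])
        tax = read_taxonomy(config.input["taxonomy"])
        meta = read_metadata(config.input["metadata"])
        truth = None
    else:
        table, tax, meta, truth = simulate_study(config.simulate, seed_sim)
    table, tax, meta = align_tables(table, tax, meta)
    return table, tax, meta, truth


@_stage("preprocess")
def _stage_preprocess_counts(table: FeatureTable, pp: PreprocessParams) -> FeatureTable:
    table = drop_low_read_samples(table, pp.min_sample_reads)
    return drop_low_abundance_otus(
        table, pp.low_abundance_frac, per_sample=pp.per_sample_low_abundance
    )


def _renorm(rel: FeatureTable, sample_ids: list[str]) -> FeatureTable:
    sub = rel.data.loc[sample_ids]
    totals = sub.sum(axis=1)
    if (totals <= 0).any():
        raise ValidationError("sample with zero subset abundance")
    return FeatureTable(sub.div(totals, axis=0), "relative")


def _perm_dict(res) -> dict:
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.p_value),
        "n_permutations": res.n_permutations,
    }


def _truth_recovery(part, oral_bs: pd.Series, truth) -> dict:
    from scipy import stats as sps

    # Recovery is scored on primary named genera only: low-confidence OTUs
    # split off into "unclassified <family>" genus-level taxa, which are a
    # taxonomy artifact rather than additional true genera.
    detect = truth.genus_detectable
    rows = {
        g: {
            "origin": truth.genus_origin[g],
            "detectable": bool(detect.get(g, False)),
            "label": part.genus.loc[g, "label"],
        }
        for g in part.genus.index
        if g in truth.genus_origin.index
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    det = frame[frame["detectable"]]
    oral_det = det[det["origin"] == "oral"]
    rumen_det = det[det["origin"] == "rumen"]
    out = {
        "oral_genus_recall": float(
            (oral_det["label"] == "oral_specific").mean()
        ) if len(oral_det) else float("nan"),
        "rumen_genus_recall": float(
            (rumen_det["label"] == "rumen_specific").mean()
        ) if len(rumen_det) else float("nan"),
        "n_detectable_oral_genera": int(len(oral_det)),
        "n_detectable_rumen_genera": int(len(rumen_det)),
    }
    lam = truth.sample_lambda.reindex(oral_bs.index).dropna()
    if len(lam) >= 3:
        est = oral_bs[lam.index]
        rho = sps.spearmanr(est, (1.0 - lam) * 100.0)[0]
        out["oral_fraction_vs_truth_spearman"] = float(rho)
    return out


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    lines = [
        "# swabpartition run report",
        "",
        f"* version: {report['version']}",
        f"* master seed: {report['seed']}",
        f"* non-default parameters: {report['non_default_parameters'] or 'none'}",
        "",
        "## Partition",
        "",
    ]
    for k, v in report.get("partition", {}).items():
        lines.append(f"* {k}: {v}")
    lines += ["", "## Oral fraction (% of BS community) by day", ""]
    for d, v in report.get("oral_fraction_pct_by_day", {}).items():
        lines.append(f"* day {d}: {v:.1f}%")
    lines += ["", "## ANOSIM", ""]
    for name, res in report.get("anosim", {}).items():
        if name == "weaning_by_day_rs_bs":
            for d, r in res.items():
                lines.append(
                    f"* weaning day {d}: R = {r['statistic']:.3f}, p = {r['p_value']:.4g}"
                )
        else:
            lines.append(
                f"* {name}: R = {res['statistic']:.3f}, p = {res['p_value']:.4g}"
            )
    if "mantel_final_day" in report:
        m = report["mantel_final_day"]
        lines += [
            "",
            f"Mantel (final-day R vs BS-RS, {m['n_animals']} animals): "
            f"r = {m['statistic']:.3f}, p = {m['p_value']:.4g}",
        ]
    with open(out / "report.md", "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
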