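"""Synthetic longitudinal two-compartment (oral x rumen) amplicon datasets.

The generator emulates the statistical structure the buccal-swab proxy
analysis assumes: every buccal-swab (BS) sample is a mixture of a latent
oral community and the animal's latent rumen community, with carryover
fraction ``lambda`` (the rumen share of the mixture) drawn per sample from
a Beta distribution whose per-day means put the *oral* fraction in the
36-66% band.  Stomach-tube (R) samples are pure rumen (``lambda = 1``) and
exist only at the final day, mirroring the study design.

The rumen community diversifies with age — OTU richness grows (each rumen
OTU has an emergence day) and evenness increases (a tempering exponent on
genus abundances relaxes towards 1) — while the oral community is static.
Weaning perturbs the rumen composition: the early-weaned group (earlyC)
switches abruptly to a "post-weaning" profile between days 42 and 70, the
late-weaned group (lateC) between days 98 and 112, and both groups
converge to the same mature profile by day 140.

Overdispersion is animal-persistent, as in any repeated-measures study:
each animal draws its genus-level composition once per compartment from a
Dirichlet around the population shares (default concentration 99,
intra-class correlation about 0.01), and every one of its samples is then
Dirichlet-multinomial around its own mixture with a mild per-sample
concentration (default 1000).  Oral and rumen genus pools are disjoint by
default so every taxon has an unambiguous ground-truth origin; a small
rare tail of genera in both compartments (about 3% of each compartment's
mass) exercises the rare-taxon class of the partition rule.

Features of real data deliberately not emulated: shared oral/rumen taxa
(available via ``shared_taxa_fraction``), sequencing error, chimeras, and
compositional interactions between compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables_io import (
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "SimulationDesign",
    "TruthLabels",
    "BaseCommunities",
    "build_base_communities",
    "simulate_sample",
    "simulate_study",
]

GROWTH_VARIABLES = (
    "hip_height",
    "withers_height",
    "back_length",
    "body_length",
    "heart_girth",
    "live_weight_gain",
)


@dataclass
class SimulationDesign:
    """Parameters of the synthetic study.

    Defaults mirror the study's scale: 59 animals sampled by buccal swab at
    days 42, 70, 98, 112 and 140 of life plus stomach tubing at day 140,
    sequencing depth around 20,000 reads, and per-day mean oral fractions
    of 36.0, 66.2, 65.0, 53.2 and 57.1%.
    """

    n_animals: int = 59
    days: tuple = (42, 70, 98, 112, 140)
    n_oral_genera: int = 141
    n_rumen_genera: int = 29
    n_rare_genera: int = 80
    oral_otus_per_genus_mean: float = 8.0
    rumen_otus_per_genus_mean: float = 40.0
    rare_otus_per_genus_mean: float = 2.0
    oral_lognormal_sigma: float = 0.5
    rumen_lognormal_sigma: float = 0.7
    rare_mass_fraction: float = 0.03
    oral_fraction_day_means: tuple = (0.360, 0.662, 0.650, 0.532, 0.571)
    lambda_concentration: float = 60.0
    depth_mean: float = 20000.0
    depth_cv: float = 0.10
    dispersion: float = 99.0
    sample_concentration: float = 1000.0
    evenness_span: float = 0.35
    initial_otu_fraction: float = 0.55
    richness_growth_per_day: float | None = None
    weaning_shock: float = 1.0
    shared_taxa_fraction: float = 0.0
    low_confidence_fraction: float = 0.10
    day42_subsample: int | None = None
    include_growth: bool = True
    seed: int = 20260927

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        if len(self.days) != len(self.oral_fraction_day_means):
            raise ValidationError("one oral-fraction mean per day required")
        for f in self.oral_fraction_day_means:
            if not 0.0 < f < 1.0:
                raise ValidationError("oral fraction means must lie in (0, 1)")
        if not 0.0 < self.initial_otu_fraction <= 1.0:
            raise ValidationError("initial_otu_fraction must be in (0, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if not 0.0 <= self.shared_taxa_fraction < 1.0:
            raise ValidationError("shared_taxa_fraction must be in [0, 1)")

    def with_(self, **kwargs) -> "SimulationDesign":
        return replace(self, **kwargs)

    @property
    def final_day(self) -> int:
        return self.days[-1]

    def richness_rate(self) -> float:
        """Fraction of dormant rumen OTUs activated per day of life."""
        if self.richness_growth_per_day is not None:
            return self.richness_growth_per_day
        span = self.days[-1] - self.days[0]
        return (1.0 - self.initial_otu_fraction) / span if span else 0.0


@dataclass
class TruthLabels:
    """Ground truth behind a simulated dataset.

    ``genus_origin`` / ``otu_origin`` give the true compartment of every
    taxon; ``genus_detectable`` marks main-pool genera (the rare tail is
    below the partition rule's 1% ceiling by construction).
    ``sample_lambda`` is the true rumen share of each sample's composition
    (1.0 for stomach-tube samples), and ``rumen_shannon`` the Shannon
    diversity (nats) of the latent rumen OTU profile per (day, group).
    """

    genus_origin: pd.Series
    genus_detectable: pd.Series
    otu_origin: pd.Series
    sample_lambda: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    rumen_shannon: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.genus_origin) - {"oral", "rumen"}
        if bad:
            raise ValidationError(f"unknown origin label(s) {sorted(bad)}")


@dataclass
class BaseCommunities:
    """Latent profiles underlying a simulated study.

    ``oral_probs`` / ``rumen_probs`` are population-mean OTU profiles (the
    latter per (day, group)); the genus-share and within-genus-weight
    fields factor those profiles so that animal-level genus compositions
    can be drawn around the shares while the day-dependent OTU structure
    stays deterministic.
    """

    otu_ids: list[str]
    oral_probs: np.ndarray  # oral community, sums to 1 over all OTUs
    rumen_probs: dict  # (day, group) -> probability vector over all OTUs
    genus_of_otu: pd.Series
    truth: TruthLabels
    oral_genus_shares: pd.Series = None  # by genus, sums to 1
    rumen_genus_shares: pd.Series = None
    oral_genus_codes: np.ndarray = None  # per oral OTU, index into oral genera
    rumen_genus_codes: np.ndarray = None
    oral_otu_mask: np.ndarray = None
    oral_within: np.ndarray = None  # per oral OTU, weight within its genus
    rumen_within: dict = None  # (day, group) -> per rumen OTU within-genus weight


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _genus_shares(rng, n_main, sigma, n_rare, rare_mass):
    """Normalized genus shares: lognormal main pool plus a tiny rare tail."""
    main = rng.lognormal(mean=0.0, sigma=sigma, size=n_main)
    main = main / main.sum() * (1.0 - rare_mass if n_rare else 1.0)
    if n_rare:
        tail = rng.lognormal(mean=0.0, sigma=1.0, size=n_rare)
        tail = tail / tail.sum() * rare_mass
        return np.concatenate([main, tail])
    return main


def _otu_counts(rng, n_genera, mean):
    return 1 + rng.poisson(max(mean - 1.0, 0.0), size=n_genera)


def build_base_communities(
    design: SimulationDesign, seed: int | None = None
) -> BaseCommunities:
    """Draw the latent oral and per-day rumen OTU profiles plus truth labels."""
    seed = design.seed if seed is None else seed
    rngs = _spawn(seed, 6)
    r_shape, r_shock, r_weights, r_emerge, _, _ = rngs

    n_rare_oral = design.n_rare_genera // 2
    n_rare_rumen = design.n_rare_genera - n_rare_oral

    oral_genus_shares = _genus_shares(
        r_shape, design.n_oral_genera, design.oral_lognormal_sigma,
        n_rare_oral, design.rare_mass_fraction,
    )
    rumen_genus_shares = _genus_shares(
        r_shape, design.n_rumen_genera, design.rumen_lognormal_sigma,
        n_rare_rumen, design.rare_mass_fraction,
    )

    oral_genera = [f"g_oral_{i:03d}" for i in range(len(oral_genus_shares))]
    rumen_genera = [f"g_rumen_{i:03d}" for i in range(len(rumen_genus_shares))]
    detectable = pd.Series(
        [i < design.n_oral_genera for i in range(len(oral_genera))]
        + [i < design.n_rumen_genera for i in range(len(rumen_genera))],
        index=oral_genera + rumen_genera,
    )
    origin = pd.Series(
        ["oral"] * len(oral_genera) + ["rumen"] * len(rumen_genera),
        index=oral_genera + rumen_genera,
    )

    # optional shared taxa: a fraction of rumen genera also seeds the oral pool
    shared_oral_extra = {}
    if design.shared_taxa_fraction > 0:
        n_shared = int(round(design.shared_taxa_fraction * design.n_rumen_genera))
        for g in rumen_genera[:n_shared]:
            shared_oral_extra[g] = float(
                rumen_genus_shares[rumen_genera.index(g)] * 0.5
            )

    # OTU expansion
    oral_k = _otu_counts(r_weights, design.n_oral_genera, design.oral_otus_per_genus_mean)
    oral_k = np.concatenate(
        [oral_k, _otu_counts(r_weights, n_rare_oral, design.rare_otus_per_genus_mean)]
    ) if n_rare_oral else oral_k
    rumen_k = _otu_counts(r_weights, design.n_rumen_genera, design.rumen_otus_per_genus_mean)
    rumen_k = np.concatenate(
        [rumen_k, _otu_counts(r_weights, n_rare_rumen, design.rare_otus_per_genus_mean)]
    ) if n_rare_rumen else rumen_k

    otu_ids: list[str] = []
    genus_of_otu: list[str] = []
    otu_weights: list[np.ndarray] = []
    for genus, k in zip(oral_genera + rumen_genera, np.concatenate([oral_k, rumen_k])):
        w = r_weights.dirichlet(np.ones(int(k)))
        w = -np.sort(-w)  # largest-weight OTU first
        for j in range(int(k)):
            otu_ids.append(f"otu_{genus[2:]}_{j:03d}")
            genus_of_otu.append(genus)
        otu_weights.append(w)
    weights = np.concatenate(otu_weights)
    genus_of_otu = pd.Series(genus_of_otu, index=otu_ids)
    n_otus = len(otu_ids)
    is_oral_otu = genus_of_otu.str.startswith("g_oral").to_numpy()

    genus_share = pd.Series(
        np.concatenate([oral_genus_shares, rumen_genus_shares]),
        index=oral_genera + rumen_genera,
    )

    # static oral profile
    oral_probs = np.zeros(n_otus)
    oral_probs[is_oral_otu] = (
        genus_share[genus_of_otu[is_oral_otu]].to_numpy() * weights[is_oral_otu]
    )
    for g, extra in shared_oral_extra.items():
        mask = (genus_of_otu == g).to_numpy()
        oral_probs[mask] = extra * weights[mask]
    oral_probs /= oral_probs.sum()

    # Rumen per day x group.  Age and weaning act on the *within-genus* OTU
    # weights (emergence masking, evenness tempering, weaning shock) while
    # genus shares stay fixed: the rumen carries a stable genus-level
    # signature whose fine OTU structure diversifies with age and is
    # reorganized by weaning.  Genus shares are renormalized within each
    # genus after masking, so the genus composition is exactly preserved.
    emergence_u = r_emerge.uniform(size=n_otus)
    # the dominant OTU of every rumen genus is present from the start
    offset = 0
    for k in np.concatenate([oral_k, rumen_k]):
        emergence_u[offset] = 0.0
        offset += int(k)

    day_span = design.days[-1] - design.days[0]
    rate = design.richness_rate()
    # earlyC switches to the post-weaning profile right after the first day,
    # lateC between the two last pre-final days, and both groups share the
    # mature profile at the final day.
    weaning_progress: dict[str, dict[int, float]] = {"earlyC": {}, "lateC": {}}
    for di, day in enumerate(design.days):
        weaning_progress["earlyC"][day] = 0.0 if di == 0 else 1.0
        if di == len(design.days) - 1:
            weaning_progress["lateC"][day] = 1.0
        elif di == len(design.days) - 2 and len(design.days) > 2:
            weaning_progress["lateC"][day] = 0.6
        else:
            weaning_progress["lateC"][day] = 0.0

    rumen_probs: dict[tuple[int, str], np.ndarray] = {}
    rumen_shannon: dict[tuple[int, str], float] = {}
    rumen_otu_mask = ~is_oral_otu
    rumen_genus_arr = genus_of_otu[rumen_otu_mask]
    rumen_weights = weights[rumen_otu_mask]
    rumen_emergence = emergence_u[rumen_otu_mask]
    otu_shock = r_shock.normal(size=int(rumen_otu_mask.sum()))
    genus_index = pd.Series(
        np.arange(len(rumen_genera)), index=rumen_genera
    )[rumen_genus_arr].to_numpy()
    genus_share_arr = rumen_genus_shares / rumen_genus_shares.sum()
    rumen_within: dict[tuple[int, str], np.ndarray] = {}
    for di, day in enumerate(design.days):
        active_frac = min(1.0, design.initial_otu_fraction + rate * (day - design.days[0]))
        active = rumen_emergence <= active_frac + 1e-12
        frac = (day - design.days[0]) / day_span if day_span else 0.0
        gamma = 1.0 + design.evenness_span * (1.0 - frac)
        for group in ("earlyC", "lateC"):
            w = weaning_progress[group][day]
            vals = rumen_weights**gamma * np.exp(
                w * design.weaning_shock * otu_shock
            )
            vals[~active] = 0.0
            per_genus = np.bincount(genus_index, weights=vals,
                                    minlength=len(rumen_genera))
            within = vals / per_genus[genus_index]
            rumen_within[(day, group)] = within
            probs = np.zeros(n_otus)
            probs[rumen_otu_mask] = within * genus_share_arr[genus_index]
            probs /= probs.sum()
            rumen_probs[(day, group)] = probs
            p = probs[probs > 0]
            rumen_shannon[(day, group)] = float(-(p * np.log(p)).sum())

    truth = TruthLabels(
        genus_origin=origin,
        genus_detectable=detectable,
        otu_origin=origin[genus_of_otu].set_axis(genus_of_otu.index),
        rumen_shannon=rumen_shannon,
    )
    # factor the oral profile into genus shares x within-genus weights so
    # animal-level genus compositions can be drawn around the shares
    oral_otu_mask = oral_probs > 0
    oral_contrib_genera = pd.Index(sorted(set(genus_of_otu[oral_otu_mask])))
    oral_mass = (
        pd.Series(oral_probs, index=otu_ids)[oral_otu_mask]
        .groupby(genus_of_otu[oral_otu_mask])
        .sum()
        .reindex(oral_contrib_genera)
    )
    oral_codes = pd.Series(
        np.arange(len(oral_contrib_genera)), index=oral_contrib_genera
    )[genus_of_otu[oral_otu_mask]].to_numpy()
    oral_within = oral_probs[oral_otu_mask] / oral_mass.to_numpy()[oral_codes]
    return BaseCommunities(
        otu_ids=otu_ids,
        oral_probs=oral_probs,
        rumen_probs=rumen_probs,
        genus_of_otu=genus_of_otu,
        truth=truth,
        oral_genus_shares=oral_mass,
        rumen_genus_shares=pd.Series(genus_share_arr, index=rumen_genera),
        oral_genus_codes=oral_codes,
        rumen_genus_codes=genus_index,
        oral_otu_mask=oral_otu_mask,
        oral_within=oral_within,
        rumen_within=rumen_within,
    )


def simulate_sample(
    mixture: np.ndarray,
    depth: int,
    dispersion: float | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dirichlet-multinomial counts around a mixture composition.

    ``dispersion`` is the total Dirichlet concentration; ``None`` (or
    ``inf``) degenerates to a plain multinomial, in which case taxa with
    zero mixture probability receive exactly zero counts.
    """
    if depth <= 0:
        raise ValidationError("sequencing depth must be positive")
    mixture = np.asarray(mixture, dtype=float)
    if mixture.sum() <= 0:
        raise ValidationError("mixture composition sums to zero")
    p = mixture / mixture.sum()
    if dispersion is None or np.isinf(dispersion):
        return rng.multinomial(depth, p)
    support = p > 0
    alpha = p[support] * dispersion
    theta = rng.dirichlet(alpha)
    counts = np.zeros(len(p), dtype=np.int64)
    counts[support] = rng.multinomial(depth, theta)
    return counts


def _lineage_for(genus: str, origin: str, gi: int) -> dict:
    return {
        "phylum": f"p_{origin}_{gi // 30:02d}",
        "class": f"c_{origin}_{gi // 15:02d}",
        "order": f"o_{origin}_{gi // 8:02d}",
        "family": f"f_{genus[2:]}",
        "genus": genus,
    }


def simulate_study(
    design: SimulationDesign | None = None, seed: int | None = None
) -> tuple[FeatureTable, TaxonomyTable, SampleMetadata, TruthLabels]:
    """Simulate the full longitudinal study.

    Buccal swabs for every animal at every day, stomach tubing at the final
    day only.  Returns the count table, taxonomy (with drawn per-rank
    confidences), metadata and ground-truth labels.  Fully reproducible
    given ``seed`` (defaults to ``design.seed``).
    """
    design = design or SimulationDesign()
    seed = design.seed if seed is None else seed
    base_seed, *_ = np.random.SeedSequence(seed).generate_state(1)
    base = build_base_communities(design, int(base_seed) % (2**31))
    rngs = _spawn(seed + 1, 5)
    r_lambda, r_counts, r_depth, r_conf, r_design = rngs

    animals = [f"A{i + 1:02d}" for i in range(design.n_animals)]
    weaning = np.array(["earlyC", "lateC"])[
        r_design.permutation(np.arange(design.n_animals) % 2)
    ]
    group_of = dict(zip(animals, weaning))

    day42_animals = set(animals)
    if design.day42_subsample is not None:
        keep = r_design.choice(animals, size=design.day42_subsample, replace=False)
        day42_animals = set(keep)

    n_otus = len(base.otu_ids)
    rumen_mask = base.genus_of_otu.str.startswith("g_rumen").to_numpy()
    oral_alpha = design.dispersion * base.oral_genus_shares.to_numpy()
    rumen_alpha = design.dispersion * base.rumen_genus_shares.to_numpy()

    records = []
    count_rows = []
    lambdas = {}
    for a_idx, animal in enumerate(animals):
        group = group_of[animal]
        # animal-persistent genus compositions (repeated-measures structure)
        theta_oral = r_counts.dirichlet(oral_alpha)
        theta_rumen = r_counts.dirichlet(rumen_alpha)
        oral_a = np.zeros(n_otus)
        oral_a[base.oral_otu_mask] = (
            theta_oral[base.oral_genus_codes] * base.oral_within
        )

        def rumen_profile(day: int) -> np.ndarray:
            probs = np.zeros(n_otus)
            probs[rumen_mask] = (
                theta_rumen[base.rumen_genus_codes]
                * base.rumen_within[(day, group)]
            )
            return probs / probs.sum()

        for di, day in enumerate(design.days):
            if day == design.days[0] and animal not in day42_animals:
                continue
            sid = f"{animal}D{day:03d}BS"
            mu = 1.0 - design.oral_fraction_day_means[di]  # mean rumen share
            lam = float(
                r_lambda.beta(
                    mu * design.lambda_concentration,
                    (1.0 - mu) * design.lambda_concentration,
                )
            )
            mixture = lam * rumen_profile(day) + (1.0 - lam) * oral_a
            depth = _draw_depth(r_depth, design)
            counts = simulate_sample(
                mixture, depth, design.sample_concentration, r_counts
            )
            count_rows.append((sid, counts))
            lambdas[sid] = lam
            records.append((sid, animal, day, "BS", group))
        # stomach tube at the final day
        sid = f"{animal}D{design.final_day:03d}R"
        mixture = rumen_profile(design.final_day)
        depth = _draw_depth(r_depth, design)
        counts = simulate_sample(
            mixture, depth, design.sample_concentration, r_counts
        )
        count_rows.append((sid, counts))
        lambdas[sid] = 1.0
        records.append((sid, animal, design.final_day, "R", group))

    table = FeatureTable(
        pd.DataFrame(
            np.vstack([c for _, c in count_rows]),
            index=[s for s, _ in count_rows],
            columns=base.otu_ids,
        ),
        "counts",
    )

    meta_df = pd.DataFrame(
        records, columns=["sample_id", "animal_id", "day", "method", "weaning_group"]
    ).set_index("sample_id")
    meta_df.index.name = None
    growth_cols: list[str] = []
    if design.include_growth:
        growth_cols = list(GROWTH_VARIABLES)
        per_animal = {}
        scales = {"hip_height": (95, 4), "withers_height": (90, 4),
                  "back_length": (60, 3), "body_length": (110, 5),
                  "heart_girth": (105, 5), "live_weight_gain": (0.85, 0.12)}
        for animal in animals:
            # early weaning slightly depresses growth, as weaned calves
            # transiently eat less
            shift = -0.3 if group_of[animal] == "earlyC" else 0.0
            per_animal[animal] = {
                v: scales[v][0] + scales[v][1] * (r_design.normal() + shift)
                for v in growth_cols
            }
        for v in growth_cols:
            meta_df[v] = [per_animal[a][v] for a in meta_df["animal_id"]]
    meta = SampleMetadata(meta_df, growth_columns=growth_cols)

    # taxonomy with drawn confidences; a configurable fraction of OTUs gets a
    # sub-threshold genus confidence to exercise the relabelling rule
    genus_list = sorted(set(base.genus_of_otu))
    genus_pos = {g: i for i, g in enumerate(genus_list)}
    tax_rows = {}
    low_conf = r_conf.uniform(size=len(base.otu_ids)) < design.low_confidence_fraction
    for i, otu in enumerate(base.otu_ids):
        genus = base.genus_of_otu[otu]
        origin = "oral" if genus.startswith("g_oral") else "rumen"
        lineage = _lineage_for(genus, origin, genus_pos[genus])
        row = {}
        for rank, name in lineage.items():
            row[rank] = name
            if rank == "genus" and low_conf[i]:
                row[f"{rank}_conf"] = float(r_conf.uniform(0.50, 0.94))
            else:
                row[f"{rank}_conf"] = float(r_conf.uniform(0.95, 0.999))
        tax_rows[otu] = row
    tax = TaxonomyTable(pd.DataFrame.from_dict(tax_rows, orient="index"))

    truth = TruthLabels(
        genus_origin=base.truth.genus_origin,
        genus_detectable=base.truth.genus_detectable,
        otu_origin=base.truth.otu_origin,
        sample_lambda=pd.Series(lambdas, name="lambda"),
        rumen_shannon=base.truth.rumen_shannon,
    )
    return table, tax, meta, truth


def _draw_depth(rng: np.random.Generator, design: SimulationDesign) -> int:
    sigma = np.sqrt(np.log(1.0 + design.depth_cv**2))
    mu = np.log(design.depth_mean) - sigma**2 / 2.0
    return max(1, int(round(rng.lognormal(mu, sigma))))
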