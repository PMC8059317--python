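"""Diversity, ordination, permutation tests and rank correlations.

All core procedures are implemented directly from their defining formulas:

* Shannon diversity ``H = -sum p_i ln p_i`` (natural log by default).
* Bray-Curtis dissimilarity ``BC(x, y) = sum|x_k - y_k| / sum(x_k + y_k)``.
* Principal coordinates analysis by Gower double-centering
  ``B = -1/2 J D^2 J`` and eigendecomposition; negative eigenvalues are
  reported, not corrected.
* ANOSIM: ``R = (mean between-group rank - mean within-group rank) / (M/2)``
  with ``M = n(n-1)/2`` dissimilarities and mean ranks for ties; permutation
  p-value by random relabelling.
* Mantel test: Pearson (default) or Spearman correlation of the upper
  triangles, permuting one matrix's sample labels jointly over rows and
  columns.
* Kruskal-Wallis with tie correction and Dunn's z post hoc, two-sided
  normal p-values, Benjamini-Hochberg adjustment.

Permutation p-values follow the ``(1 + b) / (1 + m)`` convention where
``b`` counts permuted statistics at least as extreme as the observed one,
so a p-value can never be exactly 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables_io import FeatureTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermTestResult",
    "GroupComparisonResult",
    "shannon",
    "bray_curtis",
    "pcoa",
    "within_group_similarity",
    "anosim",
    "mantel",
    "matched_abundance_spearman",
    "per_taxon_spearman",
    "kruskal_wallis_dunn",
    "bh_adjust",
    "diversity_growth_correlation",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal dissimilarity matrix with sample ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate ids in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValidationError("negative dissimilarity")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def filter(self, ids: list[str]) -> "DistanceMatrix":
        """Sub-matrix restricted (and reordered) to ``ids``."""
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise ValidationError(f"id {missing[0]!r} not in distance matrix")
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    """PCoA coordinates with eigenvalue bookkeeping."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int


@dataclass
class PermTestResult:
    """Outcome of a permutation test (ANOSIM or Mantel)."""

    method: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError("permutation p-value must lie in (0, 1]")


@dataclass
class GroupComparisonResult:
    """Kruskal-Wallis H with Dunn's pairwise post hoc and BH-adjusted p."""

    h_statistic: float
    p_value: float
    df: int
    pairwise: pd.DataFrame  # columns group1, group2, z, p_raw, p_adj
    group_sizes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# diversity and dissimilarity
# ---------------------------------------------------------------------------


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity of one sample (natural log unless ``base`` given)."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative abundance")
    total = x.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples."""
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    x = table.data.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero) >= 2:
        raise ValidationError(
            f"Bray-Curtis undefined between all-zero samples "
            f"{table.sample_ids[zero[0]]!r} and {table.sample_ids[zero[1]]!r}"
        )
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n - 1):
        rest = x[i + 1 :]
        num = np.abs(x[i] - rest).sum(axis=1)
        den = (x[i] + rest).sum(axis=1)
        d[i, i + 1 :] = num / den
    d = d + d.T
    return DistanceMatrix(table.sample_ids, d)


def pcoa(dm: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Coordinates are returned for the ``k`` leading positive eigenvalues
    (all of them when ``k`` is None), scaled by the square root of the
    eigenvalue; proportion explained is computed over positive eigenvalues
    only.
    """
    n = dm.n
    if k is not None and not 1 <= k <= n - 1:
        raise ValidationError(f"k must be in [1, {n - 1}]")
    d2 = dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2  # guard symmetry against round-off
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0]) if n else 0)
    positive = eigvals > tol
    n_negative = int((eigvals < -tol).sum())
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    if k is not None:
        coords = coords[:, :k]
        pos_kept = pos_vals[:k]
    else:
        pos_kept = pos_vals
    prop = pos_kept / pos_vals.sum() if pos_vals.sum() > 0 else np.zeros_like(pos_kept)
    frame = pd.DataFrame(
        coords[:, : len(pos_kept)],
        index=dm.ids,
        columns=[f"PCo{i + 1}" for i in range(len(pos_kept))],
    )
    return OrdinationResult(
        coordinates=frame,
        eigenvalues=pos_kept,
        proportion_explained=prop,
        n_negative_eigenvalues=n_negative,
    )


def within_group_similarity(dm: DistanceMatrix, groups) -> pd.DataFrame:
    """Mean percent similarity ``(1 - d) * 100`` over within-group pairs.

    ``groups`` maps sample id to group; singleton groups are excluded.
    Returns a frame indexed by group with columns ``mean_pct``, ``sd_pct``
    and ``n_pairs``.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    rows = {}
    for g, members in groups.groupby(groups).groups.items():
        members = [m for m in members if m in dm.ids]
        if len(members) < 2:
            import warnings

            warnings.warn(f"within_group_similarity: singleton group {g!r} excluded",
                          stacklevel=2)
            continue
        sub = dm.filter(members)
        sims = (1.0 - sub.condensed()) * 100.0
        rows[g] = {
            "mean_pct": float(sims.mean()),
            "sd_pct": float(sims.std(ddof=1)) if len(sims) > 1 else 0.0,
            "n_pairs": int(len(sims)),
        }
    if not rows:
        raise ValidationError("no group with >= 2 samples")
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------


def _anosim_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    return float((ranks[~within].mean() - ranks[within].mean()) / denom)


def anosim(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> PermTestResult:
    """Analysis of similarities between >= 2 groups of samples.

    The statistic R lies in [-1, 1]; 0 indicates random grouping, 1 that
    all between-group dissimilarities exceed every within-group one.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    labels = groups.reindex(dm.ids)
    if labels.isna().any():
        raise ValidationError("every sample needs a group label")
    labels = labels.to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs at least 2 samples")
    n = dm.n
    iu0, iu1 = np.triu_indices(n, k=1)
    ranks = sps.rankdata(dm.values[iu0, iu1])
    m = len(ranks)
    denom = m / 2.0
    codes = pd.factorize(labels)[0]
    within = codes[iu0] == codes[iu1]
    r_obs = _anosim_r(ranks, within, denom)

    rng = np.random.default_rng(seed)
    at_least = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pc = codes[perm]
        w = pc[iu0] == pc[iu1]
        if _anosim_r(ranks, w, denom) >= r_obs - 1e-12:
            at_least += 1
    p = (1 + at_least) / (1 + n_permutations)
    return PermTestResult("anosim", r_obs, p, n_permutations, seed)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "pearson",
    n_permutations: int = 9999,
    seed: int | None = None,
) -> PermTestResult:
    """Mantel correlation between two distance matrices on the same samples.

    ``dm2`` is aligned to ``dm1``'s id order; the permutation null permutes
    sample labels of the second matrix jointly over rows and columns.  The
    test is one-sided on r >= r_observed (positive association).
    """
    if set(dm1.ids) != set(dm2.ids):
        raise ValidationError("distance matrices cover different sample sets")
    dm2 = dm2.filter(dm1.ids)
    n = dm1.n
    if n < 3:
        raise ValidationError("Mantel test needs at least 3 samples")
    iu0, iu1 = np.triu_indices(n, k=1)
    x = dm1.values[iu0, iu1]
    y_mat = dm2.values
    y = y_mat[iu0, iu1]
    if method == "spearman":
        x = sps.rankdata(x)
    elif method != "pearson":
        raise ValidationError(f"unknown method {method!r}")

    def corr(yv: np.ndarray) -> float:
        if method == "spearman":
            yv = sps.rankdata(yv)
        xm = x - x.mean()
        ym = yv - yv.mean()
        denom = np.sqrt((xm**2).sum() * (ym**2).sum())
        if denom == 0:
            raise ValidationError("constant distance matrix; correlation undefined")
        return float((xm * ym).sum() / denom)

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    at_least = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        ym = y_mat[np.ix_(perm, perm)][iu0, iu1]
        if corr(ym) >= r_obs - 1e-12:
            at_least += 1
    p = (1 + at_least) / (1 + n_permutations)
    return PermTestResult(f"mantel_{method}", r_obs, p, n_permutations, seed)


def enumerate_anosim_p(dm: DistanceMatrix, groups) -> float:
    """Exact ANOSIM p-value by full enumeration of distinct relabellings.

    Intended for small n as an independent check of the permutation
    p-value; the identity assignment is included in the reference set.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    labels = groups.reindex(dm.ids).to_numpy()
    codes = pd.factorize(labels)[0]
    n = dm.n
    iu0, iu1 = np.triu_indices(n, k=1)
    ranks = sps.rankdata(dm.values[iu0, iu1])
    denom = len(ranks) / 2.0
    r_obs = _anosim_r(ranks, codes[iu0] == codes[iu1], denom)
    n_hits = 0
    n_total = 0
    sizes = np.bincount(codes)
    idx = set(range(n))
    # enumerate assignments of samples to the first group (2-group case) or
    # all set partitions with the given sizes via itertools
    assignments = _assignments(sorted(idx), list(sizes))
    for assign in assignments:
        pc = np.empty(n, dtype=int)
        for gi, members in enumerate(assign):
            pc[list(members)] = gi
        w = pc[iu0] == pc[iu1]
        n_total += 1
        if _anosim_r(ranks, w, denom) >= r_obs - 1e-12:
            n_hits += 1
    return n_hits / n_total


def _assignments(pool: list[int], sizes: list[int]):
    if len(sizes) == 1:
        yield (tuple(pool),)
        return
    first_size = sizes[0]
    rest_sizes = sizes[1:]
    for combo in itertools.combinations(pool, first_size):
        remaining = [p for p in pool if p not in combo]
        for rest in _assignments(remaining, rest_sizes):
            yield (combo,) + rest


# ---------------------------------------------------------------------------
# rank correlations
# ---------------------------------------------------------------------------


def _shared_taxa(tableA: FeatureTable, tableB: FeatureTable) -> list[str]:
    shared = [t for t in tableA.taxon_ids if t in set(tableB.taxon_ids)]
    if not shared:
        raise ValidationError("tables share no taxa")
    return shared


def matched_abundance_spearman(
    tableA: FeatureTable,
    tableB: FeatureTable,
    pairing: dict,
    pooling: str = "pairs",
) -> tuple[float, float]:
    """Spearman correlation of abundances between matched samples.

    ``pairing`` maps a sample id of ``tableA`` to its partner in ``tableB``
    (same animal sampled by the other method or at the reference day).
    With ``pooling="pairs"`` (default) all (taxon, matched pair) abundance
    pairs are pooled into a single rank correlation; ``pooling="taxon_means"``
    first averages each taxon over the matched samples of each table and
    correlates the per-taxon means.  Returns ``(R, p)``.
    """
    taxa = _shared_taxa(tableA, tableB)
    pairs = [
        (a, b)
        for a, b in pairing.items()
        if a in tableA.data.index and b in tableB.data.index
    ]
    if not pairs:
        raise ValidationError("no matched samples between the two tables")
    a_ids = [a for a, _ in pairs]
    b_ids = [b for _, b in pairs]
    A = tableA.data.loc[a_ids, taxa].to_numpy()
    B = tableB.data.loc[b_ids, taxa].to_numpy()
    if pooling == "pairs":
        r, p = sps.spearmanr(A.ravel(), B.ravel())
    elif pooling == "taxon_means":
        r, p = sps.spearmanr(A.mean(axis=0), B.mean(axis=0))
    else:
        raise ValidationError(f"unknown pooling {pooling!r}")
    return float(r), float(p)


def per_taxon_spearman(
    tableA: FeatureTable,
    tableB: FeatureTable,
    pairing: dict,
    min_pairs: int = 3,
) -> tuple[pd.Series, float]:
    """Per-taxon Spearman R across matched samples, plus the mean R.

    A taxon needs at least ``min_pairs`` matched samples and non-constant
    abundances in both tables; otherwise its R is NaN and it is excluded
    from the mean.
    """
    taxa = _shared_taxa(tableA, tableB)
    pairs = [
        (a, b)
        for a, b in pairing.items()
        if a in tableA.data.index and b in tableB.data.index
    ]
    if not pairs:
        raise ValidationError("no matched samples between the two tables")
    a_ids = [a for a, _ in pairs]
    b_ids = [b for _, b in pairs]
    A = tableA.data.loc[a_ids, taxa].to_numpy()
    B = tableB.data.loc[b_ids, taxa].to_numpy()
    out = pd.Series(np.nan, index=pd.Index(taxa), dtype=float)
    for j, taxon in enumerate(taxa):
        a, b = A[:, j], B[:, j]
        if len(a) < min_pairs or np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        out[taxon] = sps.spearmanr(a, b)[0]
    defined = out.dropna()
    mean_r = float(defined.mean()) if len(defined) else float("nan")
    return out, mean_r


def diversity_growth_correlation(
    alpha_values: pd.Series,
    growth: pd.DataFrame,
    min_pairs: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman matrix between alpha diversity and body-growth variables.

    ``alpha_values`` is indexed by animal; ``growth`` holds one numeric
    column per growth variable, same index.  Cells with fewer than
    ``min_pairs`` complete observations are NaN.  Returns ``(R, p)``
    matrices over all variables (diversity first).
    """
    df = pd.concat([alpha_values.rename("shannon"), growth], axis=1)
    cols = list(df.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            sub = df[[cols[i], cols[j]]].dropna()
            if len(sub) < min_pairs:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            rv, pv = sps.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
            r.iloc[i, j] = r.iloc[j, i] = rv
            p.iloc[i, j] = p.iloc[j, i] = pv
    return r, p


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Dunn / Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone in raw-p order)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def kruskal_wallis_dunn(values, groups, alpha: float = 0.05) -> GroupComparisonResult:
    """Kruskal-Wallis test with Dunn's post hoc and BH-adjusted pairwise p.

    ``values`` and ``groups`` are parallel sequences (or a Series pair).
    Ties are handled by mean ranks; H uses the tie correction
    ``C = 1 - sum(t^3 - t) / (N^3 - N)`` and Dunn's z the pooled tie term.
    """
    values = np.asarray(pd.Series(values), dtype=float)
    groups = np.asarray(pd.Series(groups))
    if len(values) != len(groups):
        raise ValidationError("values and groups differ in length")
    uniq, codes = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = uniq[sizes < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")
    if np.ptp(values) == 0:
        raise ValidationError("all values identical; test undefined")
    n_total = len(values)
    ranks = sps.rankdata(values)
    mean_ranks = np.array([ranks[codes == g].mean() for g in range(len(uniq))])
    h = (12.0 / (n_total * (n_total + 1))) * float(
        (sizes * mean_ranks**2).sum()
    ) - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_sum = float(((tie_counts**3) - tie_counts).sum())
    c = 1.0 - tie_sum / (n_total**3 - n_total)
    h /= c
    df = len(uniq) - 1
    p_global = float(sps.chi2.sf(h, df))

    tie_term = tie_sum / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * float(sps.norm.sf(abs(z)))
            rows.append(
                {"group1": uniq[i], "group2": uniq[j], "z": float(z),
                 "p_raw": min(p_raw, 1.0)}
            )
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = bh_adjust(pairwise["p_raw"].to_numpy())
    pairwise["significant"] = pairwise["p_adj"] < alpha
    return GroupComparisonResult(
        h_statistic=float(h),
        p_value=p_global,
        df=df,
        pairwise=pairwise,
        group_sizes={str(u): int(s) for u, s in zip(uniq, sizes)},
    )
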