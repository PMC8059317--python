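"""Readers, writers and containers for the three study tables.

The pipeline operates on three aligned tables: an OTU/feature count table
(samples x taxa), a per-OTU taxonomy with rank-resolved confidences, and
per-sample metadata (animal, day of life, sampling method, weaning group,
optional body-growth measurements).

File conventions
----------------
* Feature table: UTF-8 TSV, samples as rows, taxa as columns, first header
  cell ``#SampleID`` (QIIME mapping-file convention).  A minimal dense
  BIOM-JSON dialect is also supported.
* Taxonomy: one row per taxon, a semicolon-delimited lineage with rank
  prefixes (``p__``, ``c__``, ``o__``, ``f__``, ``g__``) and the classifier
  confidence in parentheses, e.g. ``p__Bacteroidetes(0.99); g__Prevotella(0.96)``.
  Standard lineage strings carry no per-rank confidences, which the
  confidence-threshold relabelling step needs, hence this dialect.
* Metadata: TSV with columns ``sample_id``, ``animal_id``, ``day``,
  ``method`` (BS = buccal swab, R = stomach tube), ``weaning_group``
  (earlyC / lateC) and optional numeric growth columns.

Writers emit a single ``# `` provenance comment line; readers skip such
lines.
"""

from __future__ import annotations

import io
import json
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RANKS",
    "FeatureTable",
    "TaxonomyTable",
    "SampleMetadata",
    "ValidationError",
    "ParseError",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "align_tables",
]

#: Taxonomic ranks handled by the pipeline, shallowest first.
RANKS = ("phylum", "class", "order", "family", "genus")
_RANK_PREFIX = {"phylum": "p", "class": "c", "order": "o", "family": "f", "genus": "g"}
_PREFIX_RANK = {v: k for k, v in _RANK_PREFIX.items()}

#: Admissible categorical vocabularies for the metadata table.
METHODS = ("BS", "R")
WEANING_GROUPS = ("earlyC", "lateC")

_PROVENANCE = "# swabpartition table"


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed into a table."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """A samples x taxa abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with taxon ids as columns.  Values are
        non-negative counts (``mode="counts"``) or per-sample proportions
        summing to 1 (``mode="relative"``).
    mode:
        ``"counts"`` or ``"relative"``.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.data.shape[0] == 0:
            raise ValidationError("no samples")
        if self.data.shape[1] == 0:
            raise ValidationError("no taxa")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate taxon id {dup!r}")
        values = self.data.to_numpy()
        if np.isnan(values).any():
            raise ValidationError("missing entries in feature table")
        if (values < 0).any():
            raise ValidationError("negative abundance in feature table")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
                raise ValidationError(
                    f"relative table rows must sum to 1; sample {bad!r} sums to "
                    f"{sums[np.argmax(np.abs(sums - 1.0))]:.6g}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.mode)


@dataclass
class TaxonomyTable:
    """Per-taxon lineage with per-rank classifier confidences.

    ``data`` is indexed by taxon id and holds, per rank in :data:`RANKS`, a
    name column (NaN = unassigned) and a ``<rank>_conf`` column in [0, 1]
    (NaN where the name is unassigned).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = [c for r in RANKS for c in (r, f"{r}_conf")]
        for c in cols:
            if c not in self.data.columns:
                raise ValidationError(f"taxonomy table missing column {c!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate taxon id {dup!r}")
        for rank in RANKS:
            conf = self.data[f"{rank}_conf"]
            bad = conf.dropna()
            if ((bad < 0) | (bad > 1)).any():
                taxon = bad[(bad < 0) | (bad > 1)].index[0]
                raise ValidationError(
                    f"confidence out of [0, 1] at rank {rank!r} for taxon {taxon!r}"
                )
            named = self.data[rank].notna()
            if (named & conf.isna()).any():
                taxon = self.data.index[named & conf.isna()][0]
                raise ValidationError(
                    f"name without confidence at rank {rank!r} for taxon {taxon!r}"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    def labels_at(self, rank: str) -> pd.Series:
        """Rank labels with unassigned entries mapped to ``"unassigned"``."""
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}")
        return self.data[rank].fillna("unassigned")

    def copy(self) -> "TaxonomyTable":
        return TaxonomyTable(self.data.copy())


@dataclass
class SampleMetadata:
    """Per-sample annotations, indexed by sample id.

    Required columns: ``animal_id``, ``day`` (days of life), ``method``
    (BS/R) and ``weaning_group`` (earlyC/lateC).  Any further numeric
    columns are treated as growth variables.
    """

    data: pd.DataFrame
    growth_columns: list[str] = field(default_factory=list)

    REQUIRED = ("animal_id", "day", "method", "weaning_group")

    def __post_init__(self) -> None:
        self.data = self.data.copy()  # the day column is coerced in place
        for c in self.REQUIRED:
            if c not in self.data.columns:
                raise ValidationError(f"metadata missing column {c!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        bad_method = set(self.data["method"]) - set(METHODS)
        if bad_method:
            raise ValidationError(
                f"unknown method value(s) {sorted(bad_method)}; admissible: {list(METHODS)}"
            )
        bad_group = set(self.data["weaning_group"]) - set(WEANING_GROUPS)
        if bad_group:
            raise ValidationError(
                f"unknown weaning_group value(s) {sorted(bad_group)}; "
                f"admissible: {list(WEANING_GROUPS)}"
            )
        self.data["day"] = self.data["day"].astype(int)
        # Stomach tubing was only performed on the oldest animals in the
        # study design; other combinations are suspicious but not fatal.
        odd = (self.data["method"] == "R") & (self.data["day"] != 140)
        if odd.any():
            warnings.warn(
                f"{int(odd.sum())} stomach-tube (R) sample(s) at day != 140",
                stacklevel=2,
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching all equality ``column=value`` conditions."""
        mask = pd.Series(True, index=self.data.index)
        for col, value in conditions.items():
            mask &= self.data[col] == value
        return list(self.data.index[mask])

    def copy(self) -> "SampleMetadata":
        return SampleMetadata(self.data.copy(), list(self.growth_columns))


# ---------------------------------------------------------------------------
# feature table I/O
# ---------------------------------------------------------------------------


def _read_text_skipping_comments(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("# ")]
    return "".join(lines)


def read_feature_table(path, dialect: str = "tsv") -> FeatureTable:
    """Read a feature table from ``path``.

    ``dialect="tsv"`` expects samples as rows and taxa as columns with a
    ``#SampleID`` leading header cell; ``dialect="biom_json"`` expects the
    minimal dense BIOM-JSON layout (observations as rows) and transposes it
    to samples x taxa.
    """
    if dialect == "tsv":
        text = _read_text_skipping_comments(path)
        if not text.strip():
            raise ValidationError("no samples")
        try:
            df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"could not parse {path}: {exc}") from exc
        if df.shape[0] == 0:
            raise ValidationError("no samples")
        df.index = df.index.astype(str)
        df.index.name = None
        numeric = df.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            col = numeric.columns[numeric.isna().any()][0]
            row = numeric.index[numeric[col].isna()][0]
            raise ParseError(
                f"malformed numeric cell at sample {row!r}, taxon {col!r}"
            )
        mode = _infer_mode(numeric.to_numpy())
        return FeatureTable(numeric, mode=mode)
    if dialect == "biom_json":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise ParseError("only the dense BIOM-JSON dialect is supported")
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        if not samples:
            raise ValidationError("no samples")
        values = np.asarray(doc["data"], dtype=float)
        if values.shape != (len(taxa), len(samples)):
            raise ParseError(
                f"BIOM data shape {values.shape} does not match "
                f"{len(taxa)} observations x {len(samples)} samples"
            )
        df = pd.DataFrame(values.T, index=samples, columns=taxa)
        mode = doc.get("swabpartition_mode") or _infer_mode(df.to_numpy())
        return FeatureTable(df, mode=mode)
    raise ValidationError(f"unknown dialect {dialect!r}")


def _infer_mode(values: np.ndarray) -> str:
    return "counts" if np.allclose(values, np.round(values)) else "relative"


def write_feature_table(table: FeatureTable, path, dialect: str = "tsv") -> None:
    """Write ``table`` to ``path`` in the given dialect (see reader)."""
    if dialect == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{_PROVENANCE} mode={table.mode}\n")
            fh.write("#SampleID\t" + "\t".join(map(str, table.taxon_ids)) + "\n")
            for sid, row in table.data.iterrows():
                fh.write(str(sid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
        return
    if dialect == "biom_json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "swabpartition",
            "matrix_type": "dense",
            "matrix_element_type": "float" if table.mode == "relative" else "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.data.to_numpy().T.tolist(),
            "swabpartition_mode": table.mode,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
        return
    raise ValidationError(f"unknown dialect {dialect!r}")


def _fmt(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


# ---------------------------------------------------------------------------
# taxonomy I/O
# ---------------------------------------------------------------------------

_RANK_TOKEN = re.compile(r"^([pcofg])__(.+)\(([^()]+)\)$")


def read_taxonomy(path) -> TaxonomyTable:
    """Read a rank-prefixed, confidence-annotated taxonomy TSV."""
    records: dict[str, dict[str, object]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("# ") or not line.strip():
                continue
            if line.startswith("#"):  # header line
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'taxon_id<TAB>lineage'")
            taxon_id, lineage = parts
            row: dict[str, object] = {}
            for r in RANKS:
                row[r] = np.nan
                row[f"{r}_conf"] = np.nan
            for token in lineage.split(";"):
                token = token.strip()
                if not token:
                    continue
                m = _RANK_TOKEN.match(token)
                if m is None:
                    raise ParseError(f"{path}:{lineno}: malformed rank token {token!r}")
                prefix, name, conf_str = m.groups()
                rank = _PREFIX_RANK[prefix]
                try:
                    conf = float(conf_str)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: bad confidence {conf_str!r}"
                    ) from exc
                if not 0.0 <= conf <= 1.0:
                    raise ValidationError(
                        f"{path}:{lineno}: confidence {conf} outside [0, 1]"
                    )
                row[rank] = name
                row[f"{rank}_conf"] = conf
            if taxon_id in records:
                raise ValidationError(f"duplicate taxon id {taxon_id!r}")
            records[taxon_id] = row
    if not records:
        raise ValidationError("empty taxonomy table")
    df = pd.DataFrame.from_dict(records, orient="index")
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_PROVENANCE} taxonomy\n")
        for taxon_id, row in tax.data.iterrows():
            tokens = []
            for rank in RANKS:
                name = row[rank]
                if pd.isna(name):
                    continue
                conf = float(row[f"{rank}_conf"])
                tokens.append(f"{_RANK_PREFIX[rank]}__{name}({conf:.6g})")
            fh.write(f"{taxon_id}\t" + "; ".join(tokens) + "\n")


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------


def read_metadata(path) -> SampleMetadata:
    """Read the sample metadata TSV (see module docstring for columns)."""
    text = _read_text_skipping_comments(path)
    if not text.strip():
        raise ValidationError("empty metadata table")
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    id_col = "SampleID" if "SampleID" in df.columns else "sample_id"
    if id_col not in df.columns:
        raise ValidationError("metadata missing column 'sample_id'")
    df = df.set_index(id_col)
    df.index.name = None
    required = set(SampleMetadata.REQUIRED)
    growth_cols = [c for c in df.columns if c not in required]
    for c in growth_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if "day" in df.columns:
        try:
            df["day"] = df["day"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-integer day value: {exc}") from exc
    return SampleMetadata(df, growth_columns=growth_cols)


def write_metadata(meta: SampleMetadata, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_PROVENANCE} metadata\n")
        cols = list(SampleMetadata.REQUIRED) + meta.growth_columns
        fh.write("sample_id\t" + "\t".join(cols) + "\n")
        for sid, row in meta.data.iterrows():
            cells = [str(sid)]
            for c in cols:
                v = row[c]
                cells.append("" if pd.isna(v) else (_fmt(v) if isinstance(v, float) else str(v)))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def align_tables(
    table: FeatureTable, tax: TaxonomyTable, meta: SampleMetadata
) -> tuple[FeatureTable, TaxonomyTable, SampleMetadata]:
    """Restrict the three tables to their shared identifiers.

    Samples are intersected between the feature table and metadata, taxa
    between the feature table and taxonomy.  Ordering follows sorted
    identifiers so the result is invariant to input ordering.  Dropped ids
    are logged.  Raises :class:`ValidationError` on an empty intersection.
    """
    samples = sorted(set(table.sample_ids) & set(meta.sample_ids))
    taxa = sorted(set(table.taxon_ids) & set(tax.taxon_ids))
    if not samples:
        raise ValidationError("no samples shared between feature table and metadata")
    if not taxa:
        raise ValidationError("no taxa shared between feature table and taxonomy")
    dropped_s = (set(table.sample_ids) | set(meta.sample_ids)) - set(samples)
    dropped_t = (set(table.taxon_ids) | set(tax.taxon_ids)) - set(taxa)
    if dropped_s:
        logger.info("align_tables: dropping %d unmatched sample id(s): %s",
                    len(dropped_s), sorted(dropped_s)[:10])
    if dropped_t:
        logger.info("align_tables: dropping %d unmatched taxon id(s)", len(dropped_t))
    new_table = FeatureTable(table.data.loc[samples, taxa], table.mode)
    new_tax = TaxonomyTable(tax.data.loc[taxa])
    new_meta = SampleMetadata(meta.data.loc[samples], list(meta.growth_columns))
    return new_table, new_tax, new_meta
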