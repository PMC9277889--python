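"""Readers and writers for the external representations of the pipeline.

The canonical interchange formats are plain TSV (feature tables, metadata,
sibship records) and newick (phylogenies).  A BIOM-JSON reader is provided
for interoperability with the wider 16S ecosystem but is not canonical.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

COMPARTMENTS = ("airway", "gut")

DAYS_PER_YEAR = 365.25


class ParseError(ValueError):
    """Malformed file content (bad header, unbalanced newick, empty file)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a domain invariant."""


class SchemaError(ValueError):
    """Metadata table missing mandatory columns or containing unknown enums."""


def years_between(earlier: date, later: date) -> float:
    """Signed difference ``later - earlier`` in years (exact days / 365.25)."""
    return (later - earlier).days / DAYS_PER_YEAR


def _parse_date(value: str, row: int | None = None) -> date:
    try:
        return datetime.strptime(str(value).strip(), "%Y-%m-%d").date()
    except ValueError as exc:
        where = f" at row {row}" if row is not None else ""
        raise ParseError(f"unparseable ISO-8601 date {value!r}{where}") from exc


@dataclass
class FeatureTable:
    """Samples x ASVs count matrix with optional taxonomy and sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix; rows are samples, columns are ASVs.
    taxonomy : dict, optional
        Map ``asv_id -> ranked lineage`` (list of strings, domain..genus).
    sample_meta : pandas.DataFrame, optional
        Indexed by sample_id with at least ``child_id``, ``compartment``,
        and a visit identifier (``visit_age_label`` and/or ``collection_date``).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, list[str]] | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at sample {c.index[bad[0]]!r}, "
                    f"ASV {c.columns[bad[1]]!r}"
                )
            self.counts = c = c.round().astype(np.int64)
            arr = c.to_numpy()
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {c.index[bad[0]]!r}, "
                f"ASV {c.columns[bad[1]]!r}"
            )
        if self.sample_meta is not None:
            missing = c.index.difference(self.sample_meta.index)
            if len(missing):
                raise ValidationError(
                    f"samples without metadata: {missing.tolist()[:5]}"
                )

    # -- convenience ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def asv_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        depths = self.depths.replace(0, np.nan)
        return self.counts.div(depths, axis=0).fillna(0.0)

    def subset(self, sample_ids) -> "FeatureTable":
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[list(sample_ids)]
        return FeatureTable(self.counts.loc[list(sample_ids)],
                            taxonomy=self.taxonomy, sample_meta=meta)


# ---------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------

def read_feature_table(path, format: str = "tsv",
                       taxonomy_path=None, metadata_path=None) -> FeatureTable:
    """Read a samples x ASVs count table.

    TSV dialect: first column sample_id, header row ASV ids, integer cells.
    ``biom_json`` reads the dense or sparse BIOM v1 (JSON) dialect.
    """
    path = Path(path)
    if format == "tsv":
        counts = _read_counts_tsv(path)
    elif format == "biom_json":
        counts = _read_counts_biom_json(path)
    else:
        raise ValueError(f"unknown feature-table format {format!r}")
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
    meta = read_metadata(metadata_path)[0] if metadata_path else None
    return FeatureTable(counts, taxonomy=taxonomy, sample_meta=meta)


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty feature-table file")
    header = text.splitlines()[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: header must name at least one ASV")
    try:
        df = pd.read_csv(_stdio.StringIO(text), sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path}: non-numeric count at sample {bad.index[0]!r}, "
                f"ASV {col!r}: {bad.iloc[0]!r}")
    arr = df.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValidationError(
            f"{path}: non-integer count at sample {df.index[i]!r}, "
            f"ASV {df.columns[j]!r}")
    if arr.size and arr.min() < 0:
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{path}: negative count at sample {df.index[i]!r}, "
            f"ASV {df.columns[j]!r}")
    return df.astype(np.int64)


def _read_counts_biom_json(path: Path) -> pd.DataFrame:
    obj = json.loads(Path(path).read_text())
    sample_ids = [c["id"] for c in obj["columns"]]
    asv_ids = [r["id"] for r in obj["rows"]]
    mat = np.zeros((len(asv_ids), len(sample_ids)))
    if obj.get("matrix_type") == "sparse":
        for r, c, v in obj["data"]:
            mat[r, c] = v
    else:
        mat = np.asarray(obj["data"], dtype=float)
    # BIOM is observations x samples; our convention is samples x ASVs
    return pd.DataFrame(mat.T, index=sample_ids, columns=asv_ids).astype(np.int64)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------

def read_newick(path_or_handle, missing_length: str = "zero") -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    Missing branch lengths are treated as 0 by default (``missing_length=
    'zero'``); pass ``'error'`` to reject them.
    """
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
    else:
        text = Path(path_or_handle).read_text()
    if not text.strip():
        raise ParseError("empty newick file")
    if text.count("(") != text.count(")"):
        raise ParseError("unbalanced parentheses in newick string")
    try:
        tree = TreeNode.read(_stdio.StringIO(text))
    except Exception as exc:
        raise ParseError(f"newick parse failure: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if missing_length == "error":
                raise ValidationError(f"missing branch length on {node.name!r}")
            node.length = 0.0
        if not np.isfinite(node.length) or node.length < 0:
            raise ValidationError(
                f"non-finite or negative branch length on {node.name!r}")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValidationError("duplicate tip labels in tree")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------
# metadata / sibship / outcomes
# ---------------------------------------------------------------------

MANDATORY_META_COLS = ("sample_id", "child_id", "compartment")


def read_metadata(path):
    """Read per-sample metadata; returns ``(sample_meta, extra_covariates)``.

    Mandatory columns: sample_id, child_id, compartment and at least one of
    visit_age_label / collection_date.  Unknown columns are preserved as
    opaque covariates (empty cell = missing; complete-case handling is the
    responsibility of each downstream operation).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANDATORY_META_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata missing mandatory columns: {missing}")
    if "visit_age_label" not in df.columns and "collection_date" not in df.columns:
        raise SchemaError(
            "metadata needs visit_age_label or collection_date")
    bad = ~df["compartment"].isin(COMPARTMENTS)
    if bad.any():
        val = df.loc[bad, "compartment"].iloc[0]
        raise SchemaError(f"unknown compartment {val!r} "
                          f"(expected one of {COMPARTMENTS})")
    if "collection_date" in df.columns:
        parsed = []
        for i, v in enumerate(df["collection_date"], start=2):
            parsed.append(None if pd.isna(v) or v == "" else _parse_date(v, row=i))
        df["collection_date"] = parsed
    df = df.set_index("sample_id")
    known = {"child_id", "compartment", "visit_age_label", "collection_date"}
    covariates = [c for c in df.columns if c not in known]
    return df, covariates


def read_sibships(path) -> pd.DataFrame:
    """Read sibship records: one row per sibling.

    Columns: child_id, child_birth_date, sibling_birth_date, sibling_sex.
    Children with no siblings appear with empty sibling columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"child_id", "child_birth_date"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"sibship table missing columns: {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        rec["child_birth_date"] = _parse_date(rec["child_birth_date"], row=i)
        sb = rec.get("sibling_birth_date")
        rec["sibling_birth_date"] = (
            None if sb is None or pd.isna(sb) or sb == "" else _parse_date(sb, row=i))
        sx = rec.get("sibling_sex")
        if sx is not None and not pd.isna(sx) and sx != "":
            if sx not in ("male", "female"):
                raise SchemaError(f"row {i}: unknown sibling sex {sx!r}")
        else:
            rec["sibling_sex"] = None
        out.append(rec)
    return pd.DataFrame(out)


def write_run_report(report: dict, path) -> None:
    """Machine-readable JSON run report (seeds, parameters, headline numbers)."""
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (date, datetime)):
        return obj.isoformat()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_distance_matrix(path):
    """Square TSV with sample ids as header and first column."""
    from skbio import DistanceMatrix
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_distance_matrix(dm, path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> dict[str, list[str]]:
    """TSV with columns asv_id, lineage (semicolon-separated domain..genus)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"asv_id", "lineage"} <= set(df.columns):
        raise SchemaError("taxonomy table needs columns asv_id, lineage")
    return {r.asv_id: [x.strip() for x in r.lineage.split(";")]
            for r in df.itertuples(index=False)}


def write_taxonomy(taxonomy: dict[str, list[str]], path) -> None:
    rows = [{"asv_id": k, "lineage": ";".join(v)} for k, v in taxonomy.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
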