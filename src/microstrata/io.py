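"""Readers and writers for the tabular formats the pipeline touches.

ASV tables travel as TSV (first column ``sample_id``, remaining columns ASV
identifiers) or as BIOM-format v1.0 JSON (dense or sparse). Metadata and
taxonomy are TSV with fixed headers; taxonomy lineages are accepted either
as seven rank columns or as one semicolon-delimited ``lineage`` string.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    METADATA_COLUMNS,
    RAW_COUNTS,
    TAXONOMY_RANKS,
    AsvTable,
    TaxonomyTable,
    ValidationError,
    validate_metadata,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ASV table
# ---------------------------------------------------------------------------

def read_asv_table(path: str | Path, format: str = "tsv") -> AsvTable:
    """Read a samples x ASVs count table; returns raw counts.

    Raises :class:`ParseError` naming the offending row/column on malformed
    input.
    """
    if format == "tsv":
        return _read_asv_tsv(path)
    if format == "biom":
        return _read_asv_biom(path)
    raise ValueError(f"unknown ASV table format {format!r}")


def _read_asv_tsv(path: str | Path) -> AsvTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no samples (empty file)")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: header must contain sample_id plus ASV columns")
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no samples")
    sample_ids = df["sample_id"].astype(str).tolist()
    asv_ids = list(df.columns[1:])
    body = df.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(asv_ids):
        parsed = pd.to_numeric(body[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            i = bad[0]
            raise ParseError(
                f"{path}: non-numeric value {body[col].iloc[i]!r} at "
                f"row {sample_ids[i]!r}, column {col!r}"
            )
        values[:, j] = parsed.to_numpy()
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ParseError(
            f"{path}: negative value at row {sample_ids[i]!r}, column {asv_ids[j]!r}"
        )
    try:
        return AsvTable(sample_ids, asv_ids, values, RAW_COUNTS)
    except ValidationError as e:
        raise ParseError(f"{path}: {e}") from e


def write_asv_table(table: AsvTable, path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        df = table.to_dataframe()
        # keep integer look for counts
        if table.value_kind == RAW_COUNTS and np.allclose(df.values % 1, 0):
            df = df.astype(int)
        df.to_csv(path, sep="\t", index=True, index_label="sample_id")
    elif format == "biom":
        _write_asv_biom(table, path)
    else:
        raise ValueError(f"unknown ASV table format {format!r}")


def _read_asv_biom(path: str | Path) -> AsvTable:
    """Minimal BIOM v1.0 (JSON) reader, dense or sparse matrix_type."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: invalid BIOM JSON ({e})")
    try:
        asv_ids = [str(r["id"]) for r in doc["rows"]]
        sample_ids = [str(c["id"]) for c in doc["columns"]]
        n_obs, n_samp = doc["shape"]
        mtype = doc["matrix_type"]
        data = doc["data"]
    except KeyError as e:
        raise ParseError(f"{path}: missing BIOM field {e}")
    if (n_obs, n_samp) != (len(asv_ids), len(sample_ids)):
        raise ParseError(f"{path}: BIOM shape mismatch")
    if n_samp == 0:
        raise ParseError(f"{path}: no samples")
    # BIOM is observations x samples; transpose to sample-major
    mat = np.zeros((n_obs, n_samp), dtype=float)
    if mtype == "dense":
        mat[:] = np.asarray(data, dtype=float)
    elif mtype == "sparse":
        for i, j, v in data:
            mat[int(i), int(j)] = float(v)
    else:
        raise ParseError(f"{path}: unsupported matrix_type {mtype!r}")
    if np.any(mat < 0):
        raise ParseError(f"{path}: negative value in BIOM data")
    return AsvTable(sample_ids, asv_ids, mat.T, RAW_COUNTS)


def _write_asv_biom(table: AsvTable, path: str | Path) -> None:
    obs = table.values.T  # observations x samples
    ii, jj = np.nonzero(obs)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "microstrata",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [table.n_asvs, table.n_samples],
        "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [[int(i), int(j), float(obs[i, j])] for i, j in zip(ii, jj)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path, max_timepoint: int = 4) -> pd.DataFrame:
    """Read and validate a sample metadata TSV."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty metadata file")
    df = df.replace({"": None})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing required columns {missing}")
    return validate_metadata(df, max_timepoint=max_timepoint)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out["oscorad"] = out["oscorad"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    out["filaggrin_mutation"] = out["filaggrin_mutation"].map(
        lambda v: "" if pd.isna(v) else str(bool(v))
    )
    out["timepoint"] = out["timepoint"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["is_negative_control"] = out["is_negative_control"].map(lambda v: str(bool(v)))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV: asv_id plus rank columns, or a 'lineage' column
    of semicolon-delimited ranks (domain;phylum;...;species)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty taxonomy file")
    if "asv_id" not in df.columns:
        raise ParseError(f"{path}: taxonomy missing 'asv_id' column")
    df = df.set_index("asv_id")
    if "lineage" in df.columns:
        ranks = df["lineage"].str.split(";", expand=True).reindex(
            columns=range(len(TAXONOMY_RANKS))
        )
        ranks.columns = list(TAXONOMY_RANKS)
        ranks = ranks.fillna("").apply(lambda c: c.str.strip())
        return TaxonomyTable(ranks)
    present = [c for c in TAXONOMY_RANKS if c in df.columns]
    if not present:
        raise ParseError(
            f"{path}: taxonomy needs rank columns {TAXONOMY_RANKS[:6]} or a "
            f"'lineage' column"
        )
    return TaxonomyTable(df[present])


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.lineages.to_csv(path, sep="\t", index=True, index_label="asv_id")
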