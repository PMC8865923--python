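"""Core domain types: ASV count tables, sample metadata, taxonomy.

Orientation is fixed package-wide: samples are rows, ASVs are columns.
An ASV is "detected" in a sample iff its raw count is > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
TRANSFORMED_RELABUND = "transformed_relabund"
VALUE_KINDS = (RAW_COUNTS, TRANSFORMED_RELABUND)

COHORTS = ("AD", "HC")
SKIN_STATUSES = ("HC", "NLS", "LS")
DEPTHS = ("surface", "within")
BODY_LOCATIONS = (
    "volar_forearm",
    "back",
    "elbow_crease",
    "inguinal",
    "leg",
    "neck",
    "wrist",
)
TIMEPOINT_RANGE = (1, 4)

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

METADATA_COLUMNS = (
    "sample_id",
    "participant_id",
    "cohort",
    "skin_status",
    "depth",
    "timepoint",
    "body_location",
    "oscorad",
    "filaggrin_mutation",
    "is_negative_control",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AsvTable:
    """Samples x ASVs abundance matrix.

    Parameters
    ----------
    sample_ids : list of str
        Row identifiers, unique.
    asv_ids : list of str
        Column identifiers, unique.
    values : ndarray of shape (n_samples, n_asvs)
        Non-negative counts or transformed relative abundances.
    value_kind : str
        ``"raw_counts"`` or ``"transformed_relabund"``.
    """

    sample_ids: list[str]
    asv_ids: list[str]
    values: np.ndarray
    value_kind: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise ValidationError("duplicate ASV identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite values in table")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value at sample {self.sample_ids[i]!r}, "
                f"ASV {self.asv_ids[j]!r}"
            )
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == TRANSFORMED_RELABUND:
            rowsums = self.values.sum(axis=1)
            bad = np.flatnonzero((rowsums > 0) & (np.abs(rowsums - 1.0) > 1e-9))
            if bad.size:
                raise ValidationError(
                    f"transformed rows must sum to 1; sample "
                    f"{self.sample_ids[bad[0]]!r} sums to {rowsums[bad[0]]}"
                )

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(self.asv_ids),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_kind: str = RAW_COUNTS) -> "AsvTable":
        return cls(
            sample_ids=list(map(str, df.index)),
            asv_ids=list(map(str, df.columns)),
            values=df.to_numpy(dtype=float),
            value_kind=value_kind,
        )

    def detected(self) -> np.ndarray:
        """Boolean detection matrix (value > 0)."""
        return self.values > 0

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_index(sample_id)]

    # -- subsetting -------------------------------------------------------

    def subset_samples(self, keep: list[str]) -> "AsvTable":
        """Restrict to the given samples, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        idx = [pos[s] for s in keep]
        return replace(self, sample_ids=list(keep), values=self.values[idx])

    def subset_asvs(self, keep: list[str]) -> "AsvTable":
        pos = {a: j for j, a in enumerate(self.asv_ids)}
        missing = [a for a in keep if a not in pos]
        if missing:
            raise KeyError(f"ASVs not in table: {missing[:5]}")
        idx = [pos[a] for a in keep]
        return replace(self, asv_ids=list(keep), values=self.values[:, idx])

    def drop_asvs(self, drop: set[str]) -> "AsvTable":
        keep = [a for a in self.asv_ids if a not in drop]
        return self.subset_asvs(keep)


@dataclass
class TaxonomyTable:
    """ASV -> ranked lineage (domain..species); unassigned ranks are ''. """

    lineages: pd.DataFrame  # index asv_id, columns TAXONOMY_RANKS

    def __post_init__(self) -> None:
        df = self.lineages.copy()
        for rank in TAXONOMY_RANKS:
            if rank not in df.columns:
                df[rank] = ""
        df = df[list(TAXONOMY_RANKS)].fillna("").astype(str)
        df.index = df.index.astype(str)
        df.index.name = "asv_id"
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate taxonomy entry for ASV {dup!r}")
        self.lineages = df

    def covers(self, asv_ids: list[str]) -> list[str]:
        """Return ASVs from `asv_ids` lacking a taxonomy entry."""
        have = set(self.lineages.index)
        return [a for a in asv_ids if a not in have]

    def genus_of(self, asv_id: str) -> str:
        g = self.lineages.at[asv_id, "genus"]
        return g if g else "unassigned"

    def subset(self, asv_ids: list[str]) -> "TaxonomyTable":
        present = [a for a in asv_ids if a in self.lineages.index]
        return TaxonomyTable(self.lineages.loc[present].copy())


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""


def validate_metadata(meta: pd.DataFrame, max_timepoint: int = TIMEPOINT_RANGE[1]) -> pd.DataFrame:
    """Validate and normalize a sample-metadata frame.

    Returns a copy with canonical dtypes: string categoricals, float
    ``oscorad`` (NaN when missing), nullable-boolean ``filaggrin_mutation``
    and plain-boolean ``is_negative_control``. Negative-control rows are
    exempt from participant-level checks.
    """
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing required columns: {missing_cols}")
    df = meta.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")

    def as_bool(v, col, sid, allow_missing):
        if _is_missing(v):
            if allow_missing:
                return pd.NA
            raise ValidationError(f"sample {sid!r}: missing {col}")
        s = str(v).strip().lower()
        if s in ("true", "1", "yes", "t"):
            return True
        if s in ("false", "0", "no", "f"):
            return False
        raise ValidationError(f"sample {sid!r}: bad boolean {col}={v!r}")

    records = df.to_dict("records")
    for row in records:
        sid = row["sample_id"]
        row["is_negative_control"] = bool(
            as_bool(row["is_negative_control"], "is_negative_control", sid, False)
        )
        if row["is_negative_control"]:
            nonempty = [
                c for c in ("participant_id", "cohort", "skin_status", "depth")
                if not _is_missing(row[c])
            ]
            if nonempty:
                raise ValidationError(
                    f"negative control {sid!r} carries participant-level "
                    f"fields {nonempty}"
                )
            for c in ("participant_id", "cohort", "skin_status", "depth",
                      "body_location"):
                row[c] = ""
            row["timepoint"] = pd.NA
            row["oscorad"] = np.nan
            row["filaggrin_mutation"] = pd.NA
            continue
        row["participant_id"] = str(row["participant_id"])
        if _is_missing(row["participant_id"]):
            raise ValidationError(f"sample {sid!r}: missing participant_id")
        for col, levels in (
            ("cohort", COHORTS),
            ("skin_status", SKIN_STATUSES),
            ("depth", DEPTHS),
        ):
            val = str(row[col]).strip()
            if val not in levels:
                raise ValidationError(
                    f"sample {sid!r}: unknown {col} level {row[col]!r} "
                    f"(expected one of {levels})"
                )
            row[col] = val
        if (row["skin_status"] == "HC") != (row["cohort"] == "HC"):
            raise ValidationError(
                f"sample {sid!r}: skin_status 'HC' must coincide with "
                f"cohort 'HC' (got status={row['skin_status']}, "
                f"cohort={row['cohort']})"
            )
        try:
            tp = int(row["timepoint"])
        except (TypeError, ValueError):
            raise ValidationError(f"sample {sid!r}: non-integer timepoint")
        if not (TIMEPOINT_RANGE[0] <= tp <= max_timepoint):
            raise ValidationError(
                f"sample {sid!r}: timepoint out of range "
                f"[{TIMEPOINT_RANGE[0]}, {max_timepoint}]: {tp}"
            )
        row["timepoint"] = tp
        loc = str(row["body_location"]).strip()
        if _is_missing(loc):
            loc = ""
        elif loc not in BODY_LOCATIONS:
            raise ValidationError(
                f"sample {sid!r}: unknown body_location {loc!r}"
            )
        row["body_location"] = loc
        if _is_missing(row["oscorad"]):
            row["oscorad"] = np.nan
        else:
            osc = float(row["oscorad"])
            if osc < 0:
                raise ValidationError(f"sample {sid!r}: negative oscorad")
            row["oscorad"] = osc
        row["filaggrin_mutation"] = as_bool(
            row["filaggrin_mutation"], "filaggrin_mutation", sid, True
        )

    out = pd.DataFrame.from_records(records)
    out = out[list(METADATA_COLUMNS) + [c for c in out.columns if c not in METADATA_COLUMNS]]
    out["timepoint"] = out["timepoint"].astype("Int64")
    out["oscorad"] = out["oscorad"].astype(float)
    out["filaggrin_mutation"] = out["filaggrin_mutation"].astype("boolean")
    out["is_negative_control"] = out["is_negative_control"].astype(bool)
    out = out.set_index("sample_id", drop=False)
    out.index.name = None
    return out


@dataclass
class AlignedStudy:
    """An ASV table and metadata restricted to their common samples."""

    table: AsvTable
    meta: pd.DataFrame
    dropped_from_table: list[str] = field(default_factory=list)
    dropped_from_meta: list[str] = field(default_factory=list)
    dropped_all_zero: list[str] = field(default_factory=list)


def align(table: AsvTable, meta: pd.DataFrame, drop_all_zero: bool = True) -> AlignedStudy:
    """Harmonize sample order between table and metadata.

    Samples present in only one input are reported and dropped; all-zero
    samples are dropped with a warning. Raises on zero overlap. Idempotent.
    """
    meta_ids = list(meta["sample_id"].astype(str))
    table_set = set(table.sample_ids)
    meta_set = set(meta_ids)
    common = [s for s in table.sample_ids if s in meta_set]
    if not common:
        raise ValidationError("no overlapping samples between table and metadata")
    dropped_t = [s for s in table.sample_ids if s not in meta_set]
    dropped_m = [s for s in meta_ids if s not in table_set]
    for s in dropped_t:
        logger.warning("sample %r present in table only; dropped", s)
    for s in dropped_m:
        logger.warning("sample %r present in metadata only; dropped", s)
    sub = table.subset_samples(common)
    zero = []
    if drop_all_zero:
        rowsum = sub.values.sum(axis=1)
        zero = [s for s, t in zip(sub.sample_ids, rowsum) if t == 0]
        if zero:
            logger.warning("dropping %d all-zero samples: %s", len(zero), zero[:10])
            common = [s for s in common if s not in set(zero)]
            sub = table.subset_samples(common)
    meta_sub = meta.set_index(meta["sample_id"].astype(str)).loc[common]
    meta_sub.index.name = None
    return AlignedStudy(
        table=sub,
        meta=meta_sub,
        dropped_from_table=dropped_t,
        dropped_from_meta=dropped_m,
        dropped_all_zero=zero,
    )
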