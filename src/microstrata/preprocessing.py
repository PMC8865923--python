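"""Post-ASV-table filtering and normalization.

Three filters applied in order — negative-control contaminants, low
prevalence, off-target taxonomy — followed by a fourth-root transform and
conversion to relative abundance. Each stage logs what it removed and the
read loss it caused; the aggregate report tracks the mean per-sample
fraction of reads removed over non-control samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import RAW_COUNTS, TRANSFORMED_RELABUND, AsvTable, TaxonomyTable

logger = logging.getLogger(__name__)

STAGE_NEGATIVES = "negative_control"
STAGE_PREVALENCE = "prevalence"
STAGE_TAXONOMY = "taxonomy"
STAGE_ORDER = (STAGE_NEGATIVES, STAGE_PREVALENCE, STAGE_TAXONOMY)


@dataclass
class FilterReport:
    """Per-stage removals and read-loss accounting."""

    removed_asv_ids: dict[str, list[str]] = field(default_factory=dict)
    reads_removed: dict[str, float] = field(default_factory=dict)
    per_sample_fraction_removed: dict[str, float] = field(default_factory=dict)
    mean_fraction_removed: float = 0.0
    stage_order: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def total_removed_asvs(self) -> int:
        return sum(len(v) for v in self.removed_asv_ids.values())

    def merge_stage(self, stage: str, removed: list[str], reads: float) -> None:
        self.removed_asv_ids[stage] = list(removed)
        self.reads_removed[stage] = float(reads)
        self.stage_order.append(stage)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": s,
                "n_asvs_removed": len(self.removed_asv_ids.get(s, [])),
                "reads_removed": self.reads_removed.get(s, 0.0),
                "asv_ids": ",".join(self.removed_asv_ids.get(s, [])),
            }
            for s in self.stage_order
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "stage_order": list(self.stage_order),
            "removed_asv_ids": {k: list(v) for k, v in self.removed_asv_ids.items()},
            "reads_removed": dict(self.reads_removed),
            "per_sample_fraction_removed": dict(self.per_sample_fraction_removed),
            "mean_fraction_removed": self.mean_fraction_removed,
            "warnings": list(self.warnings),
        }


def _reads_in_columns(table: AsvTable, asvs: list[str], samples: list[str]) -> float:
    if not asvs or not samples:
        return 0.0
    sub = table.subset_samples(samples).subset_asvs(asvs)
    return float(sub.values.sum())


def _non_control_samples(table: AsvTable, meta: pd.DataFrame) -> list[str]:
    neg = set(meta.loc[meta["is_negative_control"], "sample_id"].astype(str))
    return [s for s in table.sample_ids if s not in neg]


def filter_negative_contaminants(
    table: AsvTable, meta: pd.DataFrame, min_negatives: int = 10
) -> tuple[AsvTable, FilterReport]:
    """Remove ASVs detected in >= `min_negatives` negative controls, then
    drop the negative-control samples themselves.

    With zero negatives present the table is returned unchanged with a
    warning.
    """
    if min_negatives < 1:
        raise ValueError("min_negatives must be >= 1")
    if table.value_kind != RAW_COUNTS:
        raise ValueError("negative-control filter requires raw counts")
    report = FilterReport()
    neg_ids = [
        s
        for s in meta.loc[meta["is_negative_control"], "sample_id"].astype(str)
        if s in set(table.sample_ids)
    ]
    if not neg_ids:
        msg = "no negative controls present; contaminant filter skipped"
        logger.warning(msg)
        report.warnings.append(msg)
        report.merge_stage(STAGE_NEGATIVES, [], 0.0)
        return table, report
    neg = table.subset_samples(neg_ids)
    n_detected = (neg.values > 0).sum(axis=0)
    removed = [a for a, k in zip(table.asv_ids, n_detected) if k >= min_negatives]
    keep_samples = _non_control_samples(table, meta)
    reads = _reads_in_columns(table, removed, keep_samples)
    out = table.subset_samples(keep_samples).drop_asvs(set(removed))
    report.merge_stage(STAGE_NEGATIVES, removed, reads)
    logger.info(
        "negative-control filter: removed %d ASVs detected in >= %d of %d negatives",
        len(removed), min_negatives, len(neg_ids),
    )
    return out, report


def filter_rare_asvs(table: AsvTable, min_samples: int = 5) -> tuple[AsvTable, FilterReport]:
    """Remove ASVs detected in fewer than `min_samples` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if table.value_kind != RAW_COUNTS:
        raise ValueError("prevalence filter requires raw counts")
    prevalence = (table.values > 0).sum(axis=0)
    removed = [a for a, k in zip(table.asv_ids, prevalence) if k < min_samples]
    reads = _reads_in_columns(table, removed, table.sample_ids)
    out = table.drop_asvs(set(removed))
    report = FilterReport()
    report.merge_stage(STAGE_PREVALENCE, removed, reads)
    return out, report


def filter_taxonomy(table: AsvTable, tax: TaxonomyTable) -> tuple[AsvTable, FilterReport]:
    """Keep ASVs whose domain is Bacteria/Archaea and whose lineage contains
    neither Mitochondria nor Chloroplast at any rank (case-insensitive)."""
    if table.value_kind != RAW_COUNTS:
        raise ValueError("taxonomy filter requires raw counts")
    missing = tax.covers(table.asv_ids)
    if missing:
        raise ValueError(f"ASVs without taxonomy entry: {missing[:5]}")
    lin = tax.lineages.loc[table.asv_ids]
    domain_ok = lin["domain"].str.lower().isin(("bacteria", "archaea"))
    organelle = lin.apply(
        lambda row: any(
            ("mitochondria" in v.lower()) or ("chloroplast" in v.lower())
            for v in row
        ),
        axis=1,
    )
    keep_mask = domain_ok & ~organelle
    removed = [a for a, ok in zip(table.asv_ids, keep_mask) if not ok]
    reads = _reads_in_columns(table, removed, table.sample_ids)
    out = table.drop_asvs(set(removed))
    report = FilterReport()
    report.merge_stage(STAGE_TAXONOMY, removed, reads)
    return out, report


def fourth_root_relabund(table: AsvTable) -> AsvTable:
    """Fourth-root each count, then rescale every sample row to sum 1.

    All-zero rows stay all-zero (warned). Output value_kind is
    ``transformed_relabund``.
    """
    if table.value_kind != RAW_COUNTS:
        raise ValueError("normalization expects raw counts")
    transformed = np.power(table.values, 0.25)
    rowsums = transformed.sum(axis=1, keepdims=True)
    zero_rows = np.flatnonzero(rowsums[:, 0] == 0)
    if zero_rows.size:
        logger.warning(
            "%d all-zero samples left unnormalized: %s",
            zero_rows.size, [table.sample_ids[i] for i in zero_rows[:10]],
        )
    safe = np.where(rowsums == 0, 1.0, rowsums)
    values = transformed / safe
    return AsvTable(
        list(table.sample_ids), list(table.asv_ids), values, TRANSFORMED_RELABUND
    )


@dataclass
class PreprocessResult:
    """Filtered counts, normalized abundances, and the aggregate report."""

    counts: AsvTable
    normalized: AsvTable
    report: FilterReport


def run_preprocessing(
    table: AsvTable,
    meta: pd.DataFrame,
    tax: TaxonomyTable,
    min_negatives: int = 10,
    min_samples: int = 5,
) -> PreprocessResult:
    """Full chain: negative-control -> prevalence -> taxonomy filters, then
    fourth-root relative-abundance normalization.

    The report aggregates per-stage ASV removals and read losses and the
    mean per-sample fraction of reads removed, computed over non-control
    samples between the raw input and the fully filtered counts.
    """
    non_control = _non_control_samples(table, meta)
    before = table.subset_samples(non_control)
    totals_before = dict(zip(before.sample_ids, before.values.sum(axis=1)))

    t1, r1 = filter_negative_contaminants(table, meta, min_negatives=min_negatives)
    # negatives may remain if there were none to drop; ensure they are gone
    t1 = t1.subset_samples([s for s in t1.sample_ids if s in set(non_control)])
    t2, r2 = filter_rare_asvs(t1, min_samples=min_samples)
    t3, r3 = filter_taxonomy(t2, tax)

    report = FilterReport()
    report.warnings.extend(r1.warnings)
    for stage_rep in (r1, r2, r3):
        stage = stage_rep.stage_order[0]
        report.merge_stage(
            stage, stage_rep.removed_asv_ids[stage], stage_rep.reads_removed[stage]
        )

    totals_after = dict(zip(t3.sample_ids, t3.values.sum(axis=1)))
    fractions = {}
    for s in before.sample_ids:
        tot = totals_before[s]
        if tot == 0:
            fractions[s] = 0.0
        else:
            fractions[s] = 1.0 - totals_after.get(s, 0.0) / tot
    report.per_sample_fraction_removed = fractions
    report.mean_fraction_removed = float(np.mean(list(fractions.values()))) if fractions else 0.0

    normalized = fourth_root_relabund(t3)
    return PreprocessResult(counts=t3, normalized=normalized, report=report)
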