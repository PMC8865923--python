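"""Alpha diversity, the three pairwise beta metrics, and genus aggregation.

Richness and detection-based metrics operate on pre-normalization counts;
Shannon and the abundance-weighted Yue-Clayton similarity operate on
fourth-root relative abundances by default.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AsvTable, TaxonomyTable
from .preprocessing import fourth_root_relabund

logger = logging.getLogger(__name__)

WITHIN_PARTICIPANT_TEMPORAL = "within_participant_temporal"


def asv_richness(sample: np.ndarray) -> int:
    """Number of detected (count > 0) ASVs."""
    sample = np.asarray(sample)
    return int(np.count_nonzero(sample > 0))


def shannon(sample: np.ndarray) -> float:
    """Shannon diversity H = -sum p ln p (natural log) after rescaling the
    vector to sum 1. All-zero input is undefined and returns NaN."""
    p = np.asarray(sample, dtype=float)
    if np.any(p < 0):
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total == 0:
        logger.warning("Shannon undefined for all-zero sample; returning NaN")
        return float("nan")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def beta_asv_difference(a: np.ndarray, b: np.ndarray) -> int:
    """Absolute richness difference between two samples."""
    return abs(asv_richness(a) - asv_richness(b))


def jaccard_membership(a: np.ndarray, b: np.ndarray) -> float:
    """Proportion of shared ASVs: |A ∩ B| / |A ∪ B| on detection sets.

    Two empty samples are defined as identical (1.0, warned).
    """
    da = np.asarray(a) > 0
    db = np.asarray(b) > 0
    union = int(np.count_nonzero(da | db))
    if union == 0:
        logger.warning("Jaccard of two empty samples defined as 1")
        return 1.0
    inter = int(np.count_nonzero(da & db))
    return inter / union


def yue_clayton(p: np.ndarray, q: np.ndarray) -> float:
    """Yue-Clayton similarity theta = sum(pq) / (sum((p-q)^2) + sum(pq)).

    Both vectors must sum to 1 (tolerance 1e-9). Returns NaN when both are
    empty (zero denominator).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for name, v in (("p", p), ("q", q)):
        if v.sum() > 0 and abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {v.sum()})")
    cross = float((p * q).sum())
    denom = float(((p - q) ** 2).sum()) + cross
    if denom == 0:
        logger.warning("Yue-Clayton undefined for two empty samples; returning NaN")
        return float("nan")
    return cross / denom


@dataclass
class BetaPair:
    sample_id_a: str
    sample_id_b: str
    asv_difference: int
    jaccard: float
    yue_clayton: float
    pairing_context: str = "custom"


def alpha_diversity(
    counts: AsvTable,
    normalized: AsvTable | None = None,
    shannon_on_transformed: bool = True,
) -> pd.DataFrame:
    """Per-sample ASV richness (on counts) and Shannon diversity.

    Shannon uses fourth-root relative abundances unless
    ``shannon_on_transformed`` is False, in which case raw relative
    abundances are used.
    """
    if shannon_on_transformed:
        if normalized is None:
            normalized = fourth_root_relabund(counts)
        sh_src = normalized.values
    else:
        sh_src = counts.values
    rows = []
    for i, sid in enumerate(counts.sample_ids):
        rows.append(
            {
                "sample_id": sid,
                "richness": asv_richness(counts.values[i]),
                "shannon": shannon(sh_src[i]),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def within_participant_beta(
    counts: AsvTable,
    meta: pd.DataFrame,
    consecutive_only: bool = False,
) -> pd.DataFrame:
    """All unordered within-participant temporal pairs, holding skin depth
    and skin status fixed, with the three beta metrics per pair.

    Yue-Clayton is computed on fourth-root relative abundances derived from
    the counts. Negative controls are excluded. With ``consecutive_only``
    only pairs of adjacent time points are emitted (pairing_context
    'custom').
    """
    normalized = fourth_root_relabund(counts)
    m = meta.loc[~meta["is_negative_control"]]
    m = m.loc[m["sample_id"].isin(counts.sample_ids)]
    idx = {s: i for i, s in enumerate(counts.sample_ids)}
    context = "custom" if consecutive_only else WITHIN_PARTICIPANT_TEMPORAL
    records = []
    for (_, _, _), grp in m.groupby(
        ["participant_id", "depth", "skin_status"], sort=True
    ):
        grp = grp.sort_values("timepoint")
        sids = grp["sample_id"].tolist()
        tps = grp["timepoint"].tolist()
        for (sa, ta), (sb, tb) in itertools.combinations(zip(sids, tps), 2):
            if consecutive_only and abs(int(tb) - int(ta)) != 1:
                continue
            ia, ib = idx[sa], idx[sb]
            records.append(
                {
                    "sample_id_a": sa,
                    "sample_id_b": sb,
                    "participant_id": grp["participant_id"].iloc[0],
                    "depth": grp["depth"].iloc[0],
                    "skin_status": grp["skin_status"].iloc[0],
                    "asv_difference": beta_asv_difference(
                        counts.values[ia], counts.values[ib]
                    ),
                    "jaccard": jaccard_membership(counts.values[ia], counts.values[ib]),
                    "yue_clayton": yue_clayton(
                        normalized.values[ia], normalized.values[ib]
                    ),
                    "pairing_context": context,
                }
            )
    cols = [
        "sample_id_a", "sample_id_b", "participant_id", "depth", "skin_status",
        "asv_difference", "jaccard", "yue_clayton", "pairing_context",
    ]
    return pd.DataFrame(records, columns=cols)


def aggregate_by_genus(
    normalized: AsvTable, tax: TaxonomyTable, counts: AsvTable | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample genus-level summed relative abundance and detected-ASV
    richness. Unassigned genera pool under 'unassigned'.

    Richness is computed on detection in `counts` when given, else on
    nonzero normalized abundance (identical support for a fourth-root
    transform).
    """
    missing = tax.covers(normalized.asv_ids)
    if missing:
        raise ValueError(f"ASVs without taxonomy entry: {missing[:5]}")
    genera = [tax.genus_of(a) for a in normalized.asv_ids]
    ab = normalized.to_dataframe()
    det_src = counts if counts is not None else normalized
    det = pd.DataFrame(
        det_src.detected(), index=ab.index, columns=det_src.asv_ids
    )
    genus_ab = ab.T.groupby(pd.Index(genera, name="genus")).sum().T
    genus_rich = det.T.groupby(pd.Index(genera, name="genus")).sum().T.astype(int)
    return genus_ab, genus_rich
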