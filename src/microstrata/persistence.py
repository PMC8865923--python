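"""Within-participant persistence profiles, per-ASV depth/status tests, and
core / ubiquitous community identification.

Persistence of an ASV over a sample set is the exact fraction of those
samples in which it is detected (raw count > 0). Core membership uses an
inclusive >= threshold (default 0.7); the source analysis wrote ">0.7" for
the per-participant core and "0.7 or more" for ubiquity — the inclusive
convention reconciles the two and is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import AsvTable
from .permanova import PermanovaResult, compute_distance, permanova
from .stats import (
    FLAG_TWO_SAMPLE_FALLBACK,
    TestResult,
    bh_fdr,
    kruskal_wallis,
    paired_t,
)

logger = logging.getLogger(__name__)

# design axes that can stratify a profile; value = metadata column
AXES = {"depth": "depth", "status": "skin_status", "time": "timepoint"}


@dataclass
class PersistenceProfile:
    """Long-form per-(participant, stratum, ASV) detection proportions."""

    data: pd.DataFrame  # participant_id, [stratum cols], asv_id, detections, n_samples, persistence
    pooled: tuple[str, ...]
    stratum_cols: tuple[str, ...]

    def matrix(self, **stratum) -> pd.DataFrame:
        """Participants x ASVs persistence matrix for one stratum slice."""
        df = self.data
        for k, v in stratum.items():
            df = df.loc[df[AXES.get(k, k)] == v]
        return df.pivot(index="participant_id", columns="asv_id", values="persistence")

    def counts_matrix(self, value: str = "detections", **stratum) -> pd.DataFrame:
        df = self.data
        for k, v in stratum.items():
            df = df.loc[df[AXES.get(k, k)] == v]
        return df.pivot(index="participant_id", columns="asv_id", values=value)

    def total_detections(self) -> pd.Series:
        """Per-ASV number of samples detected in, over the whole profile."""
        return self.data.groupby("asv_id")["detections"].sum()

    def split_by(self, axis: str) -> dict:
        col = AXES.get(axis, axis)
        out = {}
        for lev, grp in self.data.groupby(col):
            out[lev] = PersistenceProfile(
                grp.reset_index(drop=True), self.pooled, self.stratum_cols
            )
        return out


def persistence_profile(
    counts: AsvTable,
    meta: pd.DataFrame,
    pool: tuple[str, ...] = ("time",),
    exclude_lesional: bool = True,
) -> PersistenceProfile:
    """Per-participant persistence of every ASV, stratified by the design
    axes not listed in `pool`.

    Detection is computed on the pre-normalization counts. Negative
    controls are always excluded; lesional samples are excluded when
    `exclude_lesional` is set.
    """
    unknown = set(pool) - set(AXES)
    if unknown:
        raise ValueError(f"unknown pooling axes {sorted(unknown)}; choose from {sorted(AXES)}")
    m = meta.loc[~meta["is_negative_control"]].copy()
    m = m.loc[m["sample_id"].isin(counts.sample_ids)]
    if exclude_lesional:
        m = m.loc[m["skin_status"] != "LS"]
    stratum_cols = tuple(AXES[a] for a in AXES if a not in pool)
    keys = ["participant_id", *stratum_cols]

    det = pd.DataFrame(
        counts.detected().astype(int),
        index=counts.sample_ids,
        columns=counts.asv_ids,
    ).loc[m["sample_id"]]
    det.index = m.index
    grouped_det = det.groupby([m[k] for k in keys], observed=True).sum()
    grouped_n = det.groupby([m[k] for k in keys], observed=True).size()

    long = grouped_det.stack().rename("detections").reset_index()
    long.columns = [*keys, "asv_id", "detections"]
    n_map = grouped_n.rename("n_samples").reset_index()
    n_map.columns = [*keys, "n_samples"]
    long = long.merge(n_map, on=keys)
    long["persistence"] = long["detections"] / long["n_samples"]
    return PersistenceProfile(long, pooled=tuple(pool), stratum_cols=stratum_cols)


REASON_TOO_FEW_PAIRS = "too_few_pairs"
REASON_ZERO_VARIANCE = "zero_variance"


def depth_persistence_test(
    profile_surface: PersistenceProfile,
    profile_within: PersistenceProfile,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Paired t tests of per-participant persistence, surface minus within.

    An ASV is tested iff detected in more than `min_samples` samples overall
    (both depths pooled). p-values are BH-adjusted to q-values across the
    tested ASVs. ASVs with fewer than 3 paired participants or zero
    variance of differences get a missing statistic with a reason code.
    """
    s = profile_surface.matrix()
    w = profile_within.matrix()
    participants = s.index.intersection(w.index)
    asvs = s.columns.union(w.columns)
    s = s.reindex(index=participants, columns=asvs)
    w = w.reindex(index=participants, columns=asvs)
    total_det = (
        profile_surface.total_detections().reindex(asvs, fill_value=0)
        + profile_within.total_detections().reindex(asvs, fill_value=0)
    )
    tested = total_det[total_det > min_samples].index

    rows = []
    for asv in tested:
        x = s[asv]
        y = w[asv]
        ok = x.notna() & y.notna()
        n_pairs = int(ok.sum())
        rec = {
            "asv_id": asv,
            "n_pairs": n_pairs,
            "mean_surface": float(x[ok].mean()) if n_pairs else np.nan,
            "mean_within": float(y[ok].mean()) if n_pairs else np.nan,
            "statistic": np.nan,
            "p_value": np.nan,
            "reason": "",
        }
        if n_pairs < 3:
            rec["reason"] = REASON_TOO_FEW_PAIRS
        else:
            res = paired_t(x[ok].to_numpy(), y[ok].to_numpy())
            if "zero_variance" in res.flags:
                rec["reason"] = REASON_ZERO_VARIANCE
            else:
                rec["statistic"] = res.statistic
                rec["p_value"] = res.p_value
        rows.append(rec)
    out = pd.DataFrame(
        rows,
        columns=[
            "asv_id", "n_pairs", "mean_surface", "mean_within",
            "statistic", "p_value", "reason",
        ],
    )
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def status_persistence_test(
    profile: PersistenceProfile,
    meta: pd.DataFrame,
    depth: str,
    min_patients: int = 5,
) -> pd.DataFrame:
    """Per-ASV fixed effect of AD status (NLS vs HC) on within-participant
    persistence at one skin depth.

    The model is a participant random-intercept fit; with one observation
    per participant the random-intercept variance is unidentifiable, so the
    operation degenerates to the equivalent two-sample comparison and flags
    it. ASVs enter only with nonzero persistence in more than
    `min_patients` participants.
    """
    mat = profile.matrix(depth=depth)
    det = profile.counts_matrix("detections", depth=depth)
    part_status = (
        meta.loc[~meta["is_negative_control"]]
        .groupby("participant_id")["cohort"]
        .first()
        .reindex(mat.index)
    )
    if part_status.nunique() < 2:
        raise ValueError("need two statuses (AD and HC participants)")
    n_nonzero = (mat > 0).sum(axis=0)
    tested = n_nonzero[n_nonzero > min_patients].index

    is_ad = (part_status == "AD").to_numpy()
    rows = []
    for asv in tested:
        v = mat[asv].to_numpy(dtype=float)
        x = v[is_ad]
        y = v[~is_ad]
        effect = float(x.mean() - y.mean())
        # one observation per (participant, depth): random intercept is
        # unidentifiable -> equivalent two-sample (equal-variance) t test
        nx, ny = x.size, y.size
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        if sp2 == 0:
            stat, p = np.nan, np.nan
            reason = REASON_ZERO_VARIANCE
        else:
            stat = effect / np.sqrt(sp2 * (1 / nx + 1 / ny))
            p = float(2 * sps.t.sf(abs(stat), nx + ny - 2))
            reason = ""
        rows.append(
            {
                "asv_id": asv,
                "depth": depth,
                "n_ad": nx,
                "n_hc": ny,
                "effect": effect,
                "statistic": stat,
                "p_value": p,
                "flags": FLAG_TWO_SAMPLE_FALLBACK if not reason else f"{FLAG_TWO_SAMPLE_FALLBACK},{reason}",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["asv_id", "depth", "n_ad", "n_hc", "effect", "statistic", "p_value", "flags"],
    )
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


@dataclass
class CoreCommunityResult:
    cores: dict[str, list[str]]          # participant -> core ASVs
    union: list[str]
    per_participant: pd.DataFrame        # participant, core_richness, core_share
    threshold: float
    notes: list[str] = field(default_factory=list)


def identify_core(
    profile: PersistenceProfile,
    normalized: AsvTable,
    meta: pd.DataFrame,
    threshold: float = 0.7,
) -> CoreCommunityResult:
    """Per-participant core community at a persistence threshold.

    `profile` must be pooled over depth and time with lesional samples
    excluded. Core membership is persistence >= threshold (inclusive; the
    boundary convention is recorded in the result notes). The per-
    participant core share is the summed relative abundance of that
    participant's core ASVs averaged over their retained samples.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    mat = profile.matrix()
    cores = {
        p: sorted(mat.columns[(mat.loc[p] >= threshold).fillna(False)])
        for p in mat.index
    }
    union = sorted(set().union(*cores.values()) if cores else set())

    m = meta.loc[~meta["is_negative_control"]]
    m = m.loc[m["skin_status"] != "LS"]
    m = m.loc[m["sample_id"].isin(normalized.sample_ids)]
    ab = normalized.to_dataframe()
    rows = []
    for p, core in cores.items():
        sids = m.loc[m["participant_id"] == p, "sample_id"].tolist()
        share = float(ab.loc[sids, core].sum(axis=1).mean()) if sids and core else 0.0
        rows.append(
            {"participant_id": p, "core_richness": len(core), "core_share": share}
        )
    per_part = pd.DataFrame(rows, columns=["participant_id", "core_richness", "core_share"])
    return CoreCommunityResult(
        cores=cores,
        union=union,
        per_participant=per_part,
        threshold=threshold,
        notes=[
            "core membership uses persistence >= threshold (inclusive "
            "boundary; configurable)"
        ],
    )


def identify_ubiquitous(
    counts: AsvTable,
    meta: pd.DataFrame,
    threshold: float = 0.7,
    include_lesional: bool = False,
) -> list[str]:
    """ASVs detected in at least `threshold` of all retained samples."""
    m = meta.loc[~meta["is_negative_control"]]
    if not include_lesional:
        m = m.loc[m["skin_status"] != "LS"]
    sids = [s for s in counts.sample_ids if s in set(m["sample_id"])]
    sub = counts.subset_samples(sids)
    frac = (sub.values > 0).mean(axis=0)
    return [a for a, f in zip(sub.asv_ids, frac) if f >= threshold]


def compare_core_by_status(
    core: CoreCommunityResult,
    normalized: AsvTable,
    meta: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Kruskal-Wallis on per-participant core share and core richness
    between cohorts, plus PERMANOVA on the core-subset composition (samples
    restricted to union-core ASVs, participant as strata)."""
    m = meta.loc[~meta["is_negative_control"]]
    status = m.groupby("participant_id")["cohort"].first()
    pp = core.per_participant.set_index("participant_id")
    pp = pp.join(status.rename("cohort"))
    groups = pp.groupby("cohort")
    if groups.ngroups < 2 or (groups.size() < 2).any():
        raise ValueError("need two statuses with at least 2 participants each")
    share_groups = [g["core_share"].to_numpy() for _, g in groups]
    rich_groups = [g["core_richness"].to_numpy(dtype=float) for _, g in groups]
    out = {
        "share_test": kruskal_wallis(*share_groups),
        "richness_test": kruskal_wallis(*rich_groups),
    }
    # composition of the core subset
    keep_samples = m.loc[m["skin_status"] != "LS", "sample_id"]
    keep_samples = [s for s in normalized.sample_ids if s in set(keep_samples)]
    sub = normalized.subset_samples(keep_samples)
    core_cols = [a for a in sub.asv_ids if a in set(core.union)]
    if len(core_cols) >= 2:
        vals = sub.subset_asvs(core_cols).values
        rowsum = vals.sum(axis=1, keepdims=True)
        vals = vals / np.where(rowsum == 0, 1.0, rowsum)
        core_table = AsvTable(keep_samples, core_cols, vals, "transformed_relabund")
        dm = compute_distance(core_table, metric="bray_curtis")
        sub_meta = m.loc[m["sample_id"].isin(keep_samples)]
        out["composition"] = permanova(
            dm, sub_meta, ["cohort"], n_perm=n_perm, strata="participant_id",
            seed=seed,
        )
    else:
        out["composition"] = None
    return out
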