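"""Hierarchical synthetic skin-microbiome studies with ground truth.

The generator plants the effect hierarchy the analysis is built to detect:
strong interindividual structure (per-participant log-abundance profiles),
a depth effect realized as participant-consistent subsetting of the surface
support (the within-epidermis community is a subset of the surface one),
a small status effect (pathobiont ASVs up-weighted in AD participants),
negligible temporal drift by default, and extraction negatives carrying a
dedicated contaminant pool that is sporadically spiked into surface samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import (
    BODY_LOCATIONS,
    RAW_COUNTS,
    AsvTable,
    TaxonomyTable,
    validate_metadata,
)

logger = logging.getLogger(__name__)

# genus pools for assigned lineages
_GENUS_POOL = (
    ("Corynebacterium", "Actinobacteriota", "Actinobacteria", "Corynebacteriales", "Corynebacteriaceae"),
    ("Acinetobacter", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae"),
    ("Streptococcus", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae"),
    ("Micrococcus", "Actinobacteriota", "Actinobacteria", "Micrococcales", "Micrococcaceae"),
    ("Anaerococcus", "Firmicutes", "Clostridia", "Tissierellales", "Peptoniphilaceae"),
    ("Granulicatella", "Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae"),
    ("Gemella", "Firmicutes", "Bacilli", "Staphylococcales", "Gemellaceae"),
    ("Paracoccus", "Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae"),
    ("Enhydrobacter", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae"),
    ("Kocuria", "Actinobacteriota", "Actinobacteria", "Micrococcales", "Micrococcaceae"),
)
_CONTAMINANT_GENERA = (
    ("Ralstonia", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae"),
    ("Sphingomonas", "Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae"),
    ("Bradyrhizobium", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Xanthobacteraceae"),
    ("Pseudomonas", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae"),
)
_STAPH = ("Staphylococcus", "Firmicutes", "Bacilli", "Staphylococcales", "Staphylococcaceae")


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_participants_ad: int = 20
    n_participants_hc: int = 20
    n_timepoints: int = 4
    depths: tuple[str, ...] = ("surface", "within")
    reads_mean: float = 20000.0
    reads_dispersion: float = 0.25      # sd of log sequencing depth
    n_asvs_global: int = 2000
    participant_effect_sd: float = 1.6  # sigma_P, log-abundance scale
    depth_retention_fraction: float = 0.55  # f_D
    status_effect: float = 0.5          # delta_S, log-fold pathobiont boost in AD
    time_effect: float = 0.0            # delta_T
    n_pathobiont_asvs: int = 10
    n_core_asvs_per_participant: int = 30
    n_contaminant_asvs: int = 30
    n_negatives: int = 12
    include_lesional: bool = False
    lesional_locations: tuple[str, ...] = BODY_LOCATIONS
    location_effect_sd: float = 1.0
    base_log_sd: float = 2.0
    core_log_boost: float = 4.0
    contaminant_spike_rate: float = 0.05
    contaminant_spike_frac: float = 0.02

    def __post_init__(self) -> None:
        for name in ("participant_effect_sd", "status_effect", "time_effect",
                     "location_effect_sd", "base_log_sd", "reads_dispersion",
                     "core_log_boost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.depth_retention_fraction <= 1.0):
            raise ValueError("depth_retention_fraction must be in (0, 1]")
        if not (0.0 <= self.contaminant_spike_frac < 1.0):
            raise ValueError("contaminant_spike_frac must be in [0, 1)")
        if self.reads_mean < 1:
            raise ValueError("reads_mean must be >= 1 (zero reads not allowed)")
        for name in ("n_participants_ad", "n_participants_hc", "n_timepoints",
                     "n_asvs_global"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("n_pathobiont_asvs", "n_core_asvs_per_participant",
                     "n_contaminant_asvs", "n_negatives"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_timepoints > 4:
            raise ValueError("n_timepoints above 4 violates the metadata schema")
        if self.n_pathobiont_asvs > self.n_asvs_global:
            raise ValueError("more pathobionts than ASVs")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depths"] = list(self.depths)
        d["lesional_locations"] = list(self.lesional_locations)
        return d


@dataclass
class SyntheticTruth:
    core_asvs: dict[str, list[str]]            # participant -> planted core
    contaminant_asvs: list[str]
    pathobiont_asvs: list[str]
    depth_restricted_asvs: dict[str, list[str]]  # participant -> dropped within
    realized_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cont = set(self.contaminant_asvs)
        for p, core in self.core_asvs.items():
            if cont & set(core):
                raise AssertionError(f"contaminants in core of {p}")

    def to_dict(self) -> dict:
        return {
            "core_asvs": {k: list(v) for k, v in self.core_asvs.items()},
            "contaminant_asvs": list(self.contaminant_asvs),
            "pathobiont_asvs": list(self.pathobiont_asvs),
            "depth_restricted_asvs": {
                k: list(v) for k, v in self.depth_restricted_asvs.items()
            },
            "realized_effects": dict(self.realized_effects),
        }


def _lineage_frame(asv_ids, pathobionts, contaminants, rng) -> TaxonomyTable:
    rows = {}
    patho = set(pathobionts)
    cont = set(contaminants)
    for a in asv_ids:
        if a in patho:
            g, phy, cls, order, fam = _STAPH
        elif a in cont:
            g, phy, cls, order, fam = _CONTAMINANT_GENERA[
                rng.integers(len(_CONTAMINANT_GENERA))
            ]
        else:
            g, phy, cls, order, fam = _GENUS_POOL[rng.integers(len(_GENUS_POOL))]
        rows[a] = {
            "domain": "Bacteria", "phylum": phy, "class": cls,
            "order": order, "family": fam, "genus": g, "species": "",
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "asv_id"
    return TaxonomyTable(df)


def generate_study(
    config: SyntheticConfig,
) -> tuple[AsvTable, pd.DataFrame, TaxonomyTable, SyntheticTruth]:
    """Simulate a full study: counts table, metadata, taxonomy, and truth.

    Deterministic for a fixed config (seed included): identical config gives
    bit-identical outputs.
    """
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("base", "participant", "depth", "time", "lesional", "reads",
             "sampling", "negatives", "clinical", "taxonomy", "spike"),
            master.spawn(11),
        )
    }

    n_body = cfg.n_asvs_global
    body_ids = [f"ASV{i + 1:04d}" for i in range(n_body)]
    cont_ids = [f"ASV{n_body + i + 1:04d}" for i in range(cfg.n_contaminant_asvs)]
    asv_ids = body_ids + cont_ids
    n_total = len(asv_ids)
    pathobionts = body_ids[: cfg.n_pathobiont_asvs]

    base = rngs["base"].normal(0.0, cfg.base_log_sd, n_body)

    participants = [f"AD{i + 1:02d}" for i in range(cfg.n_participants_ad)] + [
        f"HC{i + 1:02d}" for i in range(cfg.n_participants_hc)
    ]
    cohorts = {p: ("AD" if p.startswith("AD") else "HC") for p in participants}

    prof: dict[str, np.ndarray] = {}
    cores: dict[str, list[str]] = {}
    within_mask: dict[str, np.ndarray] = {}
    dropped: dict[str, list[str]] = {}
    n_keep = max(1, int(round(cfg.depth_retention_fraction * n_body)))
    for p in participants:
        lp = base + rngs["participant"].normal(0.0, cfg.participant_effect_sd, n_body)
        core_idx = rngs["participant"].choice(
            n_body, size=min(cfg.n_core_asvs_per_participant, n_body), replace=False
        )
        lp[core_idx] = lp[core_idx] + cfg.core_log_boost
        if cohorts[p] == "AD" and cfg.status_effect > 0:
            lp[: cfg.n_pathobiont_asvs] += cfg.status_effect
        prof[p] = lp
        cores[p] = sorted(body_ids[i] for i in core_idx)
        keep = set(core_idx.tolist())
        if n_keep > len(keep):
            others = np.setdiff1d(np.arange(n_body), core_idx)
            extra = rngs["depth"].choice(
                others, size=n_keep - len(keep), replace=False
            )
            keep |= set(extra.tolist())
        mask = np.zeros(n_body, dtype=bool)
        mask[sorted(keep)] = True
        within_mask[p] = mask
        dropped[p] = sorted(body_ids[i] for i in np.flatnonzero(~mask))

    time_shift = np.zeros((cfg.n_timepoints, n_body))
    if cfg.time_effect > 0:
        time_shift = rngs["time"].normal(
            0.0, cfg.time_effect, (cfg.n_timepoints, n_body)
        )

    loc_shift: dict[str, np.ndarray] = {}
    lesional_loc: dict[str, str] = {}
    if cfg.include_lesional:
        for loc in cfg.lesional_locations:
            loc_shift[loc] = rngs["lesional"].normal(
                0.0, cfg.location_effect_sd, n_body
            )
        for p in participants:
            if cohorts[p] == "AD":
                lesional_loc[p] = cfg.lesional_locations[
                    rngs["lesional"].integers(len(cfg.lesional_locations))
                ]

    # clinical covariates
    oscorad: dict[tuple[str, int], float] = {}
    filaggrin: dict[str, bool] = {}
    ad_participants = [p for p in participants if cohorts[p] == "AD"]
    flg_carriers = set(
        np.asarray(ad_participants)[
            rngs["clinical"].permutation(len(ad_participants))[
                : len(ad_participants) // 2
            ]
        ].tolist()
    )
    for p in participants:
        filaggrin[p] = p in flg_carriers if cohorts[p] == "AD" else False
        if cohorts[p] == "AD":
            base_sev = float(np.clip(rngs["clinical"].normal(20.5, 8.0), 2.0, 60.0))
            for t in range(1, cfg.n_timepoints + 1):
                oscorad[(p, t)] = float(
                    np.clip(base_sev + rngs["clinical"].normal(0.0, 3.0), 0.0, 83.0)
                )

    def draw_reads(rng) -> int:
        mu = np.log(cfg.reads_mean) - 0.5 * cfg.reads_dispersion**2
        return max(1, int(round(rng.lognormal(mu, cfg.reads_dispersion))))

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []

    def emit(sid, weights_body, weights_cont, p, status, depth, tp, location):
        w = np.zeros(n_total)
        w[:n_body] = weights_body
        if cfg.n_contaminant_asvs:
            w[n_body:] = weights_cont
        total = w.sum()
        if total <= 0:
            raise ValueError("degenerate sample: zero total weight")
        reads = draw_reads(rngs["reads"])
        counts = rngs["sampling"].multinomial(reads, w / total)
        sample_ids.append(sid)
        rows.append(counts)
        meta_rows.append(
            {
                "sample_id": sid,
                "participant_id": p or "",
                "cohort": cohorts.get(p, "") if p else "",
                "skin_status": status,
                "depth": depth,
                "timepoint": tp,
                "body_location": location,
                "oscorad": oscorad.get((p, tp), np.nan) if p else np.nan,
                "filaggrin_mutation": filaggrin.get(p, None) if p else None,
                "is_negative_control": p is None,
            }
        )

    for p in participants:
        status = "NLS" if cohorts[p] == "AD" else "HC"
        for depth in cfg.depths:
            for t in range(1, cfg.n_timepoints + 1):
                lw = prof[p] + time_shift[t - 1]
                w = np.exp(lw)
                if depth == "within":
                    w = w * within_mask[p]
                cont_w = np.zeros(cfg.n_contaminant_asvs)
                if (
                    depth == "surface"
                    and cfg.n_contaminant_asvs
                    and rngs["spike"].random() < cfg.contaminant_spike_rate
                ):
                    k = max(1, cfg.n_contaminant_asvs // 3)
                    chosen = rngs["spike"].choice(
                        cfg.n_contaminant_asvs, size=k, replace=False
                    )
                    cont_w[chosen] = (
                        cfg.contaminant_spike_frac * w.sum() / k
                    )
                sid = f"{p}_{status}_{depth[0]}_t{t}"
                emit(sid, w, cont_w, p, status, depth, t, "volar_forearm")
                if cfg.include_lesional and cohorts[p] == "AD":
                    loc = lesional_loc[p]
                    lw_ls = prof[p] + time_shift[t - 1] + loc_shift[loc]
                    w_ls = np.exp(lw_ls)
                    if depth == "within":
                        w_ls = w_ls * within_mask[p]
                    sid_ls = f"{p}_LS_{depth[0]}_t{t}"
                    emit(sid_ls, w_ls, np.zeros(cfg.n_contaminant_asvs), p,
                         "LS", depth, t, loc)

    for i in range(cfg.n_negatives):
        if cfg.n_contaminant_asvs == 0:
            break
        mu = np.log(max(cfg.reads_mean / 10.0, 10.0)) - 0.5 * cfg.reads_dispersion**2
        reads = max(1, int(round(rngs["negatives"].lognormal(mu, cfg.reads_dispersion))))
        w = rngs["negatives"].dirichlet(np.full(cfg.n_contaminant_asvs, 5.0))
        counts = np.zeros(n_total)
        counts[n_body:] = rngs["negatives"].multinomial(reads, w)
        sid = f"NEG{i + 1:02d}"
        sample_ids.append(sid)
        rows.append(counts)
        meta_rows.append(
            {
                "sample_id": sid, "participant_id": "", "cohort": "",
                "skin_status": "", "depth": "", "timepoint": None,
                "body_location": "", "oscorad": np.nan,
                "filaggrin_mutation": None, "is_negative_control": True,
            }
        )

    table = AsvTable(sample_ids, asv_ids, np.vstack(rows), RAW_COUNTS)
    meta = validate_metadata(pd.DataFrame(meta_rows), max_timepoint=cfg.n_timepoints)
    tax = _lineage_frame(asv_ids, pathobionts, cont_ids, rngs["taxonomy"])
    truth = SyntheticTruth(
        core_asvs=cores,
        contaminant_asvs=list(cont_ids),
        pathobiont_asvs=list(pathobionts),
        depth_restricted_asvs=dropped,
        realized_effects={
            "participant_effect_sd": cfg.participant_effect_sd,
            "depth_retention_fraction": cfg.depth_retention_fraction,
            "status_effect": cfg.status_effect,
            "time_effect": cfg.time_effect,
        },
    )
    return table, meta, tax, truth


def preset_default(**overrides) -> SyntheticConfig:
    """Documented preset reproducing the study's qualitative effect
    hierarchy: interindividual >> depth > status with time ~ 0, and a mean
    surface/within richness ratio of roughly 2.

    Tuned parameters, not fitted values. Overrides allow scaled-down runs
    (e.g. n_participants_ad=10, n_asvs_global=500).
    """
    params = dict(
        seed=0,
        n_participants_ad=20,
        n_participants_hc=20,
        n_timepoints=4,
        reads_mean=20000.0,
        reads_dispersion=0.25,
        n_asvs_global=2000,
        participant_effect_sd=1.6,
        depth_retention_fraction=0.5,
        status_effect=0.3,
        time_effect=0.0,
        n_pathobiont_asvs=10,
        n_core_asvs_per_participant=30,
        n_contaminant_asvs=30,
        n_negatives=12,
        base_log_sd=2.0,
        core_log_boost=4.0,
    )
    params.update(overrides)
    return SyntheticConfig(**params)
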