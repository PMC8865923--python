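"""End-to-end orchestration: simulate/load -> preprocess -> diversity ->
variance partitioning -> persistence tests -> core community -> summary.

Every stage writes TSV outputs under the configured directory; the combined
summary is deterministic JSON (sorted keys, no timestamps) so reruns with
the same config and seed are byte-identical. The run log carries seed,
package version, and a parameter echo.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .datatypes import align
from .diversity import aggregate_by_genus, alpha_diversity, within_participant_beta
from .io import (
    read_asv_table,
    read_metadata,
    read_taxonomy,
    write_asv_table,
    write_metadata,
    write_taxonomy,
)
from .permanova import METRICS, run_variance_partition
from .persistence import (
    compare_core_by_status,
    depth_persistence_test,
    identify_core,
    identify_ubiquitous,
    persistence_profile,
    status_persistence_test,
)
from .preprocessing import run_preprocessing
from .simulate import SyntheticConfig, generate_study, preset_default

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "microstrata_out",
    "inputs": {"table": None, "metadata": None, "taxonomy": None, "format": "tsv"},
    "simulation": {"preset": "default", "overrides": {}},
    "filters": {"min_negatives": 10, "min_samples": 5},
    "diversity": {"shannon_on_transformed": True},
    "permanova": {"metric": "bray_curtis", "n_perm": 999, "include_clinical": True},
    "persistence": {"min_samples": 5, "min_patients": 5},
    "core": {"threshold": 0.7, "exclude_lesional": True},
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated nested configuration; unknown keys are rejected."""

    settings: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        merged = {}
        unknown = set(raw) - set(_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, default in _DEFAULTS.items():
            if isinstance(default, dict):
                sub = dict(default)
                given = raw.get(key, {})
                if not isinstance(given, dict):
                    raise ConfigError(f"config section {key!r} must be a mapping")
                bad = set(given) - set(default)
                if bad:
                    raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
                sub.update(given)
                merged[key] = sub
            else:
                merged[key] = raw.get(key, default)
        cfg = cls(merged)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def validate(self) -> None:
        s = self.settings
        if not (0.0 < s["core"]["threshold"] <= 1.0):
            raise ConfigError("core.threshold must be in (0, 1]")
        if s["filters"]["min_negatives"] < 1:
            raise ConfigError("filters.min_negatives must be >= 1")
        if s["filters"]["min_samples"] < 1:
            raise ConfigError("filters.min_samples must be >= 1")
        if s["permanova"]["metric"] not in METRICS:
            raise ConfigError(
                f"permanova.metric must be one of {sorted(METRICS)}"
            )
        np_ = s["permanova"]["n_perm"]
        if np_ != "exact" and (not isinstance(np_, int) or np_ < 1):
            raise ConfigError("permanova.n_perm must be a positive integer or 'exact'")
        inputs = s["inputs"]
        if inputs["table"] is not None:
            if inputs["metadata"] is None or inputs["taxonomy"] is None:
                raise ConfigError("inputs.table requires metadata and taxonomy paths")

    def __getitem__(self, key):
        return self.settings[key]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2, default=_json_default,
                  allow_nan=True)
        fh.write("\n")


def _result_summary(res) -> dict:
    out = {
        "total_ss": res.total_ss,
        "residual": {"df": res.residual_df, "ss": res.residual_ss,
                     "r_squared": res.residual_r_squared},
        "n_permutations": res.n_permutations,
        "strata": res.strata,
        "terms": {},
    }
    for t in res.terms:
        out["terms"][t.term] = {
            "df": t.df, "ss": t.ss, "r_squared": t.r_squared,
            "pseudo_F": None if np.isnan(t.pseudo_f) else t.pseudo_f,
            "p_value": None if np.isnan(t.p_value) else t.p_value,
            "scheme": t.scheme, "aliased": t.aliased,
        }
    return out


def run_all(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns the summary dict.

    A stage failure aborts with the stage name in the exception; outputs of
    completed stages are retained on disk.
    """
    s = config.settings
    out_dir = Path(output_dir or s["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(s["seed"])

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("microstrata")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": seed, "version": _pkg_version, "config": s}
    stage = "setup"
    try:
        logger.info("microstrata %s seed=%d config=%s", _pkg_version, seed, s)

        stage = "inputs"
        truth = None
        if s["inputs"]["table"] is not None:
            table = read_asv_table(s["inputs"]["table"], format=s["inputs"]["format"])
            meta = read_metadata(s["inputs"]["metadata"])
            tax = read_taxonomy(s["inputs"]["taxonomy"])
        else:
            overrides = dict(s["simulation"]["overrides"])
            overrides["seed"] = seed
            if s["simulation"]["preset"] == "default":
                sim_cfg = preset_default(**overrides)
            else:
                sim_cfg = SyntheticConfig(**overrides)
            table, meta, tax, truth = generate_study(sim_cfg)
            write_asv_table(table, out_dir / "simulated_table.tsv")
            write_metadata(meta, out_dir / "simulated_metadata.tsv")
            write_taxonomy(tax, out_dir / "simulated_taxonomy.tsv")
            _dump_json(truth.to_dict(), out_dir / "simulated_truth.json")
            summary["simulation"] = sim_cfg.to_dict()

        aligned = align(table, meta)
        table, meta = aligned.table, aligned.meta

        stage = "preprocess"
        pre = run_preprocessing(
            table, meta, tax,
            min_negatives=s["filters"]["min_negatives"],
            min_samples=s["filters"]["min_samples"],
        )
        write_asv_table(pre.counts, out_dir / "counts_filtered.tsv")
        write_asv_table(pre.normalized, out_dir / "normalized.tsv")
        pre.report.to_frame().to_csv(out_dir / "filter_report.tsv", sep="\t", index=False)
        _dump_json(pre.report.to_dict(), out_dir / "filter_report.json")
        summary["preprocess"] = {
            "n_samples": pre.counts.n_samples,
            "n_asvs": pre.counts.n_asvs,
            "asvs_removed_per_stage": {
                k: len(v) for k, v in pre.report.removed_asv_ids.items()
            },
            "mean_fraction_reads_removed": pre.report.mean_fraction_removed,
        }
        meta_nc = meta.loc[~meta["is_negative_control"]]
        meta_nc = meta_nc.loc[meta_nc["sample_id"].isin(pre.counts.sample_ids)]

        stage = "diversity"
        alpha = alpha_diversity(
            pre.counts, pre.normalized,
            shannon_on_transformed=s["diversity"]["shannon_on_transformed"],
        )
        alpha.to_csv(out_dir / "alpha.tsv", sep="\t", index=False)
        beta = within_participant_beta(pre.counts, meta_nc)
        beta.to_csv(out_dir / "beta.tsv", sep="\t", index=False)
        genus_ab, genus_rich = aggregate_by_genus(pre.normalized, tax, counts=pre.counts)
        genus_ab.to_csv(out_dir / "genus_abundance.tsv", sep="\t")
        genus_rich.to_csv(out_dir / "genus_richness.tsv", sep="\t")
        a = alpha.join(meta_nc.set_index("sample_id")[["depth"]], how="inner")
        depth_means = a.groupby("depth")[["richness", "shannon"]].mean()
        summary["diversity"] = {
            "mean_richness_by_depth": depth_means["richness"].to_dict(),
            "mean_shannon_by_depth": depth_means["shannon"].to_dict(),
            "n_beta_pairs": int(len(beta)),
        }

        stage = "permanova"
        suite = run_variance_partition(
            pre.normalized, meta_nc,
            n_perm=s["permanova"]["n_perm"], seed=seed,
            metric=s["permanova"]["metric"],
            include_clinical=s["permanova"]["include_clinical"],
        )
        perm_dir = out_dir / "permanova"
        perm_dir.mkdir(exist_ok=True)
        summary["permanova"] = {}
        for name, res in suite.items():
            res.to_dataframe().to_csv(perm_dir / f"{name}.tsv", sep="\t", index=False)
            summary["permanova"][name] = _result_summary(res)

        stage = "persistence"
        prof_depth = persistence_profile(
            pre.counts, meta_nc, pool=("time", "status"), exclude_lesional=True
        )
        by_depth = prof_depth.split_by("depth")
        summary["persistence"] = {}
        if {"surface", "within"} <= set(by_depth):
            depth_tests = depth_persistence_test(
                by_depth["surface"], by_depth["within"],
                min_samples=s["persistence"]["min_samples"],
            )
            depth_tests.to_csv(out_dir / "depth_persistence_tests.tsv", sep="\t", index=False)
            summary["persistence"]["depth_tests"] = {
                "n_tested": int(len(depth_tests)),
                "n_q_lt_0.05": int((depth_tests["q_value"] < 0.05).sum()),
            }
        for depth in ("surface", "within"):
            try:
                st = status_persistence_test(
                    prof_depth, meta_nc, depth,
                    min_patients=s["persistence"]["min_patients"],
                )
            except ValueError as e:
                logger.warning("status persistence test (%s) skipped: %s", depth, e)
                continue
            st.to_csv(out_dir / f"status_persistence_{depth}.tsv", sep="\t", index=False)
            summary["persistence"][f"status_{depth}"] = {
                "n_tested": int(len(st)),
                "n_p_lt_0.05": int((st["p_value"] < 0.05).sum()),
                "n_q_lt_0.05": int((st["q_value"] < 0.05).sum()),
            }

        stage = "core"
        prof_pooled = persistence_profile(
            pre.counts, meta_nc, pool=("time", "depth", "status"),
            exclude_lesional=s["core"]["exclude_lesional"],
        )
        core = identify_core(
            prof_pooled, pre.normalized, meta_nc, threshold=s["core"]["threshold"]
        )
        core.per_participant.to_csv(out_dir / "core_per_participant.tsv", sep="\t", index=False)
        (out_dir / "core_union.txt").write_text("\n".join(core.union) + "\n")
        ubiq = identify_ubiquitous(
            pre.counts, meta_nc, threshold=s["core"]["threshold"],
            include_lesional=not s["core"]["exclude_lesional"],
        )
        (out_dir / "ubiquitous.txt").write_text("\n".join(ubiq) + "\n")
        summary["core"] = {
            "threshold": s["core"]["threshold"],
            "n_core_union": len(core.union),
            "n_ubiquitous": len(ubiq),
            "mean_core_richness": float(core.per_participant["core_richness"].mean()),
            "mean_core_share": float(core.per_participant["core_share"].mean()),
        }
        try:
            comp = compare_core_by_status(
                core, pre.normalized, meta_nc,
                n_perm=s["permanova"]["n_perm"] if s["permanova"]["n_perm"] != "exact" else 999,
                seed=seed,
            )
            summary["core"]["share_test"] = {
                "H": comp["share_test"].statistic, "p": comp["share_test"].p_value,
            }
            summary["core"]["richness_test"] = {
                "H": comp["richness_test"].statistic, "p": comp["richness_test"].p_value,
            }
            if comp["composition"] is not None:
                summary["core"]["composition"] = _result_summary(comp["composition"])
        except ValueError as e:
            logger.warning("core status comparison skipped: %s", e)

        if truth is not None:
            stage = "truth_recovery"
            recovered = []
            for p, planted in truth.core_asvs.items():
                found = set(core.cores.get(p, []))
                if planted:
                    recovered.append(len(found & set(planted)) / len(planted))
            summary["truth_recovery"] = {
                "mean_core_recall": float(np.mean(recovered)) if recovered else None,
                "contaminants_removed": sorted(
                    set(truth.contaminant_asvs)
                    & set(pre.report.removed_asv_ids.get("negative_control", []))
                )
                == sorted(truth.contaminant_asvs),
            }

        stage = "summary"
        _dump_json(summary, out_dir / "summary.json")
        logger.info("pipeline complete: %s", out_dir)
        return summary
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        root.removeHandler(handler)
        handler.close()
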