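# microstrata

Strata-aware spatial-temporal analysis of skin ASV (amplicon sequence
variant) communities. The package takes an ASV count table, sample metadata
(participant, disease status, skin depth, time point, body location,
clinical covariates, negative-control flags) and a taxonomy table, and runs
a reproducible analysis chain:

1. **Preprocessing** — negative-control contaminant filter (ASVs detected in
   ≥ 10 negatives), prevalence filter (ASVs in < 5 samples), taxonomy filter
   (keep Bacteria/Archaea, drop mitochondria/chloroplast), fourth-root
   transform + relative-abundance normalization, with per-stage read-loss
   reporting.
2. **Diversity** — ASV richness and Shannon diversity; within-participant
   temporal β-diversity as richness difference, Jaccard membership overlap,
   and abundance-weighted Yue-Clayton similarity; genus-level aggregation.
3. **PERMANOVA** — from-first-principles distance computation (Bray-Curtis /
   binary Jaccard / Euclidean), Gower centering, sequential (Type I)
   multi-factor variance partitioning, Monte-Carlo or exact-enumeration
   permutation p-values, and strata-restricted permutations with automatic
   whole-block exchange when a tested factor is constant within strata.
4. **Persistence & core community** — per-participant detection-proportion
   profiles, paired-t depth tests and status tests per ASV with
   Benjamini-Hochberg FDR, per-participant core communities at a
   persistence threshold (default 0.7), ubiquitous ASVs, and core
   comparisons between cohorts.
5. **Synthetic studies** — a hierarchical generator (participant-dominant
   log-normal profiles, depth effect as participant-consistent support
   subsetting, pathobiont up-weighting in the disease cohort, negligible
   temporal drift, contaminant-bearing extraction negatives, optional
   lesional samples at varying body locations) with full ground truth, so
   every stage is testable without external data.

## CLI

```bash
# generate a synthetic study
microstrata simulate --seed 1 --out-dir study/

# preprocessing chain
microstrata preprocess --table study/table.tsv --metadata study/metadata.tsv \
    --taxonomy study/taxonomy.tsv --min-negatives 10 --min-samples 5 --out-dir pre/

# diversity tables
microstrata diversity --table pre/counts_filtered.tsv --metadata study/metadata.tsv \
    --taxonomy study/taxonomy.tsv --out-dir div/

# variance partitioning (terms fitted in order; strata optional)
microstrata permanova --table pre/counts_filtered.tsv --metadata study/metadata.tsv \
    --terms skin_status,depth,timepoint,participant_id --n-perm 999 --seed 1 \
    --metric bray_curtis --out permanova.tsv

# persistence profiles + depth tests / core community
microstrata persistence --table pre/counts_filtered.tsv --metadata study/metadata.tsv \
    --by depth --out persistence.tsv
microstrata core --table pre/counts_filtered.tsv --metadata study/metadata.tsv \
    --threshold 0.7 --out-dir core/

# everything at once, from a YAML config
microstrata run-all --config config.yaml --seed 1 --out-dir out/
```

`run-all` writes per-stage TSVs, a deterministic `summary.json` (reruns with
the same config and seed are byte-identical), and a `run.log` with the
parameter echo.

## File formats

- **ASV table**: TSV with first column `sample_id` and one column per ASV
  (samples are rows throughout), or BIOM 1.0 JSON (dense or sparse).
- **Metadata**: TSV with columns `sample_id, participant_id, cohort,
  skin_status, depth, timepoint, body_location, oscorad,
  filaggrin_mutation, is_negative_control`. Missing values are empty
  fields; negative-control rows leave participant-level fields empty.
- **Taxonomy**: TSV with `asv_id` plus rank columns
  (`domain … species`) or a single semicolon-delimited `lineage` column.

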