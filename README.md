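# guildnet

Microbial guild discovery from co-occurrence networks. Given a samples ×
OTUs count table with case/control metadata, `guildnet` provides the full
analysis chain:

- **core_data** — OTU table model with wide-TSV and BIOM-JSON readers,
  read-depth and prevalence/abundance filtering, relative abundance, and
  the centered log-ratio (CLR) transform (optional rarefaction).
- **synthetic_data** — logistic-normal multinomial cohort simulator with
  planted correlated OTU blocks ("guilds"), condition-specific abundance
  shifts calibrated to a target odds ratio, transitional grey samples that
  mix the two condition profiles, and paired maternal–offspring tables.
- **cooccurrence** — Spearman association matrices on CLR data,
  Benjamini–Hochberg FDR across all pairs, signed network construction
  (q < 0.05 and |ρ| ≥ 0.3 by default), topology metrics (density, degree
  centrality, clustering, path length, negative-edge fraction), and
  neighbour-set Jaccard between networks.
- **guild_discovery** — cross-condition stable network (edges significant
  with consistent sign in both groups), Louvain guild detection with
  small-guild merging, Newman–Girvan modularity, Zi–Pi scores, per-sample
  guild abundance, and cross-group bridging sub-networks.
- **null_topology** — node-subset permutation null models (induced
  subgraphs of the observed background, Z-scores and two-sided
  permutation p-values) and attack-robustness curves (largest connected
  component under targeted-by-degree or random node removal).
- **stratification** — stratified 7:3 splitting, SMOTE oversampling,
  L1-selection + random-forest (or gradient-boosting) probability
  pipeline, rank-based AUC, probability-zone assignment
  (Clear_GDM / Clear_NonGDM / grey / unassigned), per-bin
  misclassification, and cross-model grey-zone concordance.
- **epidemiology** — median dichotomization, 2×2 odds ratios with
  Haldane–Anscombe correction, inverse-variance fixed-effect
  meta-analysis with Cochran's Q and I², and covariate-adjusted OLS
  outcome models.

## CLI

```bash
guildnet simulate --n-case 300 --n-control 300 --guild-sizes 17,15,12 \
    --rho-intra-case 0.7 --rho-intra-control 0.7 --seed 1 --out-dir sim/
guildnet network sim/otu_table.tsv sim/metadata.tsv --group case --out case.tsv
guildnet network sim/otu_table.tsv sim/metadata.tsv --group control --out control.tsv
guildnet guilds case.tsv control.tsv --out-dir guilds/
guildnet nulltest case.tsv --target-nodes OTU_0001,OTU_0002,OTU_0003 \
    --n-perm 1000 --seed 1 --out null.json
guildnet robustness case.tsv --strategy targeted_degree --out robustness.tsv
guildnet stratify sim/otu_table.tsv sim/metadata.tsv --out-dir strat/
guildnet meta cohort_tables.tsv --out meta.json
guildnet outcomes outcomes.tsv --outcome birth_length --covariates gest_age \
    --out model.tsv
```

## Conventions

- Depth filter keeps samples at exactly the threshold ("below" is strict).
- OTU filter drops features with prevalence < 10% or mean relative
  abundance < 5×10⁻⁵ (both strict), computed on strictly positive counts
  and relative scale respectively.
- CLR uses a 0.5 pseudocount; rows of the transform sum to zero.
- Edges require BH-adjusted p < 0.05 (strict) and |ρ| ≥ 0.3 (inclusive);
  isolated nodes are dropped unless `retain_isolates` is set.
- Grey zone is 0.4 ≤ P ≤ 0.6 regardless of label; clear zones require
  label concordance (P ≥ 0.7 case, P ≤ 0.3 control); everything else is
  unassigned. `--strict-boundaries` switches the clear bounds to strict.
- Median ties dichotomize to "low"; 2×2 tables with a zero cell get +0.5
  on every cell before the odds ratio and its SE.
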