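# regsubtype

Disease subtyping from per-sample activity of gene-expression regulators.

Conventional expression-based patient clustering works directly on tens of
thousands of genes; the resulting signatures are notoriously unstable across
cohorts. `regsubtype` instead moves the analysis to the level of *regulators*
(transcription factors, complexes, functional classes) wired to their target
genes in a user-supplied regulatory network, and clusters patients on the
activity of *clusters of regulators* — a biology-driven feature reduction from
genes to a few dozen interpretable features. It is intended for
bioinformaticians analysing bulk (or pseudobulked single-cell) transcriptomics
cohorts that contain a control group and a heterogeneous disease group.

## Method

Given a genes × samples expression matrix with a designated control group and
a regulator→target network (typed edges `Expression` / `PromoterBinding`):

1. **Preprocessing.** Intensities are log-transformed, each array is
   standardized to zero mean and unit variance, and synonymous probesets are
   collapsed to the probeset with maximum mean intensity. The control samples
   are averaged into one reference profile and each disease sample *s* gets
   per-gene log-ratios `r_g(s)` against it.
2. **Per-sample sub-network enrichment (SNEA).** For each regulator (seed),
   the log-ratios of its measured downstream targets are compared with the
   background distribution of all genes in that sample by a Mann–Whitney
   U test in which every gene is counted with multiplicity equal to its
   network connectivity (hub correction). Per sample, at most the top 100
   regulators with `p < 0.05` are retained.
3. **Regulator clustering.** The union of regulators found across samples is
   clustered with Ward's method on Jaccard distances between downstream
   target sets, `d(i, j) = 1 − |T_i ∩ T_j| / |T_i ∪ T_j|`; the number of
   clusters maximizes the average silhouette width. This groups redundant
   family members acting on one transcriptional program.
4. **Activity scoring.** Regulator *i* contributes, per sample,
   `K_i = median(r_i) × |r_i|` (median log-ratio of its downstream genes times
   their count); cluster *j* has activity `C_j = Σ_{i ∈ j} K_i`. The genes ×
   samples matrix is thereby reduced to an r × m activity matrix.
5. **Patient clustering and evaluation.** Samples are Ward-clustered on
   Pearson-correlation distance over their activity profiles. Agreement with
   reference labels is measured by the adjusted Rand index (ARI); stability by
   1000 bootstrap runs on 90% subsamples with a 95% CI of the mean ARI and
   per-sample assignment frequencies. Discriminative regulator clusters are
   selected by the Fisher criterion `F = (μ_a − μ_b)² / (σ_a² + σ_b²)` with a
   1000-label-permutation p-value, required to reach `p < 0.05` in more than
   90 of 100 subsampling runs, and reported with their ROC AUC.

A first-class synthetic-data module generates networks with regulator
families (partially overlapping target sets, hub genes) and expression with
planted subtype programs, so every stage is testable with known ground truth.

## Worked example

Simulate the default benchmark (3 subtypes × 10 patients + 10 controls,
6 regulator families × 5 regulators, planted effect δ = 2, noise σ = 0.3) and
run the full pipeline:

```bash
regsubtype simulate --preset default --seed 17 --out data
cat > config.yaml <<EOF
expression: data/expression.tsv
groups: data/groups.tsv
network: data/network.tsv
control_label: control
outdir: results
seed: 17
EOF
regsubtype run --config config.yaml
```

which prints the run summary

```json
{
  "ari_vs_reference": 1.0,
  "bootstrap_ari_mean": 1.0,
  "k_samples": 3,
  "n_regulator_clusters": 6,
  "n_regulators": 30,
  "n_selected_features": 12,
  "variance_support_fraction": 0.42954545454545456
}
```

All 30 planted regulators are recovered and grouped into 6 clusters (the 6
planted families); the patients fall into 3 activity clusters that match the
planted subtypes exactly (`ari_vs_reference = 1.0`) and perfectly reproducibly
under bootstrap subsampling (`bootstrap_ari_mean = 1.0`); 12 (cluster, class
pair) features pass the permutation-stability selection.
`variance_support_fraction` is the share of genes whose variance is lower
within controls than across pooled disease samples — a sanity check for
averaging the controls that is mainly informative on real data (see
`docs/methods.md` for why it sits below 0.5 on this calibrated simulation).
Stage outputs (`snea_records.tsv`, `regulator_clusters.tsv`, `c_values.tsv`,
`sample_clusters.tsv`, `feature_selection.tsv`, a dendrogram in Newick, and a
`manifest.json` with checksums) land in `results/`. The same stages are
available individually (`regsubtype snea`, `cluster-regulators`, `activity`,
`subtype`, `select-features`) and as scikit-learn estimators
(`RegulatorActivityTransformer`, `WardSilhouetteClustering`) for use inside
sklearn pipelines.

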