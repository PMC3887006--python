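# Methods

This note documents the statistical model behind `regsubtype`, the defaults
and why they were chosen, what the synthetic benchmark does and does not
emulate, and the numerical decisions a maintainer should know about.

## Model and procedure

The pipeline assumes that disease subtypes differ by which *regulators*
(transcription factors, complexes, functional classes) are active, and that an
active regulator leaves a coordinated footprint on the expression of its
downstream target genes. Stages:

1. **Log-ratios against an averaged control.** After log transform and
   per-array standardization, control samples are averaged into one reference
   profile and each disease sample is expressed as per-gene log-ratios against
   it. Averaging controls is justified when within-control variance is small
   relative to disease heterogeneity; `variance_support_check` quantifies this
   (fraction of genes with lower variance inside the control group than across
   pooled disease samples).
2. **Connectivity-weighted rank test per (sample, regulator).** The
   log-ratios of a regulator's measured targets are compared with the
   background of all measured genes in the same sample by a Mann–Whitney
   U test in which each gene enters with multiplicity equal to its network
   connectivity (number of incoming filtered edges). Replicating hub genes in
   *both* distributions keeps the two distributions comparable while damping
   the otherwise outsized influence of genes regulated by many seeds. Per
   sample the regulators are ranked by p-value and at most `top_n` (100) with
   `p < p_threshold` (0.05) are kept; no multiple-testing correction is
   applied — the fixed top-k/threshold rule is the selection device.
3. **Regulator clustering.** Regulators found in any sample are pooled and
   clustered by Ward's method on Jaccard distances between their *measured*
   downstream target sets; the number of clusters maximizes the average
   silhouette width over k ∈ [2, min(30, n−1)] (ties go to the smallest k).
4. **Activity.** `K_i(s) = median(r_i(s)) × |r_i|`, `C_j(s) = Σ_{i∈j} K_i(s)`.
   K is evaluated for every regulator in every sample — not only where it was
   individually significant — so the activity matrix is dense. Σ_j C_j = Σ_i
   K_i holds by construction (checked to float roundoff).
5. **Subtyping and evaluation.** Ward clustering of samples on 1 − Pearson
   correlation of activity profiles; k fixed by the user or
   silhouette-selected. Stability: `n_boot` (1000) subsamples of 90% of
   samples without replacement, ARI against the reference restricted to the
   subsample, normal-approximation 95% CI of the mean (percentile CI by flag),
   and per-sample assignment frequencies after matching subsample clusters to
   the reference by maximum overlap. Feature selection per class pair: Fisher
   criterion `(μ_a−μ_b)²/(σ_a²+σ_b²)` (unbiased variances), permutation
   p-value `(1+#{F_perm ≥ F_obs})/(n_perm+1)`, selection when `p < α` (0.05)
   in more than 90% of 100 class-stratified 90% subsampling runs, ROC AUC on
   the full data for selected clusters (positive class = lexicographically
   larger label; AUC < 0.5 means the feature is higher in the other class).

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `top_n`, `p_threshold` | 100, 0.05 | per-sample retention rule for enriched regulators |
| `min_targets` | 3 | smallest downstream set worth testing; guards degenerate rank tests |
| `weighting` | `connectivity` | hub correction; `downstream` (one-sided weighting) and `none` available for sensitivity analysis |
| `exclude_targets_from_background` | false | background = all measured genes, including the tested set (see calibration below) |
| `exact_limit` | 10 000 | exact enumeration of the permutation distribution when replicated `n_a·n_b` is at most this product; otherwise normal approximation with tie and continuity correction |
| regulator k range | [2, min(30, n−1)] | silhouette search space |
| `n_boot`, `fraction` | 1000, 0.9 | bootstrap stability runs and subsample share |
| `n_perm`, `n_runs`, `alpha`, stability | 1000, 100, 0.05, 0.9 | permutation feature selection: significant in >90/100 runs |

Log base is 2 (irrelevant to rank statistics; fixed for reproducibility).
Standardization is per array (per sample column), the standard reading for
microarray-style intensities; a per-gene axis would change the meaning of
log-ratios and is deliberately not the default. Probeset collapse keeps the
probeset with maximum mean raw intensity (ties broken lexicographically by
probeset id, then input order). Rows with missing values are dropped with a
logged count; missing-value imputation is out of scope.

## Connectivity definition

Connectivity of a gene is its in-degree under the active relation-type filter,
counting distinct (seed, target, type) edges, so connectivities sum exactly to
the number of filtered edges; a variant counting outgoing edges of genes that
are themselves seeds (`connectivity_mode="total"`) is available. In a global
curated database the analogous quantity is the gene's total relation count;
within a user-supplied network the filtered in-degree is the faithful analog.

## Exact and approximate p-values

The weighted test is defined by explicit replication: its result is identical
to the standard Mann–Whitney test with every value repeated `weight` times.
When the replicated group-size product is within `exact_limit`, the exact
conditional permutation distribution of the rank sum (ties included, via
midranks) is computed by a dynamic program over the smaller side — the DP size
is bounded because min(n_a, n_b) ≤ √(n_a·n_b). Above the limit, the normal
approximation with tie correction and a 0.5 continuity correction is used,
matching the standard asymptotic formula. Two-sided p-values are
`min(1, 2·min(P≤, P≥))`.

## Calibration

Under a global null with disjoint target sets and unit connectivity, the
per-regulator rejection rate at p < 0.05 sits inside the binomial band around
5% when the background excludes the tested set (a genuine two-sample
comparison). Two deliberate departures from the textbook two-sample setting
change this slightly and are worth knowing:

- **Inclusive background (default).** Testing a set against a background that
  contains it reduces the true variance of U below the independent-two-sample
  value, making the default test mildly *conservative* (≈0.044–0.047 observed
  at 20 targets vs ≈1400 background genes). It never inflates false
  positives; with realistically large backgrounds the effect shrinks with
  `n_targets / n_background`.
- **Connectivity weighting.** Replicated copies of a gene co-move, violating
  the independent-observation assumption of the null distribution, so the
  weighted test's nominal level is not exactly 5% either. The weighting is a
  hub-bias correction, not a calibrated test; rankings within a sample are
  the quantity of interest.

The calibration experiment in the acceptance suite therefore runs the delta=0
preset with disjoint targets, unit connectivity and the excluded-background
option, where the nominal level is the correct reference; both background
variants' rates are reported.

## Synthetic benchmark

`simulate_network` draws regulator families from a finite gene pool without
replacement: members of a family share exactly `⌈ρ·t⌉` core targets (ρ = 0.6,
t = 20 by default), families are otherwise disjoint, and a `hub_fraction` of
the pool becomes hub genes wired to a random 30–70% of all regulators.
`simulate_expression` gives every gene a shared baseline N(0, 1) plus
per-sample noise N(0, σ²) in log space, and shifts the targets of each disease
sample's active regulator families additively. Because the pipeline
re-standardizes every column, the planted shift is calibrated per sample by a
scalar root-find so that the *realized* mean log-ratio of planted targets —
after standardization and control subtraction — equals δ exactly; this is
feasible only while δ < √((1−f)/f) for planted fraction f, and a sizing error
is raised otherwise.

The default benchmark (the study conditions for the recovery ladder): 6
families × 5 regulators, ρ = 0.6, hub fraction 0.02 over a 400-gene target
pool, 1000 untargeted background genes, 3 subtypes × 10 samples + 10 controls,
2 active families per subtype, δ = 2, σ = 0.3. The null preset for
calibration: 5 families × 5 regulators with ρ = 0, no hubs, δ = 0, 800
background genes, 2×2 disease samples + 5 controls.

What the generator does *not* emulate: probe-level artifacts, batch effects,
gene–gene correlation beyond shared regulator programs, down-regulated or
sign-mixed programs (up-shifts only by default; a signed mode exists but skips
the effect-size calibration), and realistic network noise (false edges,
missing targets). Passing the recovery ladder therefore shows the machinery
is correct and sensitive under its own model, not that real cohorts will
separate this cleanly. One visible artifact: the per-column rescaling that
pins the realized effect size slightly compresses disease-column noise, so
`variance_support_check` — which on real data supports control averaging —
sits below 0.5 on the simulation; it is reported in the pipeline summary but
is not a recovery metric.

## Numerical choices and degenerate inputs

- Ward linkage is applied to the Jaccard (and Pearson) distance matrices via
  the standard Lance–Williams update, the common practical choice for
  non-Euclidean dissimilarities; average linkage is available.
- Silhouette ties (within 1e-12) resolve to the smallest k; cluster labels are
  renumbered 1..k in order of first appearance.
- Constant (zero-variance) sample columns are rejected by name at
  standardization and at Pearson-distance computation; all-tied rank tests
  return p = 1.
- Fisher criterion with both variances zero returns 0 for equal means and an
  infinite sentinel for distinct means; permutation p-values use the add-one
  estimator and are never zero.
- Bootstrap cluster matching uses maximum overlap with ties to the smaller
  reference label.
- One global seed drives everything; per-stage seeds derive via
  `SeedSequence(seed, spawn_key=(stage,))`, so stages can be rerun in
  isolation. Stage outputs are written with a fixed float format and sorted
  JSON keys; reruns with the same config are byte-identical.

## Problem sizes in tests and acceptance

The test and acceptance runs use the benchmark above (~1320 genes, 30 disease
samples, 30 regulators), 200 null replicates for the enrichment calibration,
400 simulations for the permutation type-I rate, 1000 bootstrap runs, and
500–1000 random instances for the oracle and identity checks — sizes at which
every check is decisive yet the whole suite completes in a few minutes on one
core.

## Known limitations

- Edge direction of effect (activation vs repression) is not modelled; a
  regulator driving half its targets up and half down scores a small K.
- No identifier mapping: expression gene ids and network target ids must
  share a vocabulary.
- No FDR control in SNEA (by design, matching the fixed top-k rule) and no
  survival analysis or supervised classifiers downstream.
- PAM and GSVA comparison baselines are not reimplemented; the sample
  clustering and ARI machinery accepts gene-level features (`feature_source:
  genes`) or externally produced label files for comparisons.
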