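# Methods

This note documents the statistical model behind `synergyshift`, the
choices made where the published procedure leaves freedom, and what the
synthetic test bed does and does not establish.

## The problem

Immune checkpoint blockade (anti-PD-1) benefits only a minority of
patients. The package implements an in-silico strategy for finding
chemo- or targeted-therapy compounds whose transcriptional effect on
tumor cells pushes them from a resistant toward a sensitive state, so
that they are candidate partners for combination with anti-PD-1.

The strategy has four stages:

1. **Response signatures.** From paired tumor transcriptomes sampled
   before and during anti-PD-1 therapy, compute each patient's
   treatment-induced expression change per gene,
   `log2((post + c) / (pre + c))` on the linear scale (pseudocount
   `c = 1` by default). A two-sided Wilcoxon rank-sum test compares
   induced changes between responders and non-responders gene by gene;
   genes with `p < 0.05` form the **S (sensitivity) signature** when
   the responder median change is higher and the **R (resistance)
   signature** when the non-responder median is higher.
2. **Shift ability.** Each perturbation experiment (a level-5-style
   z-score profile of a compound or shRNA treatment in one cell line)
   is ranked descending and scored with the weighted-KS enrichment
   score (weight 1) against both signatures. The shift ability is
   `ΔES = ES_S − ES_R ∈ [−2, 2]`; experiments with `ΔES ≥ 0.7` are
   called R-to-S shifters. Profiles with transcriptional activity
   score (TAS) below 0.4 are discarded first.
3. **Target prioritization.** A drug target is *concordant* when an
   efficient shRNA knockdown of it and a compound inhibiting it both
   make R-to-S calls in the same cell line. Concordant targets whose
   tumor expression is significantly negatively Pearson-correlated
   (`p < 0.05`) with ssGSEA immune-activation class scores in at least
   `min_types` cancer types are *prioritized*.
4. **Mechanism clustering.** Calling compounds' experiments are
   ternarized (z > 1 → +1, z < −1 → −1, strict) and summed per
   compound into consensus vectors; compounds are Ward-clustered on
   `1 − Pearson r` distance, each cluster summarized by the per-gene
   median consensus ranked descending and annotated by preranked GSEA.

## The enrichment engine

The running-sum statistic walks the ranked list, adding
`|score|^w / Σ_hits |score|^w` at gene-set members and subtracting
`1/(N − N_hits)` elsewhere; the ES is the signed maximum deviation from
zero (single two-sided extremum; exact `max = −min` ties resolve
positive). Conventions:

* Ranking ties break deterministically (score descending, then gene id
  ascending). This makes screens bit-reproducible.
* Set members absent from the profile are dropped before scoring and
  reported in `n_overlap`.
* If every hit has score exactly 0 at `w > 0`, hit mass falls back to
  uniform so the statistic stays defined.
* NES / nominal p / FDR use a **gene-set permutation null** (random
  same-size sets drawn without replacement from the profile), the only
  feasible null for a single preranked list. `NES = ES / mean(|null ES|
  of the same sign)`; nominal p is the add-one-smoothed same-sign tail
  fraction; FDR is the sign-stratified ratio of tails on the pooled
  normalized null. When no null of the observed sign exists, NES and
  FDR are reported as undefined rather than fabricated. The published
  cluster-annotation NES/FDR magnitudes came from an unspecified
  implementation, so exact reproduction of those values is not claimed.
* ssGSEA orders a sample's genes by decreasing expression, weights hits
  by rank value `(N − position + 1)^τ` (default exponent τ = 0.25,
  configurable), and sums the running hit-minus-miss difference over
  all positions. No cross-sample normalization is applied.

## Statistical choices

* **Rank-sum test:** two-sided, with direction assigned post hoc by the
  responder-minus-non-responder median difference; exact null when both
  classes have ≤ 10 patients, tie-corrected normal approximation
  otherwise. Genes significant with exactly tied medians are excluded
  and logged. Raw p-values are used by default (matching the reference
  procedure); a Benjamini–Hochberg option exists but is off.
* **Surrogate changes:** cohorts without paired sampling use per-gene
  mean-centered expression (deviation from the cohort population
  baseline, computed in log space) as a stand-in for induced change.
  The baseline statistic is the mean; rows of the output are exactly
  mean-zero.
* **PCA response score:** gene-centered, unscaled; the arbitrary PC
  sign is fixed by non-negative correlation with the combined
  signature score (when available), otherwise by making the
  largest-magnitude loading positive.
* **ROC AUC** equals the concordant-pair fraction with ties counted
  1/2.
* **Knockdown efficiency** (a relative comparison in the original
  description) is operationalized as: target z-score negative **and**
  at or below the 25th percentile (linear interpolation) of that
  gene's values across all experiments in the same cell line. Both the
  sign requirement and the percentile are configurable.
* **"Suppresses the R signature"** is operationalized as `ES_R < 0`
  (induction as `ES_S > 0`); an optional permutation-p gate exists in
  the enrichment layer but the screen calls on the sign plus the
  `ΔES ≥ 0.7` threshold, which is inclusive.
* **Ward on correlation distance:** the Ward update rule is applied
  directly to the precomputed `1 − r` matrix (the "Ward on distances"
  convention). Merge heights therefore live on a convention-dependent
  scale; the published absolute dendrogram cutoff (12) is exposed as a
  parameter, and the tested default is an automatic two-cluster cut.
  Constant consensus vectors get correlation 0 (distance 1) with a
  warning. Compounds are sorted by id before linkage so results do not
  depend on input order.
* **Survival:** single-covariate Cox proportional-hazards fits (Efron
  tie handling, via lifelines), hazard ratio `exp(β)` with Wald p.
  Degenerate covariates, absent events, or non-convergence yield
  flagged results, never a fabricated HR. The tertile log-rank test
  splits samples evenly by score (stable sort, ties to the lower
  tertile, group sizes within one) and compares only the top and
  bottom groups. The survival endpoint is whatever time/event columns
  are supplied; the package does not adjudicate between overall
  survival and progression-free interval.
* **Prioritization rule:** the published description does not fully
  specify how concordant targets were reduced to the prioritized list
  (number of cancer types, immunity classes, sign conventions). The
  rule here — significantly negative Pearson correlation with
  immune-class scores in ≥ `min_types` types (default 1) — is a
  documented parameterization, not a claim of exact reproduction.

## The synthetic test bed

The generators produce data with the structure the analysis assumes,
at a reduced default scale (2,000 genes; ~200 compounds × 3 cell
lines; 20 shRNA targets; 5 cancer types × 100 tumors) sized so the
full pipeline runs in minutes on one CPU. Per-seed runs are pure
functions of their parameters.

* **Paired cohort:** log2-scale expression = per-gene baseline
  `N(7, 1)` + `N(0, σ)` noise; induced change `N(0, σ)` shifted by
  `effect·σ` on planted S genes in responders and planted R genes in
  non-responders. With 20+20 patients and a 1.5σ effect the rank-sum
  split recovers ≳ 95% of planted genes with no direction errors, and
  the null false-positive rate sits at the nominal α.
* **Compendium:** profiles are `N(0, 1)` z-scores; shifters add `+γ`
  on planted S genes and `−γ` on planted R genes (default γ = 2);
  shRNA profiles set their target gene to −3 (± 0.3 noise). Mechanism
  groups add +2 to dedicated gene modules so that consensus clustering
  has recoverable structure. TAS is modeled as high (≥ 0.4,
  Beta-shaped) for transcriptionally active perturbagens and low
  (Beta(2,3)) for inert ones — TAS measures replicate reproducibility,
  which is genuinely high when the induced signal is strong — so the
  TAS filter removes mostly inert experiments, as in the real
  compendium.
* **Pan-cancer cohort:** a per-sample latent immune factor `z` loads
  positively on immune-signature genes and infiltration estimates and
  negatively on planted anti-immune targets; planted S genes track
  `+z`, R genes a partially opposed axis. Survival times are
  exponential with log-hazard `β · z_R`, where `z_R` is the
  standardized mean R-gene deviation recomputed from the final
  expression matrix — exactly the covariate the association stage
  derives — with independent exponential censoring.

What passing tests show: the statistics are implemented correctly
(oracle agreement to 1e-12), calibrated under the null (uniform
permutation p-values, ~0 mean null shift, nominal FPR), and able to
recover planted structure at realistic effect sizes. What they do not
show: behavior under real-data pathologies the generators omit —
heavy-tailed and correlated noise, batch effects, L1000 inference
artifacts, non-proportional hazards, and cohort composition biases.
Published headline numbers (patient-cohort AUCs, the 1,190/130-gene
signature sizes, 780 shifting compounds, the 49 → 17 target funnel,
TCGA correlations and hazard ratios) depend on external accessions and
are not reproducible from synthetic data; the published source itself
reports the S-signature size inconsistently (130 in one place, 139 in
another), and this implementation simply reports whatever the stated
procedure yields.

## Degenerate inputs and numerical details

ES values are clipped to [−1, 1] against floating-point overshoot;
all-hit profiles have a zero miss step; constant genes get p = 1 in
the signature test; constant covariates and event-free cohorts yield
flagged survival results; empty set/profile overlaps raise
`UnscorableSetError` naming the offending set. Output tables are
written with `%.10g` formatting and a header carrying the config hash
and seed, so identical configurations rerun to byte-identical files
(GCTX files are written without HDF5 timestamps for the same reason).
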