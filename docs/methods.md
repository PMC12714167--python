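# Methods

This note documents the models, conventions and numerical choices behind
`ctrlcircuit`, what its synthetic-data generators do and do not emulate,
and the known limitations.

## Linear network model and average controllability

Brain activity is modelled as a discrete, noise-free, linear
time-invariant system over N parcellated regions,

    x(t+1) = A x(t) + B_k u_k(t),

where `A` is the subject's symmetric FA-weighted structural connectome,
`B_k = (e_k1, …, e_kp)` selects the control regions, and `u_k` is the
external input. We use single-region control sets throughout (`p = 1`,
`B = e_i`), since the quantity of interest is reported per region.

**Stabilization.** The infinite-horizon Gramian series only converges when
the spectral radius of `A` is below 1, which raw FA matrices violate. We
normalize `A ← A_raw / (1 + λ_max(A_raw))`, the dominant convention in the
network-control literature, giving spectral radius `λ_max/(1+λ_max) < 1`.
This choice changes *absolute* controllability values (they are
convention-dependent and not comparable across normalizations); group
contrasts and the across-region ranking are what carry meaning. The
normalization is deliberately not scale-free: multiplying the raw matrix
by a constant moves the post-normalization spectral radius, so only
stability and node ranking — not values — survive pre-scaling (asserted in
tests).

**Average controllability** of region k is the trace of the
infinite-horizon controllability Gramian,

    a_c(k) = trace( Σ_{t≥0} A^t e_k e_kᵀ (Aᵀ)^t ) = Σ_{t≥0} ‖A^t e_k‖²,

the unique solution trace of the discrete Lyapunov equation
`W = A W Aᵀ + e_k e_kᵀ`. It is ≥ 1 (the t = 0 term) and finite for stable
`A`. The single-node implementation calls the SciPy Lyapunov solver; the
cohort path exploits symmetry: with `A = V diag(λ) Vᵀ`,
`a_c(k) = Σ_i V_ki² / (1 − λ_i²)`, so all N values come from one
eigendecomposition. The two routes agree to machine precision and both are
checked against a truncated power series (horizon 1000, tolerance 1e-8).

**Group comparison.** Per region: Shapiro–Wilk per group at α = 0.05 with
an all-groups-pass rule routes to one-way ANOVA (all normal) or
Kruskal–Wallis; omnibus p-values are BH-FDR corrected across regions, and
pairwise post hocs (matching the omnibus family) run only where the
omnibus survives. The "circuit framework" comparison restricts the region
set to the nodes incident to the significant differential component.

## Network-based statistic

Edgewise pooled-variance two-sample t-tests; edges with zero weight in
every subject are excluded (their variance is zero and the statistic
undefined). The primary component-forming threshold is two-sided
p < 0.001 (uncorrected) by default. Components are connected edge sets of
the suprathreshold graph; component size is edge count (extent), not
intensity. Family-wise error control uses the permutation null of the
maximum component size with uniform label shuffles;
`p = (1 + b)/(n_perm + 1)` (never zero, valid under exchangeability), with
the observed labeling never replayed as a permutation. The sign of a
component's mean t is reported so the direction of the group difference is
recoverable. Default 5000 permutations; the demo configuration uses 1000.

Behavioral relevance of a detected subnetwork is assessed by partial
correlation of per-subject mean component strength with each scale score,
residualizing both on age, sex (coded 0/1), education and medication load;
p-values are Bonferroni-corrected across the battery of scales. All-zero
covariate columns carry no information and are dropped (so the partial r
degenerates gracefully to the plain Pearson r); genuinely collinear
covariates are an error naming the offending column.

Contrast construction: the suicidal-ideation circuit compares patients
with vs. without ideation; the suicidal-behavior circuit merges both
non-behavior patient groups and compares them with the behavior group.
Healthy controls enter the controllability group comparison but not the
circuit contrasts.

## Expression-atlas preparation

Tissue samples are assigned to the nearest region centroid within 2 mm
(Euclidean; exact ties go to the lower region index), others dropped with
a logged count. Within each donor, each gene is normalized by the scaled
robust sigmoid `1/(1+exp(−(x−median)/(IQR/1.35)))` followed by min–max
rescaling to [0, 1]; IQR/1.35 approximates a robust standard deviation,
the transform is rank-preserving, and constant genes map to 0.5.
Cross-donor consistency uses differential stability — the mean pairwise
Spearman correlation of donor region-profiles — with default threshold
0.1 (a package default; exposed in config). Retained genes are pooled
across donors by region means; regions without samples stay explicitly
missing, never zero-filled. Probe-level processing (annotation, intensity
filtering, probe selection) is upstream of this module's input boundary:
inputs are gene-level. A region-label filter realizes the left-hemisphere
restriction.

## Coexpression modules

Samples are regions, variables are genes. Unsigned adjacency
`a_ij = |cor(g_i, g_j)|^β`; β is the smallest candidate (1–20) whose
scale-free fit index (signed R² of the log–log degree-distribution
regression, 10 bins) reaches 0.85. When no candidate reaches the target —
typical for block-structured synthetic data, which is not scale-free — the
standard sample-size default for unsigned networks is used (9 below 20
samples, 8 below 30, 7 below 40, else 6) with a warning; maximizing the
fit index instead favours extreme powers that zero out the adjacency.

The topological overlap matrix is
`TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`,
`TOM_ii = 1`; `1 − TOM` feeds average-linkage hierarchical clustering.
Branch cutting is a simplified dynamic rule: a static cut at 0.99 of the
maximum merge height, clusters below the minimum module size (default 100
genes) to the grey background, then iterative merging of modules whose
eigengenes are closer than 0.25 (1 − correlation). This is deliberately
simpler than the full dynamic hybrid tree cut (no PAM stage, no per-branch
adaptivity); planted-partition recovery tests (ARI ≥ 0.8 at within-module
r = 0.7) gate its adequacy. Detection is fully deterministic. Modules are
named by descending size in the standard color order (turquoise, blue,
brown, …).

A module eigengene is the first principal component (unit-norm score
vector over regions) of the z-scored module submatrix, sign-oriented to
correlate positively with its member genes on average; constant gene rows
are dropped from the PCA with a warning. Because orientation is anchored
to the member genes, negating every gene flips the eigengene coherently
and leaves all module-membership values unchanged. Module–trait
association is Pearson r with BH-FDR across all module × trait cells
(pairwise exclusion of missing regions; at least 4 required). Hub genes
satisfy |MM| > 0.8 and |GS| > 0.5, with MM the correlation with the own
module's eigengene and GS with the trait.

**Regional trait.** For the end-to-end pipeline the trait is, per region,
the summed |t| of significant differential edges incident to it (zero
elsewhere), restricted to the modelled left hemisphere (the first half of
the parcellation). When no differential component exists (null runs) the
pipeline falls back to an independent generated trait and records the
fallback in the report.

## Enrichment

**ORA.** For universe N, term K, list n, overlap x: hypergeometric upper
tail `P[X ≥ x]`; enrichment factor `(x/n)/(K/N)`. Reporting filters:
p < 0.01, overlap ≥ 3, factor > 1; results sorted by p with a top-5
reporting mode. The universe defaults to all atlas genes (the
coexpression background), not the genome.

**EWCE.** Specificity is each gene's mean expression per cell type divided
by its row sum (all-zero genes dropped). The observed statistic is the
target list's mean specificity per cell type; bootstrap lists of the same
length are drawn uniformly without replacement from the background —
without transcript-length or expression-level matching, a documented
simplification. `p = (1 + b)/(n_boot + 1)`, plus the
standard-deviations-from-the-mean z, BH-FDR across cell types; multiple
target lists are corrected independently. Default 10 000 bootstraps
(1000 in the demo).

## Validation statistics

Per-gene two-sample tests gated by the same Shapiro–Wilk rule (t-test vs.
rank-sum), DEGs at p < 0.05, candidate genes = DEGs ∩ hub list. AUC uses
the Mann–Whitney rank statistic `U/(n₁n₂)` with tied pairs counted 1/2,
equal by construction to brute-force pairwise comparison.

## Synthetic-data generators

The generators define the study conditions and write their planted truth
as a JSON sidecar, so every downstream detector can be scored without
re-deriving the structure.

- **Connectomes.** A shared random geometric base topology: parcel
  "centroids" uniform in the unit cube, edges within radius 0.45,
  weights decaying linearly with distance within the FA-like range
  [0.2, 0.7]. Per subject, Gaussian edge noise (sd 0.1) is added and
  weights are clipped to [0, 1]; matrices are exactly symmetric with zero
  diagonal. Planted differential edges are forced into the topology at
  mid-range weight and attenuated by `edge_effect × noise_sd` in the
  affected group, so `edge_effect` is the standardized mean difference at
  those edges. Phenotype scale scores are Gaussian fixtures with
  group-typical centers for a depression cohort (ideation scoring
  highest on depression severity, behavior lower; controls near floor on
  symptom scales) — fixtures for exercising the statistics, not estimates.
- **Expression atlas.** Block-correlation design: module gene =
  `√w·f_m + √(1−w)·ε`, so two module genes correlate at w. The module
  factor is `tc·trait + √(1−tc²)·η` with η orthogonalized against the
  trait *in-sample*, so the factor's empirical trait correlation is
  exactly tc and the planted value is recoverable without sampling bias.
  Background genes are independent noise.
- **Cell-type reference.** Lognormal per-gene baselines shared across cell
  types times mild multiplicative gamma noise (mean 1, cv 0.1);
  specificity is therefore uniform (1/C) in expectation. The enriched
  module's genes are multiplied by the fold in the target cell type,
  giving expected specificity ≈ fold/(fold + C − 1) there.
- **Validation dataset.** Unit-variance Gaussian expression; listed genes
  shifted by their standardized effect size in the case group.

What the generators do **not** emulate: diffusion-MRI signal or
tractography (streamline counts, distance biases, false-positive bundles),
spatial autocorrelation of expression, probe-level microarray artifacts,
realistic gene-regulatory structure beyond block correlation, and
site/batch effects. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under its stated
assumptions — not that effect sizes in real cohorts are detectable.

## Problem sizes and seeds

Demo and test runs use scaled-down but structurally faithful sizes chosen
as the package's own defaults: 60–90 regions (vs. 360 in a full Glasser
parcellation), 15–20 subjects per group, 500–700 genes over 120 regions
with 100–150-gene modules, 500–1000 permutations/bootstraps. Calibration
checks use 200 null datasets (NBS family-wise error), 50-seed power
sweeps, and 20-seed global-null pipeline runs. The pipeline fans a single
seed into per-stage seeds via `seed·100 + stage_index`, so any stage can
be re-run in isolation; identical config + seed gives byte-identical
outputs end to end.

## Known limitations

- Absolute ANC values depend on the stabilization convention; only
  contrasts and rankings are interpretable across conventions.
- The simplified tree cut can split or absorb modules whose dendrogram
  branches are not height-separated; the full dynamic hybrid algorithm is
  out of scope.
- The NBS tests raw group differences at edges; covariate-adjusted
  edgewise models and intensity-weighted component statistics are not
  implemented.
- EWCE bootstrap lists are unmatched for expression level; with strongly
  skewed baselines this is anti-conservative relative to matched
  sampling.
- The hypergeometric ORA treats gene sets as unstructured; no term
  hierarchy or redundancy pruning.
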