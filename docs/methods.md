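# Methods

`methylsubtypes` implements a complete cross-cohort DNA-methylation
subtyping workflow for late-onset Alzheimer's disease (LOAD): unsupervised
discovery of methylation subtypes within each postmortem brain cohort,
replication of those subtypes across cohorts, and downstream
characterization by epigenome-wide association, enrichment, colocalization
and transcriptomic analysis. Because the brain-bank datasets this kind of
study uses are access-restricted, the package ships a synthetic multi-cohort
generator with known ground truth; every stage is exercised against planted
signal and against its null.

## The synthetic study

`simulate.SimulationConfig` fixes the study conditions. Defaults describe
the reference experiment used by the analysis scripts and the acceptance
checks:

| parameter | default | meaning |
|---|---|---|
| `n_cohorts` | 3 | independent cohorts |
| `n_load_per_cohort` / `n_hc_per_cohort` | 150 / 75 | disease / control samples |
| `n_probes` | 5,000 | CpGs per cohort before platform masking |
| `n_shared_subtypes` | 2 | latent disease subtypes present in every cohort |
| `cohort_specific_cluster` | on (cohort 0) | a third latent group in exactly one cohort |
| `frac_subtype_cpgs` | 0.05 | causal CpGs per group (disjoint sets) |
| `delta_beta` | 0.10 | beta-scale shift at causal CpGs |
| `noise_sd` | 0.25 | logit-scale residual sd (≈0.06 beta sd at beta 0.5) |
| `platform_mask_fracs` | {cohort 2: 0.6} | 450K-like probe subset in one cohort |

Methylation is simulated on the logit scale — beta_ij =
logit⁻¹(logit(μ_j) + subtype effect + Σ_c w_jc γ_c x_ic + ε_ij) — so values
stay inside (0,1) while covariate effects (age, sex, cell proportions,
batch; per-probe random weights w_jc) are exactly linear on the modelling
scale. The subtype offset for a causal CpG is the logit-scale step whose
inverse image moves the baseline beta by ±`delta_beta`; causal CpGs are
drawn from baseline beta ∈ [0.35, 0.65] so logistic curvature does not
distort the planted beta-scale difference. `noise_sd` = 0.25 was chosen
once to put the within-group beta sd near 0.06 — the magnitude typical of
the *variable* CpGs that survive a deviation filter in cortical array data;
most CpGs on a real array are far less variable, but those never reach the
clustering stage. Each generator (methylation, bulk counts, single-cell
counts, panels, summary statistics) draws from its own named RNG substream
of the master seed, so adding a generator never perturbs another's output.

What the generator does **not** emulate: probe-type chemistry and
normalization artifacts, spatial/chromosomal correlation between CpGs
(probes are independent given the latent factors), realistic LD (coloc
regions use independent variants), cell-type deconvolution error
(proportions are observed covariates), and dropout structure in the
single-cell counts beyond the negative-binomial. Passing tests therefore
show that the *procedures* behave as specified under their own model
assumptions, not that the biological effect sizes of real cohorts are
recoverable.

## Pre-clustering preparation

Each probe is adjusted by OLS on the covariates (intercept always included;
near-collinear designs are rejected naming the offending columns), and the
residuals feed all discovery steps. Non-variant probes are removed by a
robust deviation score: the 90th percentile of |value − probe median|.
Because an absolute cutoff cannot be transported between datasets, both an
absolute-threshold mode and a keep-top-fraction mode are provided; the
pipeline uses the top 20% of probes. Cohorts on different array generations
are harmonized to their probe-set intersection in lexicographic order.

## Subtype discovery

Two algorithms cluster the disease samples of one cohort: Ward.D2
agglomerative clustering on Euclidean distances (scipy's `ward` linkage)
and k-means (25 k-means++ restarts, seed recorded). The cluster count is
chosen in two stages, mirroring how elbow screening and agreement
arbitration are used in practice:

1. **Elbow per algorithm** — k maximizing the second difference of the
   within-cluster-sum-of-squares curve; ties go to the smallest k. The full
   curve is returned for audit, and a *weak elbow* is flagged when the
   maximal second difference is below 0.25 of the total WCSS drop —
   clustered data produce relative curvature near 0.5, unstructured noise
   stays under about 0.2 (measured on simulation, not tuned to a dataset).
2. **NMI arbitration** — among the elbow candidates, the k with the highest
   normalized mutual information between the two algorithms' partitions
   (ties to smallest k). NMI is normalized by the average of the two
   entropies and cross-checked against scikit-learn in the tests.

K-means labels are aligned to the hierarchical label space by the Hungarian
maximum-agreement matching on the contingency table; samples on which the
aligned labels disagree are marked inconsistent and excluded from subtype
membership. Cluster names are canonicalized by decreasing size — names
carry no meaning, and deterministic naming replaces arbitrary relabeling.

## Sparse PLS-DA and the feature-stability check

The sPLS-DA is sparse PLS in the Lê Cao formulation: per component the
dominant singular pair of the deflated X'Y cross-covariance is iterated
with soft-thresholding so exactly `keepX` X-weights survive (unit norm),
X and Y are deflated by regression on the component score, and the rotation
R = W(PᵀW)⁻¹ maps standardized data straight to scores, making projection
of a replication cohort a single matrix product (training round-trip is
exact; the dense limit is verified against a power-iteration oracle).
Feature stability follows the label-randomization design: for each
proportion p and repetition, the labels of a random ⌈pn⌉ sample subset are
shuffled among themselves (class frequencies preserved), the model is
refit, and the overlap of the selected-feature union with the original
union is compared with the hypergeometric chance level s²/m.

## Cross-cohort replication and confirmation

*Probe level.* Per-cluster median profiles (on the common replication probe
space — the intersection of the per-cohort variable-probe selections) are
correlated between cohorts; clusters are paired by a mutual-best-match rule
(r must be both its row and column maximum, above a configurable floor).

*Sample level.* A replication cohort is projected into the discovery
cohort's first two latent components; a convex hull (exact geometry, with a
10⁻⁹-relative buffer so boundary points count as inside) is drawn around
each discovery cluster, and each (replication cluster, discovery hull) cell
gets an upper-tail hypergeometric p. Two populations are reported. The
plain version uses all projected replication samples. The version used for
confirmation conditions on the samples that fall inside at least one hull:
projecting new data through a supervised model shrinks class separation
relative to the overfit training scores, so a large fraction of the
replication cloud can land outside every hull for reasons unrelated to
cluster identity, and the unconditional test loses power precisely when the
replication is genuine. Conditioning preserves an exact hypergeometric null
(labels are independent of geometry under no association; verified
KS-uniform in the test suite) while asking the sharper question — does a
replication cluster concentrate in the matching hull. Hull p-values are
Bonferroni-corrected over the tested cells of each direction.

A subtype is **confirmed** when a set of clusters, one per cohort, is
mutually matched by correlation *and* hull-significant in every ordered
direction, under both clustering algorithms (cliques are computed per
method and intersected; overlapping cliques are resolved greedily by total
correlation). Clusters in no confirmed clique are **Unassigned**, and
samples with inconsistent dual-algorithm labels are reported as Unassigned
as well.

## Subtype EWAS, empirical null, meta-analysis

Each subtype is contrasted against controls with the other disease samples
excluded (the reference-group choice is switchable); per probe, methylation
is regressed on the group indicator, the covariates and surrogate
variables. Surrogates are the leading right singular vectors of the data
after projecting out the full design *including the contrast* — leaving
the contrast out would let the first surrogate absorb the subtype signal
itself. Their number is chosen by a permutation rule: each probe's values
are permuted across samples, re-residualized, and components are kept while
their singular value exceeds the maximum permuted value (20 permutations;
~95% specificity on unstructured data).

Test-statistic calibration uses the empirical-null (bias μ, inflation σ)
model of a three-component normal mixture on z = effect/se, fitted by EM
with median/MAD initialization — a deterministic replacement for the Gibbs
sampler usually used for this model; stochastic equivalence is not claimed,
but the estimator recovers planted (μ=0.3, σ=1.4) contamination to ±0.05
at 50k probes. Correction (z′=(z−μ)/σ, se′=se·σ) is applied only when
σ > 1.05 or |μ| > 0.05. The genomic inflation index λ is the median
observed χ²₁ quantile over 0.4549.

Cohorts are combined per probe by inverse-variance weighting; the default
is random-effects with REML τ² (standard fixed-point iteration, verified
against r-metafor), fixed-effects available; Q and I² are reported from
fixed weights. Cohorts lacking the contrast group (a cohort-specific
Unassigned cluster) are skipped, down to a flagged single-study
passthrough. DMPs require Bonferroni-adjusted meta p strictly below 0.05,
with m = the number of meta-analyzed probes.

## Overlap statistics, panels, ORA

Feature-list overlaps are summarized by Fisher's conditional
maximum-likelihood odds ratio — the ψ solving E[A | margins, ψ] = a under
the noncentral hypergeometric model, computed from exact log-space weights
and bracketed root-finding (relative tolerance 10⁻⁶; cross-checked against
`scipy.stats.contingency.odds_ratio`) — with an upper-tail hypergeometric
enrichment p. The sample odds ratio ad/bc is always reported alongside.
The default universe for DMP overlap tests is the meta-analyzed probe set.
Cell-type CpG panels are tested per (cell type × specificity level) with
BH adjustment across panels; the generic over-representation test takes
user-supplied GMT gene sets (size bounds 10–2000 by default).

## Colocalization

Per variant, the Wakefield log approximate Bayes factor
0.5·log(1−r) + 0.5·r·Z² with r = W/(V+W), prior effect variance W = 0.15²
for quantitative traits. The five-hypothesis posterior uses per-variant
priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (the conventional defaults; exposed in
config) and is computed entirely in log-sum-exp space; it matches
brute-force enumeration over causal-variant configurations to 10⁻⁹. A
region is significant when PP(H3)+PP(H4) > 0.90. The cis-mQTL filter keeps
variants with p strictly below 10⁻⁵ and drops regions with none.

## Transcriptomic signatures

Bulk counts are filtered (drop genes below 10 counts in strictly more than
80% of samples), TMM-normalized (30% M-trim, 5% A-trim, reference = library
with upper-quartile fraction closest to the mean, factors centered to unit
geometric mean; verified against edgeR) and expressed as log₂ CPM with a
0.5 prior count against effective library sizes. Differential expression is
a per-gene linear model with empirical-Bayes variance moderation: the prior
(d₀, s₀²) is a method-of-moments fit of a scaled inverse-χ² to the log
residual variances (trigamma inversion by Newton), the moderated t has
d₀ + d_res degrees of freedom, and the d₀→0 / d₀→∞ limits reproduce the
ordinary and fully pooled t exactly. A gene is a cross-cohort DEG iff
p < 0.05 in every cohort, |log₂FC| > log₂ 1.5 in at least one, and the
sign agrees everywhere.

Single-cell counts are summed into per-(sample, microglial state)
pseudobulk profiles (exact integer identity). A state enters the analysis
only when every compared group averages ≥10 cells and ≥1000 summed counts
per sample (thresholds exposed; chosen as conventional pseudobulk minima).
Per state, a gene is reported iff it separates the two subtypes at p < 0.05
*and* differs from controls in at least one subtype; the pooled list is
deduplicated across states.

## Platform-preservation check

A deliberately simplified module detector replaces full weighted
correlation-network analysis, which this workflow uses only as a robustness
check: probes are clustered by average linkage on 1 − |r| with a fixed tree
cut, small clusters fall into an unassigned module, and each module is
summarized by its eigenprobe (first PC of the standardized submatrix,
sign-aligned to the module mean). A cluster-associated module (ANOVA
p < 0.05 on the eigenprobe) is *preserved* on the 450K-like probe subset
iff the subset-recomputed eigenprobe remains significant and a paired
t-test of full vs subset scores is non-significant within every cluster.

## Problem sizes

The analysis scripts and acceptance checks run the reference experiment at
3 × 150 disease samples and 5,000 probes, the null-calibration loops at 36
disease samples and 300 probes per cohort (100 repetitions), the
empirical-null recovery at 50,000 z-scores, colocalization at 50 regions
per scenario with 100 variants each, and DEG power at 1,000 genes with 50
samples per group — sizes at which every planted effect is comfortably
identified and the full suite completes in a few minutes on one core.

## Known limitations

- The hull test's conditional population is this package's resolution of
  the projection-shrinkage problem; with very few in-hull samples the test
  is valid but weak.
- The EM empirical null is deterministic but can converge to a local
  optimum under heavy, asymmetric signal contamination; the median/MAD
  fallback is then used with a warning.
- The elbow second-difference rule inherits the elbow method's bias toward
  the first large drop when cluster separations are very unequal; the NMI
  arbitration only chooses among elbow candidates.
- Module detection is not a substitute for full network analysis; its
  modules are convenience summaries for the preservation check.
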