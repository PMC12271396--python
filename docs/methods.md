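# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `admixscreen`, in the order the pipeline runs them.

## Synthetic study design

The generator produces a multi-source admixed cohort with known ground
truth; its defaults define the study conditions every test and the
acceptance script run under.

**Ancestral allele frequencies.** Three ancestral populations (labeled
AFR, AME, EUR) diverge from a shared ancestral frequency `p` (drawn
Uniform(0.05, 0.95) per site) under the Balding–Nichols model: each
population's frequency is Beta-distributed with shapes
`p(1−F)/F, (1−p)(1−F)/F`, i.e. mean `p` and variance `F·p(1−p)`. The
default divergence `F = 0.15` is in the range typical of continental-scale
human differentiation. Sites are biallelic, autosomal, ploidy 2; no LD,
phasing, indels, or multiallelic records are simulated, and no sex
chromosomes (the emulated setting releases no participant sex).

**Admixture clusters.** Samples are drawn from a five-cluster mixture on
the ancestry simplex: three near-ancestral clusters
(AFR-like (0.80, 0.08, 0.12), AME-like (0.05, 0.90, 0.05),
EUR-like (0.05, 0.05, 0.90)) and two admixed clusters, one
European-leaning (0.08, 0.295, 0.625) and one Indigenous-leaning with a
minor African component (0.15, 0.55, 0.30). Mixing weights
(149, 75, 232, 603, 350)/1409 follow the relative group sizes of the
cohort being emulated; with these centroids the expected cohort-mean
ancestry is (16.7, 32.7, 50.6)% — the published composition of that
cohort. Within-cluster spread is Dirichlet with concentration 60
(per-component SD ≈ 0.05), chosen once to reproduce the tight, visually
distinct clusters such cohorts show on a ternary plot. Genotypes are
`g_ij ~ Binomial(2, Σ_k q_ik p_kj)`.

**Platforms and missingness.** Each dataset observes a site subset
(array ≈ 55%, exome ≈ 30%, WGS = 100% of sites by convention) with
missing-completely-at-random dropout (1–5%). A configurable number of
"planted" markers (default 15) get strongly population-specific
frequencies (0.9 in one ancestral population, 0.02 elsewhere — the
Duffy-null pattern) plus pathogenic/likely-pathogenic annotations; they
are included on every platform's site list, as clinically important
markers are in practice. The annotation catalog otherwise assigns sparse
independent ClinVar-style classes (uncertain 5%, conflicting 2%,
pathogenic/LP 1%) and pharmacogenomic evidence levels.

What the generator does **not** emulate — and what passing tests therefore
do not establish for real data: LD structure, platform-specific genotyping
error and strand/allele-swap inconsistencies, batch effects confounded
with ancestry, annotation classes correlated with ancestry, and
non-random missingness. The diagnostic-yield homogeneity checks in the
test suite hold only under this unconfounded design.

## Harmonization

Variant identities are normalized to `chrom:pos:ref:alt` (any `chr`
prefix stripped, alleles upper-cased; records with `ref == alt`, empty
alleles, or `pos < 1` are rejected with a reason). Merging is an exact
union on these keys: a sample's genotype at a site its dataset never
assayed is missing, and records at the same position with different
alleles remain distinct sites. Merging is ref/alt-sensitive by design —
strand flips and allele swaps are assumed already resolved upstream, which
holds for the internally consistent synthetic data and is a documented
limitation for external inputs.

QC order: kinship filter → sample-missingness filter → site filters →
occupancy ranking → LD pruning. Sample-level QC runs before site
statistics so per-site missingness and MAF are computed on the retained
cohort.

* **Kinship.** Pairwise kinship uses the heterozygote-concordance
  estimator `φ = (N_AaAa − 2 N_AA,aa)/(N_Aa(i) + N_Aa(j))` over sites
  called in both samples, which is robust to population structure
  (duplicates ≈ 0.5, first-degree ≈ 0.25, unrelated ≈ 0). Pairs above
  2^(−5/2) ≈ 0.177 are flagged; the member with more missingness is
  dropped; 2^(−3/2) ≈ 0.354 separates duplicates from first-degree calls.
  Pairs sharing < 100 called sites are skipped with a warning.
* **Missingness/MAF.** Samples with > 99% missing genotypes are dropped
  (kept verbatim from the emulated protocol although unusually permissive;
  configurable). Sites are dropped when missing fraction > 0.75 or when
  MAF (over non-missing alleles — the denominator choice forced by
  union-merge missingness) is strictly below 0.05; all-missing sites drop.
* **Occupancy ranking.** Sites are ranked by the number of datasets
  carrying them, descending, ties broken by genomic coordinate, and the
  top N (default 3,000 here; 250,000 at full scale) are kept for ancestry
  inference. Ranking is global across datasets; a per-dataset mode exists
  because the underlying protocol is ambiguous on this point.
* **LD pruning.** Greedy left-to-right within sliding windows (default
  window 50 sites, step 25, r² ≤ 0.5): the later site of any pair whose
  squared dosage correlation exceeds the bound is dropped; missing values
  are pairwise-excluded and monomorphic sites are treated as uncorrelated.

## Ancestry inference

**Reference PCA.** Eigenvectors are computed from reference samples only:
sites are centered at `2p̂` and scaled by `sqrt(2p̂(1−p̂))` (monomorphic
sites excluded, missing genotypes mean-imputed), and the SVD of the
standardized matrix gives orthonormal site loadings, eigenvalues, and
percent variance. Study samples are projected with the model's reference
frequencies; their missing entries impute to the standardized zero.
Projection of the reference samples themselves reproduces their PCA
scores exactly, and admixed samples land inside the convex hull of the
reference clusters.

**Admixture EM.** The binomial admixture likelihood (K = 3) is maximized
by simultaneous multiplicative EM updates of Q and P; both updates use the
same E-step expectations, so the likelihood is provably non-decreasing
(asserted in tests at every iteration). Missing genotypes contribute
nothing. Defaults: tol Δℓ < 1e-4, max 2000 iterations; P is clipped to
[1e-6, 1−1e-6] and π to [1e-12, 1−1e-12] to keep logs finite. EM was
chosen over quasi-Newton block relaxation for its monotonicity guarantee
and adequacy at desk scale. Supervised mode initializes P from
reference-panel frequencies and can hold it fixed; unsupervised runs
return arbitrary component order, and `align_components` restores the
(AFR, AME, EUR) order by maximal correlation of inferred frequencies with
panel frequencies (one-to-one Hungarian assignment). Unsupervised K = 3
admixture is weakly identified at low divergence (F ≈ 0.05) from an
admixed cohort alone; including unadmixed reference samples in the run —
as real analyses do — anchors the components, and the recovery tests do
exactly that. The pipeline default uses supervised mode with fixed panel
frequencies and tol 1e-3 / 1000 iterations, which converges several-fold
faster at equal or better Q accuracy on the synthetic design.

**Cluster number and naming.** K-means (25 restarts by default, seeded)
runs for K = 1..k_max on Q. The chosen K is the knee of the log
within-cluster sum of squares: the K whose log-inertia lies furthest
below the secant joining the endpoints of the curve. The log scale is
essential — raw inertia drops scale with the remaining inertia, so both
the raw second difference and the raw-scale knee systematically elect
very small K on mixture data regardless of how well separated the true
clusters are, whereas on a K*-cluster mixture log-inertia falls roughly
linearly up to K* and flattens after it. On data with no cluster
structure any elbow-style rule returns an arbitrary K; perfectly
explained data (zero inertia at k_min) choose k_min. Clusters whose
centroid has a dominant ancestry component (≥ 0.65) are named for it
(conflicts resolved toward the more dominant centroid); the rest are
ADX1, ADX2, … in order of decreasing European fraction, so ADX1 is the
European-leaning admixed group.

## Enrichment screen

**Allele tables.** Per site and ancestry group: alt = summed dosage over
non-missing samples, ref = 2·(called samples) − alt. Groups with a fully
missing site keep a (0, 0) column (dropped before testing, with k reduced).

**Fisher exact test (2 × k).** Two-sided by probability-mass ordering: p
is the total null probability of tables with the observed margins whose
multivariate-hypergeometric probability is at most the observed table's
(relative tie tolerance 1e-7). The exact path enumerates column
compositions depth-first with exact subtree bounds — the maximum
attainable remaining log-weight comes from pooling each column's
(log-concave, hence decreasing) binomial increments and taking the R
largest; the minimum is attained at a vertex of the capped simplex and is
enumerated directly — so whole subtrees are added in closed form
(Vandermonde: Σ Π C(c_i, a_i) = C(Σc_i, R)) or pruned. The traversal is
vectorized level-by-level and capped by a node budget (`mc_cutoff`,
default 500,000; the pipeline uses 3,000 for throughput). Past the
budget, the p-value is estimated by Monte-Carlo sampling of fixed-margin
tables (`mc_reps` default 1e6; pipeline 10,000; add-one estimator, never
exactly zero, reported with its standard error). When no sampled table is
as extreme as the observed one, a deterministic Chernoff bound
`P(W ≤ w_obs) ≤ min_s exp(s·log w_obs + log Z(1−s) − log C(N, A))`, with
`Z(β) = Σ_tables Π C(c_i, a_i)^β` computed exactly by log-space
convolution over columns, replaces the Monte-Carlo value whenever it is
sharper. The bound is a valid (conservative) p-value, minimized over a
fixed grid s ∈ {0.5, 1, 2, 4, 8, 16} with early exit below 1e-16; it is
what allows tables with thousands of alleles — where full enumeration is
infeasible — to be certified below genome-wide significance. Results carry
a method tag: `exact`, `monte_carlo`, or `upper_bound`.

**Threshold.** Genome-wide alpha defaults to 5e-8; 1e-8 is available by
flag (both appear in the emulated protocol's description). No further
multiple-testing correction is applied.

**F_ST.** `1 − H̄_S/H_T` with group weights f(i) = proportion of
individuals (not alleles); a monomorphic site returns 0 with a flag, and a
group with zero allele total contributes zero heterozygosity with a
warning. The statistic is invariant to ref/alt relabeling and column
permutation, and non-decreasing as one group's frequency diverges.

**Poisson regressions.** `genotype ~ ancestry` with log link, fit by IRLS
(statsmodels GLM; convergence tol 1e-8, 100 iterations), one fit per
ancestry component, Wald test on the slope. All-zero genotypes leave the
slope unidentified and are reported `converged=False` rather than as a
number. Fits require ≥ 10 non-missing samples.

**Outputs.** Hits sorted by ascending p, with the enriched cluster
(highest alternate-allele frequency; ties to the larger column total,
then name order), annotations, and separate pharmacogenomic / clinical
partitions; evidence-level filtering (default {1A, 1B, 2A, 2B}) is a
separate operation.

## Diagnostic yield and summaries

`D_i^p` uses the *carried-variant* denominator — the number of variants
with at least one alternate allele among the group's non-missing
genotypes — which makes yield comparable across groups of unequal size; an
all-cohort-variant denominator is available by flag. Percentages are
reported to 4 significant digits with raw counts alongside. Per-dataset
frequency summaries report allele count = 2·(called samples) and
ref/alt frequencies; a variant absent from (or fully missing in) a
dataset produces no row. In real multi-platform data, differences in
platform site sets can bias yield comparisons across ancestry groups; the
synthetic design is unconfounded, so the pipeline does not attempt to
correct for this.

## Reproducibility and problem sizes

All randomness flows from one master seed through `numpy` SeedSequence
spawning; repeated runs are bit-identical (asserted on every output file).
Default problem sizes — 600 samples, 6,000 sites, 4 datasets, 180
reference samples, 3,000 ancestry sites — were chosen so a full pipeline
run completes in about two minutes on one CPU while leaving every stage
statistically testable; the recovery and calibration tests use 2,000–10,000
sites and 100–1,409 samples as each check requires. The acceptance script
reports only quantities computed during its own run.
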