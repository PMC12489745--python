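# Methods

This note documents the models and estimators implemented in `popgea`,
the numerical conventions, what the simulator does and does not emulate,
and the design choices made where the field offers more than one
convention.

## Data model

The central container is a dosage matrix: n individuals × L biallelic
SNPs, entries in {0, 1, 2} counting alternate alleles, with a missing
sentinel. Positions are 1-based (VCF convention) throughout. All
statistics use locus-wise or pairwise-complete observations; the only
operations that impute are PCA and the GEA response matrix (site-mean
imputation), because ordination requires a complete matrix. Per-site
mean depth is taken from the mean of FORMAT/DP when present, otherwise
INFO/DP divided by the sample count.

## QC filtering

Individuals are filtered first (mean depth < 3× or missingness > 20%
by default), then sites (mean depth outside [5, 12], quality < 50,
missingness > 10%, non-biallelic, MAF below the analysis-specific
threshold), with the MAF recomputed after individual removal. The
individual depth cutoff is a coverage in ×, not a percentage; the CLI
help repeats this because the two are easy to confuse when filters are
quoted secondhand. Filtering is idempotent, and a per-rule removal count
is reported (a site can fail several rules, so rule counts can exceed
the net removal).

Different analyses intentionally use different MAF levels: kinship runs
on MAF 0.00 (rare alleles carry most of the identity information, and
MAF filtering is known to bias allele-sharing estimators), while
structure, summary statistics and GEA run on MAF-filtered data.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors over
individuals called at both sites — the genotype (composite) measure,
appropriate for unphased data. Decay profiles bin pairs by physical
distance (default window: 100 SNPs / 1,000 kb); under free
recombination E[r²] ≈ 1/n, which the tests use as the null level.

Pruning removes, for every pair exceeding the threshold within a shared
50 kb window (10 kb stride), the member with higher missingness (ties:
larger position). This differs from the sequential greedy familiar from
other tools in one deliberate way: the removal decision depends only on
the pair, not on the order of prior removals. That choice makes the
result provably monotone in the threshold (the removed set at r² > 0.2
is a subset of the set at r² > 0.1) and guarantees the survivors contain
no offending pair — two properties the sequential greedy does not have —
at the cost of removing slightly more sites when high-LD clusters chain
together. Both 0.1 and 0.2 thresholds are supported as the stringent and
relaxed defaults.

## Population structure

**PCA** mean-imputes missing dosages, centers columns and does not
variance-scale them, so common variants contribute proportionally to
their variance. Reconstruction from all axes reproduces the centered
matrix to machine precision (asserted in tests).

**Cluster number** is scanned with k-means on the PC scores and scored
by BIC = n·ln(WSS/n) + k·ln(n). The automatic choice codifies the usual
interactive rule — the first BIC minimum before a subsequent increase —
and can be overridden. This BIC form rewards splitting tight
low-dimensional blobs indefinitely; it behaves as intended on PC score
matrices, where cluster structure lives in a few leading axes on top of
many noise axes, and the tests exercise it in that regime.

**DAPC** fits linear discriminants on retained PCs. The number of PCs is
chosen by the a-score: observed correct-reassignment rate minus the mean
rate over label permutations (default 50), averaged over groups — a
direct penalty for discrimination that is an artifact of dimensionality.
At most n_groups − 1 discriminant functions exist.

**Admixture** maximizes the binomial likelihood
Σ<sub>ij</sub> [g ln h + (2−g) ln(1−h)], h<sub>ij</sub> = Σ<sub>k</sub>
q<sub>ik</sub> f<sub>kj</sub>, by EM block updates on Q and F (expected
allele-copy assignments to ancestral populations). EM is slower than
quasi-Newton acceleration but monotone by construction — the
log-likelihood trace is asserted non-decreasing in tests — and adequate
at the scales this package targets. F is clamped to [1e−6, 1−1e−6].
Cross-validation masks a random 1/folds of the *called genotype entries*
per fold (not whole individuals), refits, and scores (g − 2ĥ)²; the K
minimizing the CV error is preferred. Intended input is MAF-filtered,
LD-pruned genotypes from unrelated individuals; that mapping is the
pipeline's responsibility, not the function's.

## Selection scan

Genotypes are standardized, each SNP is regressed on the first K PC
score vectors, and the K-vector of regression z-scores is summarized by
Mahalanobis D² under a robust covariance across SNPs (minimum covariance
determinant when L ≥ 10K, sample covariance otherwise — the robust
estimator needs enough rows to be stable). D² is rescaled by the genomic
inflation factor λ = median(D²)/median(χ²<sub>K</sub>); upper-tail
χ²<sub>K</sub> probabilities give p-values and Storey q-values give the
outlier set at q ≤ α (default 0.1).

K is a required argument. The scree of the genotype PCA (an assistive
elbow report is provided) is the usual guide, but the elbow judgement is
visual in practice and is not automated into the scan itself.

Storey's π₀ is estimated by a cubic smoother over the λ-grid
0.05…0.90 evaluated at the largest λ, falling back to π₀ = 1
(Benjamini–Hochberg behavior) if the fit leaves (0, 1].

## Diversity and differentiation

Three estimator families are implemented, because they answer different
questions and aggregate differently:

* **Nei/Nei–Chesser**: per locus, H<sub>O</sub> is the mean observed
  heterozygosity across populations; H<sub>S</sub> applies the
  small-sample correction ñ/(ñ−1)·(mean 2p<sub>i</sub>q<sub>i</sub> −
  H<sub>O</sub>/2ñ) with ñ the harmonic mean sample size; H<sub>T</sub>
  uses unweighted mean frequencies plus the corresponding corrections.
  Global values are locus means, and F<sub>ST</sub> = 1 −
  H̄<sub>S</sub>/H̄<sub>T</sub> (ratio of averages, not average of
  ratios). Note this G<sub>ST</sub>-type quantity is depressed relative
  to θ by a factor ≈ (r−1)/r with r populations; the two agree on
  simulations only as r grows, which the tests encode.
* **Weir–Cockerham (1984)**: per-locus variance components a (among
  populations), b (among individuals within), c (within individuals);
  θ = Σa/Σ(a+b+c) and f = 1 − Σc/Σ(b+c) as ratios of sums over loci.
  This is the estimator whose parameter-recovery against the simulator's
  drift value anchors the acceptance checks.
* **Weir–Goudet β**: population-specific differentiation from allele
  matching — M<sub>i</sub> the within-population matching between
  distinct individuals, M<sub>B</sub> the mean between-population
  matching, β<sub>i</sub> = (M<sub>i</sub> − M<sub>B</sub>)/(1 −
  M<sub>B</sub>). β makes no HWE or independence assumption and is the
  right tool when populations differ in drift. Bootstrap CIs resample
  loci with replacement (default 1,000 draws, percentile 2.5/97.5%).

Pairwise F<sub>ST</sub> applies the WC estimator to each population pair
with the same locus bootstrap. Nei's D defaults to the 1972 standard
distance D = −ln(ΣJ<sub>xy</sub>/√(ΣJ<sub>x</sub>ΣJ<sub>y</sub>)); the
1978 unbiased variant is available (`variant="1978"`), since citations
of "Nei's D" are frequently ambiguous between the two. Individual-level
distances treat each individual as a population of one with frequencies
from its two allele copies.

Neighbour joining uses the Studier–Keppler Q-criterion; negative branch
lengths are clamped to zero with the deficit transferred to the sister
edge, so additive metrics are recovered exactly and path lengths are
preserved where possible. The implementation is cross-checked against an
independent NJ implementation on additive metrics in the tests.

## Kinship

β-kinship from dosages: pair matching (x<sub>i</sub>x<sub>j</sub> +
(2−x<sub>i</sub>)(2−x<sub>j</sub>))/4 and self matching 1 − x(2−x)/2,
averaged over pairwise-complete loci, referenced to the mean
off-diagonal matching M<sub>B</sub>. The diagonal reports the inbreeding
coefficient 2β*<sub>ii</sub> − 1. Because the reference is the average
pair of the sample, β is relative: in a structured sample,
within-population dyads sit above zero before any pedigree relationship
is added. Kinship should be computed on data not filtered by MAF.
Individuals with fewer than 100 called loci are flagged. A min-scaling
transform is provided for heatmap display only; it is affine and
rank-preserving, and statistics always use raw values.

The robust screening estimator is φ = (N<sub>het,het</sub> −
2N<sub>opposing hom</sub>)/(N<sub>het</sub>(i) + N<sub>het</sub>(j)) over
shared loci; it is unbiased under population structure for the
relationship classes it is used for (duplicates ≈ 0.5, first-degree
≈ 0.25) and intentionally unclamped (negative values mean "less related
than random").

Relative pruning removes, iteratively, the individual in the most dyads
at or above the threshold (default 0.125), ties broken by lower call
rate then lexicographically larger id. On family-structured kinship
graphs — cliques of relatives with occasional cross-family links, the
structure pedigrees actually produce — this greedy matches the exhaustive
minimum vertex cover within one removal (verified against brute-force
enumeration on 12-individual instances). On adversarial random graphs it
can exceed the minimum by more; no pedigree generates those.

## Genotype–environment association

The response is the individual allele-frequency matrix, dosage/2 with
site-mean imputation. (Deriving individual frequencies from allele
depths is supported conceptually by the data model but is noisy at low
coverage; dosage/2 is the default and the only mode exercised by tests.)

Predictors are pruned in two stages: drop one of each pair with |r| >
0.7 (the first-listed variable is kept — the order of the input table is
the user's priority ranking; both are logged), then iteratively remove
the highest-VIF variable until all VIF ≤ 3. The VIF-stage removals are
returned as a conditioning set: they are not independent signals but
still belong in the model as covariates. Only the VIF-stage removals are
conditioned on, not the correlation-stage ones — conditioning on a
variable nearly collinear with a kept one would cancel the kept
variable's signal.

**Partial RDA**: response and predictors are residualized on the
conditioning block (structure PCs from the outlier-filtered data plus
the conditioned-out variables), the residual regression's fitted values
are eigendecomposed into canonical axes, and SNP loadings are the axis
eigenvectors. Adjusted R² uses the Ezekiel correction
1 − (1−R²)(n−1)/(n−p−1). The variance partition follows the standard
adjusted-R² differencing: full = adjR²([X,Z]), climate|structure =
full − adjR²(Z), structure|climate = full − adjR²(X). Per-axis p-values
permute the rows of the residualized response and compare each canonical
eigenvalue with its permutation distribution. Candidates are SNPs whose
loading on any retained axis (default 3) is more than 2.5 or 3 SD from
the axis mean; each is assigned the environmental variable with the
largest absolute correlation to its frequency column.

**LFMM (ridge)**: one model per environmental variable, minimizing
‖Y − xbᵀ − UVᵀ‖² + λ‖b‖² by alternating a rank-K factor step (top-K left
singular subspace of the residual, computed from the n×n Gram matrix)
and a ridge step, up to 100 iterations (λ default 1e−5, K default 5 —
the number of genetic clusters). Per-SNP z-scores come from OLS of Y on
the variable with the K factors as covariates; the GIF
median(z²)/median(χ²₁) recalibrates p per variable before Storey
q-values. Multiple testing is controlled per variable, matching the
one-model-per-factor design, not pooled.

**Intersection**: the final candidate set requires RDA, LFMM and scan
evidence simultaneously. Its empirical FDR is bounded by each single
method's (asserted on simulations), at the cost of recall — the correct
trade-off when candidates inform conservation decisions. Stricter
threshold pairs (SD 3 / FDR 0.05) produce subsets of looser ones
(SD 2.5 / FDR 0.10) by construction.

## Simulator

The generator is the package's study-conditions definition, not a
convenience: population frequencies follow Balding–Nichols drift
Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral frequencies uniform on the
configured MAF range; selfing at rate s produces the equilibrium
heterozygote deficit F<sub>IS</sub> = s/(2−s); admixed individuals draw
Dirichlet ancestries and genotype from mixed frequencies; pedigree dyads
(parent–offspring, full sib, half sib) are created by explicit gene
dropping from founders; adaptive loci shift logit(p) per individual by
effect × standardized environmental value; environmental variables are a
north–south gradient attached per individual (so GEA has within-
population contrast) plus correlated noise; missingness and site
depth/quality metadata are applied last. All draws derive from one seed;
identical configurations produce byte-identical VCFs.

What it does not emulate: linkage between the main loci (neutral loci
are unlinked; a separate AR(1)-haplotype generator provides a linked
chromosome for the LD machinery), realistic demographic history
(bottlenecks, expansions, isolation by distance beyond the single
gradient), sequencing-read-level noise, or genotype-calling error
correlated with depth. Passing tests therefore demonstrate estimator
correctness under the stated generative models, not robustness to every
artifact of low-coverage sequencing.

The `paperlike` preset (five populations, 269 individuals including an
admixed block and pedigree dyads, F = 0.15, partial selfing,
environment-tracking loci) is a shape for integration tests, not a claim
of equivalence to any real collection.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately moderate scales —
typically 100–270 individuals and 2,000–20,000 loci, chosen as the
smallest sizes at which each estimator's sampling error is well inside
the tolerance being asserted (e.g. θ at F = 0.15 is recovered to ±0.02
with 5×40 individuals and 5,000 loci; kinship dyad means to ±0.03 need
~20,000 loci). Statistical power scenarios are stated with the test:
the selection-scan recall target uses a weakly drifted background
(F = 0.01), because a fixed allele-frequency differential is only an
outlier relative to background drift smaller than itself; the GEA
intersection uses F = 0.03 with logit effect 2.0 along a strongly
structured gradient — the strong-local-adaptation regime a
triple-evidence design is built for.

Other conventions: dosage missingness uses a sentinel, never NaN, in the
integer matrix; zero-variance SNPs propagate missing statistics rather
than zeros; bootstrap and permutation routines take explicit seeds and
are bit-reproducible; EM admixture returns the best fit with a flag
rather than raising when the iteration cap is hit; ridge and EM
tolerances are documented at the call sites.

## Known limitations

* The admixture EM converges slowly near the optimum; for datasets
  beyond ~10⁵ loci an accelerated implementation would be preferable.
* The pRDA axis test permutes residualized response rows axis-by-axis
  rather than implementing the full sequential (conditional) test; on
  planted-signal simulations the two agree on which axes carry signal.
* Individual-frequency responses from allele depths (rather than
  dosages) are not implemented; at low coverage they would propagate
  depth noise into the GEA response.
* The scan's K is user-chosen; the scree report assists but does not
  decide.
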