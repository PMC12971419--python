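# Methods

## Scope and model

`deprofiler` analyzes bulk RNA-seq count data from a 2x2 factorial design —
genotype (wt / ko) crossed with a transgene (nontg / tg) — of the kind used
to ask whether a genetic manipulation reshapes the transcriptional response
to a disease model. Counts for gene *g* in sample *s* are modeled as
negative binomial,

    y_gs ~ NB(mu_gs, phi_g),   Var = mu + phi mu^2,

with log mu_gs = log(effective library size_s) + x_s' beta_g. The design
columns are intercept, genotype (ko = 1), transgene (tg = 1) and their
interaction; a nonzero interaction coefficient means the transgene response
differs by genotype.

## Normalization

Between-sample normalization is trimmed-mean-of-M-values (TMM). For each
sample against a reference (the sample whose upper-quartile expression is
closest to the mean upper-quartile), M values (log2 ratios of
depth-corrected counts, genes positive in both samples) are trimmed 30%
two-sided and A values (average log abundance) 5% two-sided; surviving M
values are averaged with inverse-variance weights from the binomial
delta-method approximation, and factors are rescaled to geometric mean 1.
Log-normalized expression for PCA is log2 CPM on effective library sizes
with a prior count interpreted per million reads and scaled to each
sample's depth (prior_s = prior x L_s/1e6, default prior 0.5/million); this
scaling makes the transform exactly invariant to joint rescaling of counts
and library sizes.

## Dispersion estimation

The common dispersion maximizes the Cox-Reid adjusted profile likelihood
(per-gene NB log-likelihood at the IRLS-fitted means minus half the
log-determinant of the weighted information X'WX) summed over genes,
located by a coarse log-spaced grid bracket followed by golden-section
refinement on log phi in [1e-6, 5]. Tagwise dispersions maximize a weighted
objective per gene — the gene's own APL plus (prior_df / residual_df) times
the mean APL curve across genes (interpolated on the grid) — by a
vectorized per-gene golden section; prior_df defaults to 10. A prior_df of
1e4 or more is treated as the infinite-shrinkage limit and returns the
common value for every gene.

A known limitation: shrinkage targets the *common* value, not a
mean-dispersion trend. When the true dispersion varies strongly with
abundance (as in the generator's phi_g = phi0 + a/mu model with large a),
low-count genes are under-dispersed by the estimator and their tests run
mildly liberal (interaction LRT rejection ~0.07 at alpha = 0.05 in our
measurements). The shipped calibration scenario therefore uses homogeneous
dispersion, where rejection rates sit at 0.045-0.065.

## Pairwise exact tests

Group comparisons use the conditional NB exact test. Counts of the two
groups are rescaled to their geometric-mean effective library size
("pseudo-counts", rounded half-to-even), group sums y_A, y_B are formed,
and the test conditions on t = y_A + y_B: the sum of n iid NB(mu, phi)
variables is NB with mean n mu and size n/phi, so the conditional
probability of each split (y, t - y) is the normalized product of the two
group-sum pmfs. The two-sided p-value sums the probabilities of all splits
as or less likely than the observed one (a relative slack of 1e-9 guards
floating-point ties). For totals above 5x10^5 the enumeration is restricted
to +-50 conditional standard deviations around the mean — the excluded
mass is below double precision, so this is still the same enumeration.
Reported log2 fold-changes use normalized group means with a prior count
of 0.125 per sample.

## Two-factor GLM and interaction test

The full NB GLM is fitted per gene by Fisher-scoring IRLS, vectorized
across genes (4x4 weighted normal equations solved in batch), converging
when the relative deviance change drops below 1e-8 (at most 100
iterations, with step-halving on deviance increases). Each tested term is
assessed by a likelihood-ratio test against the model with that single
column removed, with chi-square(1) reference; non-converged genes are
flagged and their p-values set to NA. Interaction p-values are BH-adjusted
across genes. Benjamini-Hochberg adjustment is the exact step-up rule
(sorted p_(i) m/i with a reverse cumulative minimum, capped at 1), with
NAs passed through.

## Differential profiles and cluster-number selection

Genes with interaction FDR strictly below 0.2 form the clustering set.
Each selected gene's profile is, per pairwise contrast, log2FC x
(-log10 p) (p floored at 1e-300), and each profile column is divided by
its standard deviation. The log base is immaterial under per-column SD
normalization — a base change multiplies a column by a constant — which
the tests verify numerically; log10 is fixed for the reported raw
products.

k-means is scanned over k = 2..20. For each k, ten clustering results are
produced; each result is the minimum-WSS partition over ten Lloyd runs
from k-means++ (D^2-weighted) seeds, all seeded deterministically from
(base_seed, k, init_index, restart). The best-of-restarts convention
matches how practitioners actually run k-means (both sklearn and R return
the best of several starts), and it is what gives the reproducibility
statistic its discriminating shape: a single uniformly-seeded Lloyd pass
routinely leaves two centroids trapped in one blob, so no granularity above
k = 2 would ever look stable, whereas best-of-restart results agree exactly
whenever the global optimum is found reliably.

The distance between two results is d = 1 - f, where f is the mean of the
two fractions of shared co-clustered gene pairs (|P_A & P_B|/|P_A| and
|P_A & P_B|/|P_B|, computed from the contingency table); identical
partitions give d = 0, disjoint pair sets give d = 1, and d is invariant
to cluster relabeling. For each k the distance is averaged over all 45
result pairs, and the selected k* is the largest k with average distance
strictly below 1e-5 — the finest granularity at which the partition is
independent of the random initialization. If no k qualifies, the argmin of
the average distance is taken (smallest k on ties) and the selection is
flagged as a fallback. Final labels come from the minimum-WSS result at
k*.

## Enrichment and signatures

Over-representation of a DEG list (FDR < 0.05 and |log2FC| > 0.1) in a GMT
term is tested with the hypergeometric upper tail after intersecting the
term with the universe (all genes that entered differential testing);
terms with zero overlap are excluded from testing and from the BH family.
Ranking is by FDR. The combined score is c = -ln(p) x z with z the
analytic standardization of the overlap under the hypergeometric null —
a deterministic replacement for Enrichr's simulation-derived rank z-score
with the same monotone intent. Signature panels (homeostatic microglia,
stage-1/2 DAM, the core IRM interferon signature, nucleic-acid sensors)
are scored per contrast as per-gene log2FC with significance tiers
(* FDR < 0.05, ## FDR < 0.001) and per-panel mean log2FC / fraction
significant; panel genes absent from the data are reported, never dropped
silently.

## qPCR quantification

Relative expression uses 2^-ddCt with amplification efficiency fixed at 2:
dCt = Ct_target - Ct_reference within each sample, ddCt subtracts the mean
control-condition dCt per target, and condition summaries report the
geometric-mean fold (2^-mean ddCt) with SD kept in ddCt space. Technical
replicates are averaged in Ct space first (configurable). Group
comparisons are Welch t-tests on ddCt values, not on folds, because folds
are log-normal under Gaussian Ct noise. Knockdown is reported as
100 x (1 - fold), negative values indicating an increase.

## Synthetic data

The generator draws per-gene baselines log2 mu ~ Normal(mean, sd),
per-sample library factors exp(Normal(0, 0.2)), and counts NB with
dispersion phi_g = phi0 + a/mu_g. Planted programs add per-group log2
offsets; a program may ramp per-gene amplitudes linearly across its genes
(co-regulated genes never respond with identical strength). An optional
background-effect SD gives every gene small idiosyncratic per-group
offsets (off in all presets so calibration runs on exact nulls). All
randomness derives from one scenario seed through fixed stream indices.

The `ad_like` preset (2000 genes, n = 5/group, phi0 = 0.1 — a biological
CV of ~0.32, typical for mouse tissue — baseline (5.0, 1.2)) plants four
disjoint 60-gene programs whose differential-profile directions sit at the
vertices of a regular tetrahedron in the rank-3 subspace spanned by the
four pairwise contrasts — the best separation four directions admit there.
All four programs carry a genotype x transgene interaction (the clustering
stage selects genes by interaction FDR, so only interaction-bearing
programs can be clustered): an ISG-like program induced mainly in
(ko, tg), a DAM-like program up with the transgene in wt, a genotype
program up in (ko, nontg), and a weaker transgene-down program whose
amplitude ramps from 0.4 to 1.0 of full strength. The weak ramp is
deliberate: BH selection at FDR < 0.2 necessarily admits ~20-25% false
positives, which occupy the low-significance center of profile space, and
a program that grades continuously into that region makes the center part
of one cluster rather than a spurious extra concentration. The three
strong programs are kept symmetric and radially compact so that candidate
splits at k = 5 remain near-degenerate — and therefore irreproducible —
across initializations. `two_blob` (120 genes, two symmetric strong
programs, no null background) and `null` (2000 genes, no programs,
homogeneous dispersion) complete the presets.

What the presets do not emulate: real mouse hippocampus expression
distributions, gene-gene correlation, outlier samples, batch effects, or
a mean-dispersion trend in the calibration null. Passing tests demonstrate
that the estimators and the selection algorithm recover planted structure
under the stated NB model, not that they are robust to everything real
data does.

## Problem sizes and numerical choices

The shipped validation runs the full chain at 2000 genes x 20 samples; the
cluster-count recovery check aggregates 20 generation seeds, and the
acceptance script reports the modal selected k over 20 consecutive seeds.
Dispersion search spans phi in [1e-6, 5] (21-point log grid plus 30-40
golden-section steps). IRLS tolerance is 1e-8 on relative deviance;
k-means caps at 300 Lloyd iterations; p-values are floored at 1e-300
before logs; degenerate cases (constant profile columns, zero-variance
panels, empty pair sets) are handled explicitly as described above.
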