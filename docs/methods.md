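# Methods

`celldiv` quantifies how genes distinguish replicated cell-population
expression profiles. This note records the models, the defaults and why
they were chosen, the numerical details, and what the synthetic-data
generator does and does not emulate.

## Differentiation Matrices, DEF and FCR

For P populations, each gene gets a symmetric binary P×P *Differentiation
Matrix* (DM): entry (i, j) is 1 when the gene's expression distinguishes
populations i and j. Two construction rules exist:

* **Replicated data** — DM[i,j] = 1 iff |log2 fold-change| > 2 (strict) and
  Benjamini–Hochberg q < 0.05 from the moderated pairwise test below.
* **Cluster averages only** — DM[i,j] = 1 iff |difference of log2(x+1)
  means| > 1. Used for references without replicate structure.

From the DM, **DEF** (differentially expressed fraction) is the fraction of
the P(P−1)/2 unordered pairs distinguished. When a gene's DM is induced by
a partition of populations into expression classes of sizes n_k, DEF equals
the Gini–Simpson diversity index (P² − Σn_k²)/(P² − P); this identity is
property-tested exhaustively. **FCR** (fold-change ratio) is the mean
|log2FC| over distinguished pairs divided by that over undistinguished
pairs — a signal-to-noise measure. FCR is NaN when DEF = 0 (no signal to
rate) and +∞ when no undistinguished pair remains or the denominator is 0;
rankings place +∞ genes first (ordered by DEF) and never rank NaN.

**Combinatorial codes.** The combined DEF of a gene set is the DEF of the
OR of their DMs. The greedy search picks the highest-DEF gene first, then
whichever gene adds the most newly distinguished pairs, stopping at a
coverage threshold (default 0.99). Ties break by higher individual DEF,
then lexicographic gene id, so results are deterministic and independent of
candidate order. Greedy set cover is within the usual (1 − 1/e)
approximation of the NP-hard optimum; on random instances ≤ 12 genes it
matches the exhaustive minimum in well over 80% of cases (tested).

## Moderated pairwise testing

Per gene, a one-factor linear model (population as the only factor) is fit
on log2(x+1) values; the residual variance s² is pooled across populations
with d = n − P degrees of freedom. Gene-wise variances are shrunk toward a
prior by empirical Bayes: assuming s² ~ s0²·F(d, d0), the prior (d0, s0²)
is estimated by method of moments on log s² (digamma/trigamma closed forms,
trigamma inverted by Newton iteration); the posterior variance is
s̃² = (d0·s0² + d·s²)/(d0 + d). The moderated t for pair (i, j) is
(μ_i − μ_j)/(s̃·√(1/n_i + 1/n_j)) with d + d0 df. This is the classical
variance-moderation core; one test cross-checks it against limma's
`lmFit`/`eBayes` on the same matrix and they agree to 6 decimals.
Zero-variance genes are excluded from the hyperparameter fit (their log
variance is −∞) but still receive a shrunken posterior variance.
Precision weights (voom-style trends) are not estimated — with two
replicates per group a trend fit is unstable — but a per-observation
weights hook exists.

BH adjustment is applied across genes within each population pair
(`bh_scope="pair"`, the default) with a `"global"` switch; per-contrast
adjustment is the standard behavior of the framework this mirrors. To
equalize power across populations with unequal replication, callers pass
`max_replicates=2`, which keeps the two samples of highest acquisition
order per population ("most recent two"); the acquisition order is an
explicit integer column, never inferred from sample ids.

## OFF noise, enrichment, orthogonality, pan-neuronal filter

**OFF noise** is the n−1 standard deviation of a gene's FPKM over samples
with FPKM < 1, computed on the linear scale (all OFF values are below 1, so
linear and log2(x+1) nearly coincide; configurable). It is undefined when
fewer than max(2, 10% of samples) are OFF — a one-sample OFF set has no
spread to estimate. Noise classes use OFF noise < 0.2 (low) and > 0.3
(high) with a minimum maximal expression of 20 FPKM (the boxes' horizontal
extent is not published; the default is configurable and the class counts
are not reproduction targets).

**Over-representation** of a family in a gene list is the hypergeometric
upper tail P[X ≥ overlap] over the chosen universe, flagged at p < 1e-5.

**Orthogonality** of a family is the mean pairwise (1 − Pearson r) of its
members' log2(x+1) population-mean patterns; constant patterns are excluded
(undefined correlation). It lies in [0, 2] and is invariant to per-gene
affine rescaling. Because its dispersion shrinks with family size, each
family is compared against `n_draws` random same-size subsets of a
universe (default: genes with max population mean ≥ 1 FPKM — restricting
the null to expressed genes is the package's choice of sampling universe),
reporting a Z-score and the empirical 0.5%/99.5% interval; families with
fewer than 50 in-universe members are rejected.

**Pan-neuronal genes** satisfy all seven strict conditions on NE/NNE (the
replicate-averaged FPKM means over neuronal/nonneuronal populations):
mean NE > 20; min NE > 5; mean NE > max NNE; min NE > mean NNE;
mean NE > 4·mean NNE; mean NE > mean NNE + 2·std NNE; and
mean NE − 2·std NE > mean NNE. Standard deviations are across populations
(not raw samples), matching the population-centric definition. A test
fixture isolates each condition; isolating conditions 4 and 7 requires ≥ 8
populations because a sample minimum cannot sit more than (n−1)/√n
standard deviations below the mean.

## NNLS decomposition

Queries are decomposed over reference cluster profiles (log2(CPM+1) means)
by `min ‖Ax − b‖₂, x ≥ 0`. **Gene selection**: candidates are visited by
descending one-way ANOVA F (of the primary dataset) and accepted only if
the Jaccard index of their cluster-average DM with every accepted gene's
DM stays below 0.5 in every supplied dataset, stopping at 500 genes — this
keeps the panel from being dominated by genes that separate the same one
or two extreme classes. Two all-zero DMs get Jaccard 0 (no pattern to
compare); genes with NaN F are dropped, +∞ F (zero within-class variance)
ranks first. **Quantile normalization** maps the query's rank r value to
the r-th smallest target value, averaging target values over query ties,
so the output's sorted values equal the target exactly and the map is
idempotent. The target is the element-wise mean of the sorted per-cluster
profiles (a "sort after averaging" variant is available). **Purity** is
max coefficient / coefficient sum (undefined when all coefficients are 0);
coefficients are reported raw, not normalized to 1, so scaling the query
by c scales coefficients by c and leaves purity unchanged.

**Split-half cross-validation** halves each population's replicates by
acquisition order, builds the panel from one half and decomposes the other
half's population means; singleton populations are excluded with a
warning. Quantile normalization is off by default here: it exists to align
distribution differences *between* datasets, and the two halves of one
dataset already share units, so it would only perturb an exact match. When
a half has one replicate per population (R = 2 data), gene ranking falls
back from ANOVA F to the variance of population means.

## Dirichlet-multinomial differential splicing

Junctions sharing (chrom, strand, donor position) form a donor unit with
m ≥ 2 acceptors (single-acceptor donors are not alternative). Coordinates
are 0-based half-open; strand determines which end is the donor, and
strands never merge. Per sample, branch probabilities are count shares,
defined only when the donor's total reads strictly exceed 10; failing
samples are dropped from tests, not zero-filled, and a pair is testable
only when both groups keep ≥ 1 sample.

Counts follow DirMult(n, φ·π) with usage π on the simplex and one
concentration φ shared by both groups and both hypotheses; the null shares
π, the alternative gives each group its own, so the LRT has m − 1 df. Two
departures from a naive ML likelihood-ratio test, both forced by ~2–3
replicates per group:

1. **φ is not profiled by maximum likelihood.** Under the null the DirMult
   likelihood can drive φ → 0 and absorb any between-group difference as
   within-group overdispersion — an all-or-none usage flip then looks
   unremarkable — and the ML φ from ~6 samples is strongly biased. Instead
   the intra-class correlation ρ = 1/(1+φ) is estimated once by a
   Williams-type moment estimator from within-group Pearson χ² and held
   fixed in both models. When ρ̂ ≤ 0 the test reduces to the exact
   multinomial likelihood-ratio test (so a perfectly consistent all-or-none
   flip gets the astronomically small p the data deserve).
2. **F reference.** ρ is estimated with only S − 2 df (S = testable
   samples), and a χ² reference ignores that uncertainty — at 3v3 this
   alone inflates type-I error to ~0.11, for the same reason a 4-df t
   statistic referred to the normal rejects at 0.107. The LRT is therefore
   referred to F(m−1, S−2) via LRT/(m−1). Measured calibration at 3v3
   (m=2, φ=10, coverage ≈ 50): type-I 0.046 at α=0.05 over 2000 null
   simulations; power 0.99 for (0.8,0.2) vs (0.2,0.8) at φ=20. The
   classical `reference="chi2"` remains available and is used automatically
   when S − 2 < 1.

π is maximized at fixed φ over a logit parameterization with analytic
digamma gradients (L-BFGS-B, initialized at pooled proportions, declared
non-converged after 500 iterations → untestable with a diagnostic).
PSI per group comes from pooled counts over passing replicates (pooling
weights by coverage; a mean-of-ratios would not). The splice DM marks a
pair when p < 0.05 and max |ΔPSI| > 0.1; untestable pairs are 0. Raw p is
used as stated by the rule; a BH switch across donors exists. A gene's
splice DEF is the DEF of the OR over its donors' DMs.

## Gene-length analyses

Genes are binned by floor(bins_per_log · log10(length bp)), four bins per
decade by default (bin 20 starts at 100 kb). Binned summaries exclude
non-finite metric values. The long-gene fraction of a population is the
count share of expressed genes (mean expression > 1 FPKM by default) that
are ≥ 100 kb; an expression-weighted variant is provided since the
original axis definition is not printed anywhere.

The **length-bias rank test** asks, per bin, whether between-group
fold-changes exceed within-group replicate fold-changes (one-sided
Mann–Whitney, BH across bins, bins with < 10 genes excluded). Fold-changes
are computed between individual replicates, and the genes of each bin are
randomly split (seeded) between the between-group and within-group roles so
the two rank-sum samples are independent: under the null both are
|difference of two iid values| and the p-values are exactly calibrated
(verified by KS against uniform over 200 null runs). The alternative of
comparing |difference of group means| against replicate differences is kept
as `scheme="means"` but is conservative under the null — a mean of R
replicates fluctuates √R less than a single replicate. The exact statistic
of the original replication-control analysis was published separately;
this rank formulation is the package's documented approximation.

## Synthetic data

The generator emulates sorted-population RNA-seq at desk scale: P = 20
populations × R = 3 replicates (three replicates is typical of
sorted-population designs; DM calculation then uses the most recent two to
equalize power), 20% of populations nonneuronal, and four gene classes:

| class | n | length | expression structure | dispersion |
|---|---|---|---|---|
| marker | 150 | 10^(3.8±0.3) bp | ON in ~20% of populations at ~30 FPKM, OFF leak 0.01 FPKM | 0.02 |
| effector | 400 | 10^(5.2±0.3) bp | log-normal population means, σ = 2.5 log2 units, mean 10 FPKM | 0.15 |
| housekeeping | 1200 | 10^(4.0±0.4) bp | flat ~15 FPKM | 0.05 |
| pan-neuronal | 60 | 10^(4.2±0.3) bp | ~80 FPKM in neuronal populations, 0.5 FPKM leak elsewhere | 0.05 |

Markers' restricted ON fraction and tiny OFF leak give the low-OFF-noise,
high-FCR regime of binary identity factors; the effector spread of 2.5
log2 units lets single genes distinguish up to ~60% of pairs, the regime
where the observed DEF ceiling sits, and their length distribution puts
most of them above 100 kb. Counts are negative binomial with variance
μ + μ²·dispersion (Poisson at dispersion 0), expected counts
FPKM · length_kb · library/10⁶ with log-normal library sizes (mean 2×10⁶,
CV 0.2). Class FPKM targets are renormalized per population so that
Σ FPKM·length_kb = 10⁶ exactly — the identity real FPKM satisfies — and the
graded log-normal is mean-corrected, so converting simulated counts back to
FPKM recovers the recorded truth up to counting noise and absolute
thresholds (20 FPKM etc.) stay meaningful. Budgets are chosen so the
renormalization factor is near 1.

Junction tables draw per-sample totals Poisson(coverage 50) and acceptor
counts DirMult(φ = 20); half the donors are "all-or-none" (usage 0.95 on a
per-population random vertex — the source of bimodal branch probabilities)
and half share one usage vector across populations (true nulls for
calibration). All randomness flows from one seed through named substreams
(SeedSequence spawn keys), so any component regenerates independently.

**What passing tests do and do not show.** The generator produces
independent genes with clean class structure, no correlation between genes
beyond the shared per-population normalization factor, no batch or
dissection covariates, no ambient contamination, no length-coupled
counting bias beyond the FPKM definition itself, and no linkage between
splicing and expression. Tests passing on it demonstrate that the
machinery computes what it claims under its stated model — not that real
sorted-population data satisfy that model.

## Problem sizes

Default analyses run at the scale above (1810 genes × 60 samples, 190
population pairs, 60 donor units); statistical calibrations use 1000–2000
simulations. These sizes give sub-minute runs for every stage while
keeping Monte-Carlo standard errors a few times smaller than the
tolerances being checked.

## Known limitations

* Voom-style precision weights are not estimated; with counts near zero
  the constant-variance assumption on log2(x+1) is approximate.
* The moment estimator of ρ is noisy at 2 replicates per group; the F
  reference accounts for that on average, but per-donor φ estimates should
  not be interpreted individually.
* Greedy codes are not guaranteed minimal (set cover is NP-hard).
* `select_decomposition_genes` is O(accepted² · datasets) in Jaccard
  checks; fine at 500 genes, not tuned for panels of 10⁴.
* The length-bias test's gene-splitting halves the genes contributing to
  each role, costing some power in exchange for exact null calibration.
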