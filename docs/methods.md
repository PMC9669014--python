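# Methods

`invapop` packages the statistical workflow used to characterise a
recent biological invasion from reduced-representation (RAD-style) SNP
data and field ecology: data cleaning, diversity and structure,
single-population demographic inference on the folded site frequency
spectrum (SFS), host-plant resource selection, and climatic
niche-overlap indices. This note records the models, the estimators,
the numerical choices, and what the synthetic-data experiments do and
do not demonstrate.

## Genotype filtering (`io_filters`)

Genotypes are alternate-allele dosages (0/1/2) with an explicit missing
marker. The site filter cascade runs in a fixed order — allele count,
per-site missingness, mean depth window, monomorphy, minor allele
frequency, external exclusion list — and attributes each removed site
to the *first* criterion that rejects it, so per-criterion counts are
well defined and sum to the total. Defaults: biallelic only, site
missingness ≤ 25 %, mean depth 6–100×, individuals dropped above 45 %
missing, MAF ≥ 0.03. The MAF filter must be disabled
(`maf_min=None`) for demographic inference, which needs rare variants.

LD pruning is PLINK-style: windows of 50 consecutive sites advanced by
5, removing the later member of any pair whose genotype r² exceeds the
pairwise equivalent of a variance-inflation-factor threshold of 2
(VIF = 1/(1−R²), so r² = 0.5). The choice of the *later* site makes
the pass deterministic; allele-frequency-based tie-breaking would
change at most which member of a correlated pair survives. Missing
genotypes are excluded pairwise from frequency and r² computations
throughout the package.

An outlier-SNP screen (e.g. from a Bayesian F\_ST scan) is supported
only as a plug-in exclusion list; detecting outliers is out of scope.

## Diversity statistics (`popgen_stats`)

* Expected heterozygosity uses the Nei small-sample correction,
  He = 2p(1−p)·m/(m−1) with m the non-missing gene copies at the site;
  Ho is the heterozygote fraction. Population values are means over
  sites with ≥ 2 genotyped individuals.
* F\_IS = 1 − mean(Ho)/mean(He), a multilocus ratio of averages, with a
  percentile bootstrap over sites (the resampling unit is the locus;
  default 9,999 replicates, seeded).
* Allelic richness is hypergeometric rarefaction to g gene copies,
  Ar = Σ\_a [1 − C(n−n\_a, g)/C(n, g)], reported both as the per-locus
  mean (≈ 1–2 for biallelic SNPs) and the per-dataset sum, since
  published tables are ambiguous between the two conventions.
* Private alleles count (site, allele) pairs observed in exactly one
  population.
* Tajima's D uses the canonical constants per genomic window (default
  10 Mb); with missing data the constants are evaluated at the median
  non-missing copy number of the window's segregating sites, and the
  summary SE is the standard error of the mean across windows.
* Nucleotide diversity divides the summed unbiased per-site
  heterozygosity by the total number of sequenced sites (variant plus
  invariant), and the drift effective size is Ne = π/(4μ).
* Differentiation is the Weir–Cockerham (1984) variance-components θ,
  combined across loci as Σa/Σ(a+b+c), with a percentile bootstrap over
  loci. θ is slightly negative for identical finite samples — expected
  behaviour of the unbiased estimator, not a bug.

## Structure (`structure`)

PCA mean-imputes missing genotypes per site, centres columns, and takes
the SVD; scores are deterministic up to axis sign.

The admixture estimator is a documented re-implementation of the sNMF
algorithm *class*: the one-hot genotype encoding X (n × L × 3) is
factorised as X ≈ Q G with Q rows projected to the probability simplex
and G holding per-cluster genotype-class frequencies, by alternating
non-negative least squares (per-site linear solves for G, per-individual
NNLS for Q). Missing entries are excluded from the loss rather than
imputed. No sparsity prior is applied by default; a ridge term is
configurable. Because of the simplex renormalisation the loss is not
guaranteed to decrease at every half-step; the loop stops on a relative
tolerance of 10⁻⁵ or after 100 iterations, and the best of `n_runs`
random restarts is kept. K is chosen by the cross-entropy criterion:
a random 5 % of called genotype entries is masked, the model is fitted
on the rest, and the held-out entries are scored by mean negative log
predicted class probability (probabilities clipped to [10⁻⁶, 1]); this
finds the K with the best predictive accuracy, not a biological truth.

## Demographic inference (`demography`)

Four piecewise diploid size histories, backwards in time: constant
(A); instantaneous size reduction at T\_BOT from N\_ANC to the fixed
contemporary size N\_CUR (B); as B but with exponential change
N(t) = N\_CUR·e^{G\_R t} in the recent epoch, negative G\_R meaning
forward-time expansion (C); and a full bottleneck with an explicit
bottleneck size N\_BOT on [T\_ENDBOT, T\_BOT) (D). N\_CUR is supplied
by the user — typically π/(4μ) — and never estimated. Default bounds:
T\_BOT ∈ [50, 1000] generations, N\_ANC ∈ [10³, 10⁷], G\_R ∈ ±10⁻³.

**Expected SFS.** Genealogy level times T\_k (duration with k ancestral
lineages) are simulated by inverting the cumulative pair-coalescence
intensity ∫dt/2N(t) through the epochs (analytic per epoch, including
exponential ones; the inversion is validated against numerical
integration). Topology is integrated out analytically: a branch present
while k lineages remain subtends i of the 2n sampled copies with
probability C(2n−i−1, k−2)/C(2n−1, k−1), so per-class expected branch
lengths follow from the times alone. Class probabilities are
E[L\_i]/E[L\_tot] — the length-biased measure appropriate for spectra
built from one SNP per *segregating* locus, which converges to the
classical 1/i spectrum under constant size. The data simulator uses the
same measure, placing each SNP on a pooled (genealogy × level) length
measure and drawing its class from the exchangeable-topology
distribution.

**Fitting.** The objective is the multinomial composite log-likelihood
over polymorphic folded classes (probabilities floored at 10⁻⁸ and
renormalised; the monomorphic class is excluded). Each optimisation
replicate draws a random start within bounds (log-uniform for sizes)
and a fixed matrix of standard exponentials driving the Monte-Carlo
expected SFS — common random numbers, so the surface is deterministic
within a replicate and cyclic bounded scalar (Brent-style) line search
per free parameter is well behaved. Cycling stops when a full cycle
gains < 10⁻³ nats. AIC = 2k − 2 lnL in natural logs; a base-10
likelihood convention would shift every AIC by a constant factor
without changing rankings. Model comparison reports ΔAIC, Akaike
weights, a joint-support flag at ΔAIC < 3, and a selection frequency —
the fraction of replicate runs (paired by replicate index) in which a
model attains the lowest AIC, our operationalisation of "selected in
X % of the iterations".

**Uncertainty.** Parametric bootstrap: datasets of the same sample size
and SNP count are simulated at the point estimates and re-fitted, the
first replicate initialised at the point estimates and the rest at
random starts so the re-fit replicates the original estimator's
behaviour; percentile 2.5/97.5 intervals are reported and ≥ 80 % of
replicates must converge. The N\_ANC–T\_BOT likelihood surface has a
pronounced ridge (a later, larger bottleneck mimics an earlier, smaller
one), so honest intervals for either parameter are wide; re-fitting
only locally from the point estimate would understate this and is
deliberately avoided.

**Problem sizes.** Paper-scale settings (100 replicates, 40 Brent
cycles, 10⁵ simulations, 100 bootstrap replicates) are accepted via the
API; the package's test and validation experiments use a reduced desk
profile (4,000 Monte-Carlo genealogies per likelihood, 4 replicates,
6 cycles; bootstrap 25 datasets × 2 re-fit replicates at 2,000
genealogies) chosen so the full validation sweep runs on one CPU in
minutes. Below roughly 2,000 genealogies the Monte-Carlo error of the
expected SFS starts to dominate the estimator's scatter, so likelihood
precision is not worth trading much further. The level-times recursion
is compiled with numba when available; a pure-numpy path computes the
identical recursion. The recovery
experiment truth — N\_CUR = 5,000 diploids, N\_ANC/N\_CUR = 5,
T\_BOT = 200 generations, 30 sampled diploids, 5,000 unlinked SNPs —
is a recent-but-detectable founder event; at much larger N\_CUR the
same generation count becomes a vanishing fraction of coalescent time
and the SFS carries little signal.

## Host use (`host_use`)

Incidence is attacked/examined. Between-species comparison is a
binomial GLM with logit link on per-site counts, quasi-style dispersion
from the full model's Pearson statistic, and an F test of the species
term — the same computation as R's `anova(glm(..., quasibinomial),
test = "F")`, against which it is tested. Complete separation is
flagged and handled with a 0.5 continuity correction per group.

The Neu method tests the omnibus null (attacks proportional to
availability) with a χ² goodness-of-fit, then classifies each category
by the Bonferroni simultaneous interval
p̂\_j ± t\_{α/2k, n−1}·√(p̂\_j(1−p̂\_j)/n), where p̂\_j is category j's
share of all attacks, n the total attacked plants at the analysis
level (pooled across sites for taxon-level analyses), and k the number
of categories. Intervals are reported untruncated — negative lower
bounds are meaningful for rarely used hosts — with an optional clamp.
A category is *preferred* when its availability share lies below the
interval, *avoided* when above, *proportional* otherwise.

## Niche overlap (`niche_overlap`)

Schoener's D = 1 − ½Σ|p\_a − p\_b| and Hellinger-based
I = 1 − ½Σ(√p\_a − √p\_b)² on grids normalised to probability
distributions over valid cells. Both are symmetric, invariant to
positive rescaling, and satisfy 0 ≤ D ≤ I ≤ 1. Grids must agree in
shape and no-data mask; silent intersection of mismatched masks is
refused. Niche-model *fitting* (MaxEnt calibration, variable selection,
future projections) is out of scope.

## Synthetic data (`synthetic_data`)

Genotype scenarios (panmictic, two-deme island/divergence, bottleneck
B/C, full D) are coalescent-simulated with msprime as independent
unlinked loci, one biallelic SNP per locus, positions strewn along one
pseudo-chromosome at 5 kb spacing, with uniform random missingness;
folded SFS datasets use the package's own coalescent core so that
demographic fitting is a genuine recovery experiment rather than a
round trip through one engine. Host surveys draw attacked plants
without replacement with probability proportional to planted taxon
weights; suitability-grid pairs mix shared and private Gaussian
kernels. Every generator is bit-reproducible from its seed and returns
a truth record sufficient to score downstream recovery.

What the synthetic data does *not* emulate: linked sites within RAD
loci, sequencing/genotyping error, depth-dependent missingness,
spatially structured sampling, or selection — so passing recovery
experiments demonstrate correctness of the estimators under the model
assumptions, not robustness to those real-data features.

A note on expansion signatures: a recent size reduction in front of a
deep ancestral epoch produces *positive* Tajima's D (burst coalescences
act like a partial catastrophe), not the negative values characteristic
of expansions. The founder-expansion scenario used in validation
(≈ 34 founders growing to 5,000 diploids over 1,000 generations,
ancestral epoch nearly unreachable) is the regime where the classical
negative-D, singleton-excess signature appears.

## Known limitations

* The composite likelihood treats SNPs as independent; with truly
  unlinked single-SNP loci this is exact as a multinomial, but AIC
  comparisons inherit Monte-Carlo noise from the expected-SFS estimate.
* N\_ANC and T\_BOT are only jointly weakly identified from a folded
  SFS of this size; interval estimates for either parameter alone are
  wide and the bootstrap is designed to show that.
* The admixture estimator targets the algorithm class, not numerical
  agreement with any published sNMF implementation.
* Tajima's D with heavy missingness uses a single effective sample size
  per window, an approximation.
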