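# Methods

## The model

`blrfine` fits the multiple linear regression

    y = X b + e,    e ~ N(0, I sigma_e^2),

where X holds centered-and-scaled genotypes, w_i = (x_i - 2 p_i) /
sqrt(2 p_i (1 - p_i)) for effect-allele count x_i and frequency p_i, and the
joint SNP effects b carry a sparsity-inducing prior:

* **BayesC** (spike and slab): b_i = 0 with probability 1 - pi, otherwise
  b_i ~ N(0, sigma_b^2).  `pi` in this package is always the probability of
  a *non-zero* effect; the conventional initial value is 0.01.
* **BayesR** (finite mixture): b_i belongs to class c with probability pi_c
  and b_i ~ N(0, gamma_c sigma_b^2), with gamma = (0, 0.01, 0.1, 1.0) by
  default.  The conventional initial probability vector (0.99, 0.06, 0.03,
  0.01) is not a simplex; we renormalize it (and keep the raw vector as
  `pi_raw`), since the Dirichlet conditional requires one.

Individual-level data are never required.  From marginal GWAS effects b~,
their standard errors, per-variant sample sizes n_i and an LD correlation
matrix B, the cross-products are reconstructed as

    X'X = D^{1/2} B D^{1/2},    X'y = D b~,

with D_i = n_i when genotypes are centered and scaled (the default
convention; phenotypes are assumed scaled to variance 1) and
D_i = 1/(se_i^2 + b~_i^2/n_i) when they are centered only.  B must store
*signed* correlations for this identity to hold; squared correlations are
used only where the credible-set machinery explicitly asks for r^2.  With
in-sample LD and exact in-sample scaling the reconstruction is an algebraic
identity, which the test suite verifies to < 1e-6 relative error and which
makes the summary-statistic fit match an individual-level fit of the same
model.

## The Gibbs sampler

The sampler is the canonical right-hand-side-updating scheme: it maintains
r = X'y - X'X b and, for each variant in turn, forms the residualized
single-variant statistic r_i + (X'X)_{ii} b_i, samples the mixture class
from the conditional posterior odds (the per-class Gaussian marginal
likelihood against the point mass), then samples a non-null effect from its
Gaussian full conditional and restores r.  Hyperparameter conditionals:

* sigma_b^2 ~ scaled-inverse-chi-square with prior (nu_b, S_b^2), updated
  from the sum of b_i^2/gamma_c over non-null variants.  nu_b defaults to 4.
  When S_b^2 is not given it is set so the prior mean equals
  sigma_g2_init / (m * sum_c pi_c gamma_c) — the per-causal effect variance
  implied by an assumed genetic variance (default 0.1) on the scaled
  parameterization.  The conventional printed relation "S_b^2 =
  sigma_b^2 nu_b", motivated by a t-distribution variance of
  nu_b/(nu_b - 2), is internally inconsistent; we use the consistent
  reading S_b^2 = sigma_b^2 (nu_b - 2)/nu_b and leave `S_b2` directly
  settable for anyone who wants the literal one.
* sigma_e^2 ~ scaled-inverse-chi-square from the summary-level residual sum
  of squares n Var(y) - 2 b'X'y + b'X'X b with Var(y) = 1 by convention
  (`var_y` is exposed), under a weak prior (nu_e = 4, S_e^2 = 0.5).
* pi ~ Beta (BayesC) or Dirichlet(c + alpha) (BayesR) over the class
  counts, when `estimate_pi` is set; alpha = (1, 1, 1, 1).

The scan order is a fresh random permutation each sweep (random-scan
Gibbs).  A fixed sequential scan deterministically includes the
first-scanned member of a tightly correlated group at chain start, and
label swapping between near-duplicate variants mixes slowly, so the fixed
order leaves a visible asymmetry; random scan makes the stuck mode
symmetric across independent chains.  `nrun` independent chains (one master
seed spawning per-run streams) are averaged — recommended for dense
regions, and the route to symmetric PIPs under near-perfect LD.

Initialization: b = 0, sigma_e^2 = 1, sigma_b^2 at its prior mean, all
variants in the null class.  Defaults: 10,000 iterations, 1,000 burn-in,
thin 1, nrun 1.  A genome-wide variant of the sampler takes banded LD
(half-bandwidth 1,999 SNPs corresponds to the conventional 2,000-SNP
sliding window) and touches only in-band neighbours when restoring r.
Numerical guards: a non-positive diagonal in X'X raises with advice to add
a diagonal ridge (`ridge` adds ridge * n to the diagonal); the residual sum
of squares is floored at 1e-8.  The inner loops are compiled with numba.

The per-variant posterior inclusion probability (PIP) is the fraction of
kept iterations with a non-zero effect.  An exhaustive 2^m enumeration
oracle (Gaussian marginal likelihood per inclusion pattern, fixed
hyperparameters, m <= 12) serves as the independent reference: the sampler
agrees with it to < 0.02 in the test suite.

## Regions and credible sets

Simulated-data regions are index windows of `half_width` = 500 SNPs on
either side of each causal variant (1,001 SNPs max; the two-causal design
uses 1,000 a side), clipped at chromosome ends and never merged.  Real-data
regions are 1 Mb windows around genome-wide significant lead SNPs
(P < 5e-8), chosen by greedy p-value clumping, merged transitively when
they overlap by more than 500 kb (keeping the most significant lead).

**CS1** sorts a region's variants by PIP (ties broken by ascending
position) and accumulates until the cumulative PIP reaches the coverage
threshold (0.9); if the region's total mass falls short, no set is emitted
and the region scores as a false negative.  **CS2** first emits every
variant with PIP >= coverage as a singleton set, then iteratively seeds on
the highest remaining PIP, groups unassigned variants with r^2 >= 0.5 to
the seed, and emits the group if its cumulative PIP reaches coverage,
discarding the seed group otherwise.  A PIP floor (0.001 in real-data use,
0 in simulations) drops uninformative variants first.  Purity is the mean
absolute pairwise correlation among a set's members (mean r^2 is also
reported); singletons have no purity, and sets beyond 100 SNPs use a seeded
random subsample.

## Evaluation

Per region: a credible set containing a causal (index) SNP is a true
positive unless it exceeds 10 SNPs (then a false negative); a set without a
causal SNP is a false positive; a region with no set, or whose fit did not
converge, is a false negative.  Causals are scored independently, so one
set containing both causals of a two-causal region yields two true
positives.  F1 = 2pr/(p + r) with zero denominators giving 0 (so
empty-output methods score worst).  The PIP AUC is the midrank Mann-Whitney
statistic against the causal indicator.  Convergence uses the Geweke
diagnostic on the sigma_b^2, sigma_e^2, sigma_g^2 and pi chains: the means
of the first 10% and last 50% of a chain are compared with a
spectral-density-at-zero standard error (Bartlett window spanning 4% of
the segment — the diagnostic's classic proportional bandwidth; a fixed
short lag underestimates the long-run variance of slowly mixing chains
and over-flags stationary ones), and |Z| > 3 on any assessable chain
flags the region.  Constant chains are non-assessable rather than
failures.  The class-probability chain of the mixture prior has a
correlation length of hundreds of sweeps on 1,000+-SNP regions, so dense
regions warrant long chains (the benchmark uses 20,000 sweeps with 2,000
burn-in) before the diagnostic is informative.

## The simulator

Genotypes are two haplotypes per individual, each a first-order
autoregressive latent Gaussian (lag-one correlation `ld_rho`, default 0.9
in the workflow) thresholded at the per-variant effect-allele frequency
(uniform in [0.01, 0.49]; the 0.01 floor mirrors common MAF QC).  This
produces tunable, banded, blocky LD — what region-wide and banded
genome-wide fine-mapping need to be exercised — but it is an emulator:
real-cohort LD has long-range structure, variable recombination, and allele
frequency/LD coupling the AR(1) process does not reproduce.  Passing tests
therefore demonstrate correctness of the machinery under controlled LD,
not performance guarantees on any particular cohort.

Quantitative phenotypes follow y = sum w_i b_i + e with sigma_g^2 = h2 and
sigma_e^2 = sigma_g^2 (1/h2 - 1), so Var(y) = 1 in expectation.  GA1 draws
all causal effects from N(0, sigma_g^2/m_C); GA2 assigns causals to
small/moderate/large classes in proportions 93/5/2% (largest-remainder
apportionment, so 1,000 causals split exactly 930/50/20) with per-SNP
variances (0.6, 0.2, 0.2) sigma_g^2 over the class counts, making the
classes contribute 60/20/20% of genetic variance in expectation.  The
two-causal design places two variants with fixed effects (L = 0.05,
S = 0.01) and residual variance fixed at 1.0 (not rescaled), i.e. per-SNP
heritabilities of ~0.0025 and ~0.001.  Binary traits label the top
`prevalence` fraction (exactly round(n * PV) individuals, ties broken by
sample index) as cases; the binary GWAS is a per-variant Newton-Raphson
logistic regression whose log-odds effects are fed to the same
reconstruction treating them as approximately Gaussian marginal effects —
an approximation, the same one made when PLINK logistic output is used.

## Workflow scale choices

A biobank-scale experiment (hundreds of thousands of individuals times
half a million SNPs times ten replicates) is not a desk-scale object.
`run_scenario` defaults are chosen so grids run on one CPU: cohort n = 20,000-25,000, m = 2,000-5,000, 5 replicates with
80% subsampling per replicate, and (in tests) region half-widths of 60
SNPs and 1,500-3,000 Gibbs iterations.  The two-causal benchmark is the
exception and runs at its stated n = 300,000 and 2,001-SNP regions with
3-4 replicates and 20,000-sweep chains (see the convergence remark
above).  All randomness flows from one master seed through named,
hashed substreams (genotypes, subsampling, phenotypes, MCMC per
method/region), so every scenario is bit-reproducible from its config; a
failed or non-converged region becomes a false negative rather than
aborting.

## Known limitations

* With estimated class probabilities, the BayesR class at gamma = 0.01 can
  become statistically indistinguishable from the null class on data with
  little or no signal (its slab variance approaches zero, Bayes factors
  approach 1), letting the class probabilities random-walk and inflating
  PIPs.  On weakly informative regions the chain can even settle into a
  quasi-stable mode with most variants carrying tiny class-2 effects.
  This is an identifiability property of the mixture prior, not a sampler
  defect; the spike-and-slab prior does not share it, and on data with
  real signal the variance scale is anchored.  Null-calibration and
  equivalence checks therefore use the spike-and-slab model, and multiple
  independent runs (nrun) are advisable for BayesR on weak regions.
* Single-site Gibbs swaps labels between perfectly correlated variants very
  slowly; a single chain can hold an asymmetric split of the shared
  inclusion mass for tens of thousands of sweeps.  Random scan plus
  chain-averaging (nrun >> 1) restores symmetry; the joint inclusion mass
  is unaffected.
* Parameter-recovery checks for pi are run in an identifiable design
  (independent variants, strong per-variant power): under heavy LD or weak
  data the causal count itself is weakly identified — architecture draws
  include near-zero "causal" effects no likelihood can see — and interval
  coverage degrades for reasons unrelated to sampler correctness.
* The logistic-to-linear bridge (log-odds effects into a Gaussian residual
  model with Var(y) = 1) is heuristic; it matches established practice but
  its sigma_e^2 chain should not be interpreted as a residual variance on
  the observed scale.
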