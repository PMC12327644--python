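# blrfine

Statistical fine-mapping with Bayesian linear regression (BLR) on GWAS
summary statistics.

After a genome-wide association study, an associated locus typically
contains dozens of variants in linkage disequilibrium (LD) with the causal
one(s).  Fine-mapping narrows the signal: given per-variant marginal
effects b~, their standard errors, sample sizes and an LD correlation
matrix **B**, `blrfine` fits the joint model

    y = X b + e,    X'X = D^{1/2} B D^{1/2},    X'y = D b~,

by Gibbs sampling under sparsity priors — **BayesC** (spike and slab:
b_i = 0 with probability 1 − π, else N(0, σ_b²)) or **BayesR** (a mixture
with a null class and graded slab variances γ·σ_b², γ = (0, 0.01, 0.1, 1)) —
producing for every variant a **posterior inclusion probability** (PIP),
the fraction of MCMC iterations in which it carries a non-zero effect.
PIPs are condensed into 90% **credible sets** (a simple cumulative-PIP set,
or multiple LD-grouped sets with an r² ≥ 0.5 purity rule), and the package
scores fine-mapping output with the credible-set confusion rules
(precision, recall, F1 = 2pr/(p+r), PIP AUC), checks chains with the
Geweke |Z| > 3 diagnostic, and computes polygenic scores
PGS = Σ x_i b̂_i with R²/AUC predictive metrics.

It is aimed at statistical geneticists who want a self-contained,
summary-statistic-native fine-mapping toolkit with a fully scriptable
simulation bench: genotypes with tunable banded LD, quantitative phenotypes
under single-normal (GA1) or three-class-mixture (GA2) architectures,
two-causal-variant regions, and binary traits by top-quantile
dichotomization.

## Worked example

```python
import numpy as np
import blrfine as bf

# simulate a cohort and one causal variant region
G = bf.simulate_genotypes(n=10_000, m=500, ld_rho=0.9, seed=1)
W = bf.scale_genotypes(G)
sim = bf.simulate_ga1(W, m_causal=1, h2=0.02, seed=2)

# GWAS summary statistics + in-sample LD
ss = bf.gwas_linear(W, sim.y)
B = bf.compute_ld(W)

# BayesR fine-mapping on summary statistics only
fit = bf.fit_blr(ss, B, bf.BayesRPrior(estimate_pi=True),
                 bf.MCMCOptions(n_iter=5_000, n_burnin=1_000, seed=3))

# 90% credible sets with LD grouping
sets = bf.cs2(fit.pip, B)
```

With print statements on the causal truth, the top GWAS hit, the leading
PIPs and the resulting sets, this session produces:

```
causal variant: 1:snp418 (effect -0.0739)
top GWAS hit: 1:snp418 (p = 2.21e-12)
PIP[1:snp418] = 1.000
PIP[1:snp40] = 0.322
PIP[1:snp173] = 0.266
credible set: ['1:snp418'] (cumulative PIP 1.000, purity None)
```

The simulated causal variant carries a PIP of 1.000 and is recovered as a
singleton credible set (purity is undefined for single-SNP sets); the two
other moderately ranked variants do not accumulate enough posterior mass to
form a set.  Under the confusion rules this region scores one true
positive and no false positives.

A command-line interface mirrors the pipeline
(`blrfine simulate | gwas | ld | finemap | credsets | evaluate | pgs |
run-scenario`); data flows through plain TSV files and YAML scenario
configs, and every metrics table carries its config hash and seed.

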