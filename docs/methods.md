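# Methods

## The model

`triogxe` infers gene–environment interaction from case-parent trios: an
affected child and both biological parents, genotyped at candidate SNPs,
with a binary maternal exposure `E` recorded per trio. Disease risk is
log-linear in the child's minor-allele count `g ∈ {0,1,2}`, the exposure
`e ∈ {0,1}` and a stratification covariate `x`:

    log P(D=1 | g, e, x) = β₀ + g·β_G + e·β_E + x·β_X
                           + g·e·β_GE + g·x·β_GX + e·x·β_EX + g·e·x·β_GEX

Conditioning the child's genotype on the parental genotypes `G_p` and the
affected status eliminates every term not involving `g`. What remains is
the genotypic odds

    P(G=g | D=1, e, x, G_p) / P(G=g−1 | …) = exp(k_p + β_G + e·β_GE + x·β_GX + e·x·β_GEX)

where `k_p` is the log-ratio of consecutive Mendelian transmission
probabilities for the parental pair and cancels from the normalized
conditional likelihood. Consequently only the four genotype-involving
coefficients are estimable; exposure and stratification main effects are
invisible to the design by construction (and the package's tests verify
that changing them in the generative model leaves the fitted surface
unchanged up to Monte Carlo error).

The conditional likelihood of a trio is the Mendelian transmission
probability of the observed child genotype, reweighted by
`exp(g·(β_G + e·β_GE + x·β_GX + e·x·β_GEX))` and normalized over the
Mendelian-compatible child genotypes. Trios with both parents homozygous
admit a single child genotype, contribute a constant, and are excluded from
the informative count.

The no-interaction null `β_GE = β_GEX = 0` is tested by a likelihood-ratio
statistic on 2 degrees of freedom (1 df for the unadjusted model without
`x`). Group-specific interactions are summarized by the exponentiated
contrasts `exp(β_GE)` (surrogate-0 group) and `exp(β_GE + β_GEX)`
(surrogate-1 group) with Wald 95% intervals, the latter using
`var(β_GE) + var(β_GEX) + 2·cov`.

### Why adjustment is needed

G×E inference from trios is biased by *exposure-related population
structure*: when subpopulations differ both in haplotype frequencies across
a linked causal/test locus pair and in exposure rates, the exposure tags
ancestry, ancestry tags the locally varying apparent genetic effect at the
non-causal test locus, and a spurious interaction appears. The `g·x` term
absorbs group-specific genetic effects and the `g·e·x` term group-specific
interactions; with a good surrogate `x` the adjusted 2-df test restores the
nominal error rate.

Two surrogates are implemented:

* **SRA** — self-reported ancestry, coded 0 (reference group) / 1
  (comparison group); trios outside the two named groups are excluded.
* **EEGM** — expected exposure given genetic markers: fitted probabilities
  of a logistic regression of `E` on principal components of a marker
  panel, rescaled onto [0,1] by `(v − min)/range`. The continuous value
  enters the likelihood directly, without discretization.

## Estimation and numerics

* The conditional log-likelihood is concave in the four coefficients (a
  conditional multinomial exponential family with a linear natural
  parameter). It is maximized by projected Newton with analytic gradient
  and Hessian inside the box |β| ≤ 15, convergence at projected-gradient
  max-norm < 1e-8, with up to 3 jittered restarts and a box-constrained
  L-BFGS-B fallback. A coordinate parked at the box boundary indicates a
  monotone likelihood direction (separation, typical when exposed trios
  are nearly absent in one stratum); the bound approximates the supremum,
  the estimate is flagged `separation` and its covariance `vcov_unreliable`.
  Parking at the bound also guarantees nested fits never produce a negative
  LRT statistic.
* Covariance is the inverse observed information at the optimum.
* Identifiability: a fit falls back along adjusted → common-G×E (drop
  `β_GEX`) → unadjusted, each step flagged, when the observed information
  at β=0 has an eigenvalue below 1e-8 of the largest, or — for a binary
  surrogate — when an exposed stratum cell contains no informative trios.
  The common-G×E model assumes one shared interaction across groups.
* LRT statistics are floored at 0; p-values come from the upper χ² tail.
* Per-SNP scans drop trios excluded by *any* requested surrogate from all
  three analyses, so the unadjusted, SRA and EEGM fits compare the same
  cohort.

## Principal components and the number of axes

PCA operates on the frequency-standardized genotype matrix
(`(g − 2p)/sqrt(2p(1−p))`, monomorphic markers dropped, missing genotypes
mean-imputed) of one family member per trio — the child by default, so
there is exactly one vector per trio. Components are sign-fixed (largest
absolute loading positive), making results bit-reproducible.

The number of PCs fed to the exposure regression matters more than is
commonly appreciated at small panel sizes. With two subpopulations a single
axis carries all structure; every additional axis is noise, and a logistic
regression of exposure on noise axes partially memorizes each trio's own
exposure. That contaminates EEGM with the very variable it is meant to
summarize and measurably inflates the adjusted test's type-I error (at 500
trios × 300 markers, ten axes push the 2-df rejection rate at α=0.05 to
≈0.075). `compute_pcs(k="auto")` therefore retains only components whose
covariance eigenvalue exceeds the Marchenko–Pastur bulk edge
`(1 + sqrt(m/n))²` of a structureless standardized matrix (at least one, at
most ten) — the random-matrix analogue of keeping only significant axes.
The simulation harness uses `"auto"`; a fixed `k` (default 10) remains
available for explicit control.

The exposure-structure diagnostic is the k-df likelihood-ratio test of the
logistic regression of `E` on the PCs against the intercept-only model; a
non-significant result means the panel carries no exposure-related
structure for EEGM to adjust.

Logistic fits use maximum likelihood; on detected separation (diverging or
non-finite coefficients) a ridge-penalized refit (penalty 1e-4) supplies
bounded values, flagged.

## The synthetic cohort generator

The generator is the package's stand-in for a multi-ancestry orofacial-cleft
trio study and defines the conditions under which the methods are tested:

* Two latent subpopulations (default equal proportions) with per-subpop
  frequencies over the four haplotypes of a causal/test locus pair, and
  per-subpop maternal exposure rates — defaults 4% and 41%, the observed
  alcohol-consumption rates in East Asian and European trio groups of a
  462-trio oral-cleft consortium cohort.
* Parents are formed by random mating within subpopulation; each parent
  transmits one haplotype uniformly; maternal exposure is Bernoulli by
  subpopulation. Only the mother's exposure is generated — the exposure is
  a maternal, peri-conceptual one.
* Ascertainment is rejection sampling on the child's affected status under
  the full risk model evaluated at the child's causal-locus genotype and
  the true group indicator; a run aborts if the acceptance probability
  falls below 1e-6. G and E are independent given parental genotypes
  within subpopulation by construction.
* An accompanying marker panel (default 300 independent loci) follows
  Balding–Nichols divergence: ancestral frequencies Uniform(0.1, 0.9) and
  per-subpop Beta draws at Fst 0.15 — divergence on the order of
  continental-scale differentiation. Parents are HWE within subpopulation;
  children receive one transmitted allele per parent.
* True subpopulation labels, causal genotypes and haplotype phase go to a
  sidecar table, never into analysis inputs. A single seeded generator
  drives all draws; cohorts are bit-reproducible.

The `spurious_gxe` preset realizes exposure-related structure with **no
true interaction**: causal-allele frequency 0.10 vs 0.40 across
subpopulations, LD with the test locus (r ≈ 0.6) only in the
high-frequency group, test-allele frequency 0.50 in both, per-copy causal
relative risk 3, baseline log-risk −5, exposure relative risk 1.5. The
divergence level is the package's own choice — large but within the range
of continental allele-frequency differences — and is justified by the
simulation harness: at 500 trios the unadjusted 1-df test rejects a true
null at ≈0.25 instead of 0.05, while both adjusted 2-df tests stay at the
nominal level.

The `single_population` preset (identical subpopulations, one locus,
exposure rate 41%, minor-allele frequency 0.3, β_G=0.3, β_GE=0.5,
β₀=−4) drives parameter-recovery studies.

### What the generator does not emulate

Genotyping error, missingness patterns, linkage disequilibrium among
markers, admixed individuals, more than two ancestral groups (the config
accepts ≥2 but presets use two), assortative mating, and parental-genotype
main effects. Passing tests therefore demonstrate correctness of the
inference machinery and the bias/adjustment mechanism under clean
two-population structure, not robustness to the full messiness of array
data.

## Problem sizes

Simulation studies in the test-suite and the acceptance script use cohorts
of 500–1,000 trios, 300-marker panels and 300–1,000 replicates — sizes at
which the Monte Carlo error of a rejection rate at α=0.05 is below 0.01
and a full study completes in minutes on one core.

## Known limitations

* Per-copy (log-additive) genotype effects only; no codominant coding.
* Binary exposures only; the EEGM idea extends to continuous exposures via
  linear regression, but this is not implemented.
* No sibling-augmented designs, parent-of-origin or maternal-genotype
  effects, and no local-ancestry (haplotype-level) adjustment.
* Wald intervals and χ² reference distributions are asymptotic; with very
  few informative exposed trios the separation flag, not the interval,
  is the meaningful output.
* P-values are reported raw, without multiple-testing correction.
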