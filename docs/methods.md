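# Methods

## The estimation problem

A family pool is a bulk DNA sample from many plants of one family; GBS
measures, at each biallelic SNP, the pool allele frequency with a number of
reads (the sequencing depth). For F2 families — the progeny of
intercrossing two F1 full sibs from a pair cross — the true pool frequency
is determined by the four founder allele copies carried by the two F1
parents and therefore lies on the quarter grid {0, ¼, ½, ¾, 1}; the pool
behaves like a tetraploid genotype. `poolherit` treats the SNP × family
matrix of observed pool frequencies as the genotype data, builds a
relationship matrix between families from it, and partitions phenotypic
variance of plot-level trait records into genomic, uncorrelated-family,
parent-population and residual components.

## Genomic relationship matrix

Frequencies are centered per SNP by the mean over non-missing families;
missing cells are mean-imputed, which is exactly a zero in the centered
matrix. The scaling constant K = 0.25 Σ X̄ᵢ(1 − X̄ᵢ) is the sum of expected
per-SNP variances of non-inbred F2 pool frequencies, so the diagonal of
G = M′M/K is interpretable as 1 + (excess apparent inbreeding + measurement
inflation). Centering makes G singular with one (near-)zero eigenvalue;
`invert_grm` eigendecomposes G, raises the smallest eigenvalue to
`repair_factor` (default 0.99, configurable) times the second smallest, and
assembles the inverse as E Λ⁻¹ E′ from the repaired spectrum.

The optional missing-rate correction divides each element (j, k) by a
pairwise constant K_jk accumulated only over SNPs observed in both families
j and k, so that relationships among sparsely genotyped samples are not
shrunk toward zero by imputed cells. It is a no-op on complete data, is on
by default in the empirical pipeline and off in the simulation study (whose
data are complete). The means X̄ᵢ and K are recomputed on exactly the SNP
subset entering each GRM (depth bin or subsample).

## Quality filters

Order: mean-depth filter (> 60 discarded) → mean-frequency filter (outside
[0.02, 0.98] removed, boundaries retained) → family missing-rate filter
(> 50 % dropped) → depth binning. The frequency bounds are applied to the
per-SNP mean frequency across families — the same mean that centers the
GRM; a per-cell rule would be an alternative reading, but the mean is the
quantity the GRM actually uses. Mean depth includes zero-depth (missing)
cells, since depth 0 is a real sequencing outcome of a SNP. Depth bins are
(lo, hi] with the first bin closed at 0; the convention at shared edges is
configurable via `DepthBinSpec`.

## AI-REML

The REML log-likelihood (constants dropped) is
ℓ = −½(log|V| + log|X′V⁻¹X| + y′Py) with V = Σ σ²ᵢ Vᵢ + σ²_e I and
P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹. Updates use the average-information matrix
AI_ij = ½ y′PVᵢPVⱼPy and score −½(tr(PVᵢ) − y′PVᵢPy). Numerical policy:

- starting values: equal partition of the OLS residual variance;
- the first 2 iterations are EM steps (σ² ← σ² + σ⁴(y′PVᵢPy − tr(PVᵢ))/qᵢ)
  for stability, and any AI step that would decrease ℓ falls back to an EM
  step, making the objective non-decreasing over accepted iterations;
- proposals are truncated at a floor of 1e-8 × phenotypic variance;
  components pinned at the floor with negative score are dropped from the
  AI solve for that iteration;
- convergence when |Δℓ| < 1e-9 or the maximum relative parameter change is
  < 1e-8; iteration cap 200, after which a convergence error carrying the
  trajectory is raised. All controls are configurable.
- rank-deficient fixed designs are reduced to a full-rank column basis by
  pivoted QR, so the likelihood is invariant to over-parameterization.

The asymptotic covariance of the estimates is the inverse AI matrix at the
optimum; heritability standard errors use the delta method on the ratio
estimators (likelihood-profile intervals would be an alternative; the
delta method is what the output labels).

Two kernels implement the identical algorithm. The dense kernel handles
arbitrary terms (used for the empirical model with its parent-population
term). For balanced family-GBLUP models — one or two replicates per family,
genomic plus optional iid family term — the data are first transformed by
per-family sums/differences (scaled orthonormally) and then rotated into
the eigenbasis of G; both are orthogonal data transformations under which
the REML likelihood is unchanged, and they make every covariance structure
diagonal, so each iteration is O(n) after one eigendecomposition. Tests
verify the two kernels agree to numerical precision and that both match a
direct numerical maximization of the same coded likelihood. Mixed-model
systems are solved by dense factorizations throughout (problem sizes are a
few thousand at most).

With one replicate per family the iid family effect is confounded with the
residual and is omitted; requesting it explicitly raises an error.

## Heritability estimators

var(y) = Ḡ σ²_g + σ²_f + w σ²_p + σ²_e, where Ḡ is the mean diagonal of the
GRM used in the fit and w is the diagonal of WW′ (2 when every family has
two parents from two parent populations). The "G" multiplying σ²_g in the
broad-sense numerator is likewise the mean diagonal. This is the mechanism
by which depth bias expresses itself: measurement noise inflates Ḡ and
deflates σ̂²_g, and h²_G = σ²_g/var(y) falls while H² (which multiplies
σ̂²_g back by Ḡ) stays near the truth.

## Simulator

The simulator emulates an F2 family-pool study: per-SNP population
frequencies uniform on [0.05, 0.95]; independent SNPs (no linkage or
ancestral LD); true pool frequencies in quarters; GBS noise as
Binomial(depth, q)/depth per cell (depth "infinite" returns the truth); a
uniformly chosen QTL subset with standard-normal effects; genetic values
standardized to empirical variance exactly 1; overall mean 0. With genetic
variance 1, the nuisance variances follow from the target heritabilities:
σ²_e = 3 for one replicate (h² = 0.25) and σ²_f = 0.5, σ²_e = 2.5 for two
replicates (h² = 0.25, H² = 0.375). One root seed per dataset is split into
documented sub-streams (frequencies → pool genotypes → reads → phenotypes),
so any stage can be regenerated independently.

Two founder-allele constructions are provided, because the exact generator
for "25 % inbred" F2 pools is genuinely open:

- `independent` (default): the four founder copies are iid Bernoulli(p),
  pool frequency = Binomial(4, p)/4, per-SNP variance 0.25 p(1−p), expected
  scaled GRM diagonal ≈ 1.0 at infinite depth, inflation ≈ +3/depth.
- `f1_intercross`: two diploid parents with alleles (a₁,a₂), (b₁,b₂); each
  F1 sib inherits one allele per parent; the pool frequency is the mean of
  the two sibs' four alleles. Founder copies are then positively correlated
  within a family: per-SNP variance 0.375 p(1−p), expected diagonal ≈ 1.5.

Neither construction yields a diagonal of exactly 1.25 (the value implied
by 25 % inbreeding); the two bracket it. Run against the depth-bias study,
the `independent` model reproduces the expected pattern: its per-SNP
reliability is r = depth/(depth + 3), giving h²_G ≈ 0.25 r² ≈ 0.10 / 0.17 /
0.20 at depths 5 / 15 / 25, whereas the correlated-founder model predicts
r = 3d/(3d + 5) and ≈ 0.14 at depth 5, which does not match. `independent`
is therefore the default; the option is exposed on the scenario and the
generator functions.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real field data: linkage and LD between markers,
finite-pool sampling of plants into the bulk sample, sequencing error on
top of binomial read sampling, genotype-by-environment interaction, spatial
field trends, and non-Gaussian trait distributions. The
`simulate_empirical_dataset` helper adds the structural features the field
pipeline needs (per-cell Poisson depths spanning the bins, missing cells at
depth 0, trial blocks assigned round-robin, parent-population effects, two
plots per family) but inherits the same distributional idealizations.

## Problem sizes and runtime choices

The scenario runner uses the paper-scale study conditions: 500 families,
1000 SNPs, 50 datasets per scenario; with the spectral REML path one
scenario takes a few seconds. The in-suite cross-engine, oracle and
pipeline tests use smaller instances (tens to hundreds of families), chosen
so each test isolates one property rather than repeating the full study.
Monte Carlo assertions use 3-standard-error bands (2 SEs for directional
gap checks), with SEs computed from the runs themselves.

## Known limitations

- The empirical pipeline is exercised only on synthetic field-shaped data;
  field datasets of this kind are generally not public, so per-trait
  heritability estimates from real trials are not reproduced here.
- Single-trait REML only; no multi-trait models, BLUP reporting, Bayesian
  estimation or genomic prediction.
- The delta-method SEs assume an interior optimum; at a variance boundary
  they are reported but approximate, and a non-PSD AI covariance yields
  NaN SEs with a warning.
- The missing-rate correction can make G slightly non-PSD for extreme
  missingness patterns; the repaired inverse guards downstream solves.
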