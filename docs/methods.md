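# Methods

## Model

For a quantitative trait `y` measured on `n` members of one or more
pedigrees, the animal model is

```
y_i | eta_i, sigma_e^2  ~  N(eta_i, sigma_e^2)
eta_i = beta_0 + x_i' beta + u_i
u | sigma_g^2 ~ N(0, sigma_g^2 A),     A = 2K
```

with `K` the kinship matrix and `A` the additive relationship matrix.
Narrow-sense heritability is the variance ratio
`h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)`. For non-inbred pedigrees
`diag(A) = 1`, so `sigma_g^2` is each individual's additive genetic variance.

Kinship coefficients are computed by the standard recursion over a
parents-before-offspring ordering (`phi(i,i) = 1/2 + 1/2 phi(f,m)`,
`phi(i,j) = 1/2 (phi(f,j) + phi(m,j))`), with missing parents treated as
unique unrelated founders. An independent gene-dropping Monte Carlo oracle
(`pediherit.validation`) simulates allele transmission and never touches the
recursion; the two agree within Monte Carlo error in the test suite.

## Priors

* Variance components: the **precision** `1/sigma^2` of each component has a
  Gamma(shape = 1, rate = 0.00005) prior, the conventional vague choice for
  latent Gaussian models. On the log-variance scale `t = log sigma^2` this is
  `p(t) = b^a / Gamma(a) * e^{-a t} * exp(-b e^{-t})`. Note this prior is
  *not* flat in `h^2`: for weakly informative data it induces a U-shaped
  `h^2` prior with mass piled near 0 and 1, which is why posterior modes at
  small `n` can snap to the boundaries and why genuinely zero-heritability
  traits produce near-zero posteriors rather than diffuse ones.
* Fixed effects: independent N(0, 1000²) on standardized (centered/scaled)
  covariates; estimates are reported back on the original scale. The Gaussian
  prior keeps the marginal likelihood of the variances available in closed
  form (a rank-p Woodbury correction).
* Units: age enters in years, gender as 0/1; the defaults of the synthetic
  generator are 0.01 trait-SD per year and 0.1 trait-SD respectively.

## Posterior engines

Both engines work in the eigenbasis of `A = 2K` (one `O(n^3)`
factorization per kinship subset, cached and shared across traits/sites),
where the marginal covariance of `y` given the variances is diagonal plus a
rank-p term; each marginal-likelihood evaluation costs `O(n p^2)`.

* **Grid** (default, deterministic): the joint posterior of
  `(log sigma_g^2, log sigma_e^2)` is evaluated on an 81 × 81 grid over
  [−12, 6] per axis and normalized by the trapezoid rule. If more than 1% of
  the mass lands on the outermost ring, the grid is widened by ±6 once and
  the fit retried (a persistent boundary raises a `grid_boundary` warning).
  The `h^2` posterior follows by the change of variables
  `h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)`: the mode from a 512-bin
  weighted histogram, the mean and equal-tailed 95% interval from weighted
  quantiles. The fixed-effect posterior is the grid-weighted Gaussian
  mixture of the per-cell conditional posteriors.
* **Gibbs** (stochastic cross-check): a blocked conjugate sampler drawing
  `beta` from its variance-marginal conditional, then the genetic effects
  coordinate-wise in the eigenbasis, then both variances from inverse-gamma
  conditionals; 10,000 iterations after 2,000 burn-in by default, explicit
  seed required. Effective sample size of the `h^2` chain is estimated with
  arviz and a `low_ess` warning is raised below 100.

At `n ≈ 500` and moderate true `h^2`, grid and Gibbs posterior means agree
within 0.01. At `n ≲ 300` the `h^2` posterior can be bimodal (a spike near 0
from the prior plus a data-driven lobe) and the sampler may weight the modes
differently from the grid; the grid engine is the reference in that regime.

## Formulations

* `direct` — the model above.
* `reparameterized` — the observation variance is fixed at a small nuisance
  `sigma_0^2 = 4.54e-5 = exp(-10)` and both the genetic effect and an iid
  residual effect are latent. This is the standard trick that makes the full
  `h^2` posterior directly accessible in latent-Gaussian software; it is
  equivalent to `direct` up to `O(sigma_0^2)` and the package verifies the
  two agree to < 0.02 in `h^2` mode. A `sigma0_large` warning fires if
  `sigma_0^2` is not small relative to `var(y)`.
* `null` — no genetic component; the comparison model for selection.

## Model selection

The genetic component is retained when `ΔDIC = DIC(null) − DIC(genetic) > 10`
(strict). Two deviance conventions are implemented, both computed on every
fit and selectable via `dic_kind`:

* **conditional** (default): `D(beta, u, sigma_e^2) = −2 log N(y; X beta + u,
  sigma_e^2 I)` — the deviance of the data given the latent field, the
  convention of latent-Gaussian (INLA-style) software. On the grid it has a
  closed form per cell via per-coordinate shrinkage factors; the plug-in
  point is the posterior mean fitted field with the log-scale posterior mean
  noise variance. Measured operating characteristics at `n ≈ 500`
  (50 replicates per condition): selection rate 0.00 at true `h^2 = 0` and
  `0.1`, ≈ 0.7 at `0.3`, 1.00 at `0.5`; median ΔDIC monotone in `h^2`.
* **marginal**: `D(theta) = −2 log p(y | sigma_g^2, sigma_e^2)` with the
  latent field and fixed effects integrated out, `theta` the log-variances.
  It has ~2 effective parameters by construction and substantially lower
  power (~60% at `h^2 = 0.3`); it is kept because it is cheap, exactly
  recomputable from any stored posterior representation, and useful as a
  conservative alternative.

The conditional variant is the default because it reproduces the selection
behavior expected of this model family; the choice is recorded on every
result (`dic_kind`, plus both `dic_conditional` and `dic_marginal`).

## Methylation preprocessing

Beta values (methylated proportions in (0,1)) are transformed to M-values
`M = log2(beta / (1 − beta))` with betas clipped to `[1e-6, 1 − 1e-6]`;
probes on a user-supplied SNP exclusion list are dropped before scanning,
because their apparent methylation partly reflects genotype and would
inflate heritability.

## Genome scan

`pediherit.scan.scan` fits the genetic/null model pair at every site,
sharing the kinship eigendecomposition and all y-independent grid quantities
across sites (amortized ≈ 20 ms per site pair on one CPU). Summaries report
the number and fraction of selected sites, mean/median/IQR of `h^2` modes
among selected sites, the median over all sites ("zero component included",
using non-selected sites' actual near-zero estimates, not literal zeros),
and the Pearson correlation of estimates over sites selected at both of two
time points. Per-site failures become warned NaN records and never abort a
scan.

## Synthetic data generator

The generator emulates a family study, not any particular cohort:

* **Pedigrees**: `three_generation_default` families have 4 founder
  grandparents, a father and mother who are offspring of the two
  grandparental couples, and 1 + Poisson(3) children (≈ 10 members/family);
  `full_sib_pairs` gives 2 founders + 2 sibs. 50 families ≈ 500 individuals.
* **Covariates**: age uniform within generation (60–80 / 35–55 / 10–30
  years), gender from the pedigree.
* **Traits**: the animal model run generatively with
  `sigma_g^2 = h^2 * total_variance`.
* **Methylomes**: per-site true `h^2` follows a zero-inflated mixture —
  zero with probability `pi0` (default 0.05), otherwise Beta(2.5, 4.5)
  (mode 0.3, right-skewed). Two time points are coupled by a Gaussian copula
  on the mixture draws (default correlation 0.6) plus a shared genetic
  draw, so true and estimated `h^2` are correlated across time points.
* **Seeding**: all randomness descends from one master seed through named
  `SeedSequence` streams (master → purpose → family/site), so any family or
  site is reproducible in isolation.

Not simulated: array probe chemistry, batch effects, shared-household
environmental covariance, SNP genotypes.

## Problem sizes and performance

Defaults target a single CPU: `n ≈ 500` individuals, 448-site scans. One
grid fit costs ≈ 0.4 s cold and ≈ 20 ms with a shared design cache; a Gibbs
fit ≈ 7 s; a 448-site scan (genetic + null per site) ≈ 35 s per time point.

## Limitations

* The ΔDIC > 10 rule has essentially no power below true `h^2 ≈ 0.2` at
  `n ≈ 500`; genome-scan selection therefore censors low-heritability sites,
  and the median `h^2` among *selected* sites overestimates the
  nonzero-component median of the generating mixture (measured gap ≈ 0.11 at
  448 sites). Larger cohorts shrink this selection bias; summaries report
  the all-sites median alongside the selected-only one for this reason.
* The Gamma precision priors are not scale-free: extremely small or large
  trait variances shift mass toward the zero-variance spike. The grid
  auto-widens, but traits should be roughly unit-scale (M-values are).
* Posterior `h^2` modes at small `n` can sit exactly at 0 or 1 (induced
  U-shaped prior); the posterior mean and interval are the more stable
  summaries in that regime.
* No dominance, epistasis, shared environment, or GxE terms; a single
  additive genetic component only.
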