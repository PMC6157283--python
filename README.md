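# pediherit

Bayesian estimation of narrow-sense heritability in extended pedigrees, with a
genome-scan mode for DNA-methylation (CpG) traits.

`pediherit` fits the **animal model** — a linear mixed model whose random
effect encodes additive genetic covariance between relatives — to one
quantitative trait or to every site of a methylation matrix:

```
y_i | eta_i, sigma_e^2  ~  N(eta_i, sigma_e^2)
eta_i = beta_0 + x_i' beta + u_i,       u ~ N(0, 2 sigma_g^2 K)
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)
```

`K` is the pedigree kinship matrix (so `A = 2K` is the additive relationship
matrix) and `h^2` is narrow-sense heritability. Each variance component's
precision gets a vague Gamma(1, 0.00005) prior; fixed effects (age, gender by
default) get vague Gaussians. Whether a trait is heritable at all is decided
by comparing the model against its no-genetics counterpart with the deviance
information criterion: ΔDIC > 10 means strong support for the genetic
component.

## What's in the box

| Module | Purpose |
| --- | --- |
| `pediherit.pedigree` | pedigree I/O (LINKAGE/CSV), validation, topological utilities |
| `pediherit.kinship` | recursive kinship matrix, `A = 2K`, cached eigendecomposition |
| `pediherit.model` | `HeritabilityModel` / `HeritabilityResults`: grid and Gibbs posterior engines, direct / reparameterized / null formulations |
| `pediherit.selection` | ΔDIC model selection (conditional and marginal deviance variants) |
| `pediherit.methylation` | beta ↔ M-value transforms, SNP-probe filtering, TSV I/O |
| `pediherit.scan` | per-site genome scan, genome-wide summaries, cross-time-point correlation |
| `pediherit.simulate` | synthetic pedigrees, covariates, traits and two-time-point methylomes with known truth |
| `pediherit.validation` | gene-dropping Monte Carlo oracle for kinship coefficients |
| `pediherit.cli` | `pediherit kinship / fit / preprocess / scan / simulate` |

## Worked example

```python
import pediherit as ph

# simulate a 50-family three-generation study with a 50%-heritable trait
config = ph.SimulationConfig(n_families=50, true_h2=0.5, seed=21)
ped = ph.simulate_pedigree(config)
kinship = ph.kinship_matrix(ped)
covariates = ph.simulate_covariates(ped, config.seed)
data, truth = ph.simulate_phenotype(ped, config, covariates=covariates,
                                    kinship=kinship)

model = ph.HeritabilityModel(data, kinship)
result = model.fit(engine="grid")
print(result.summary())

null = ph.HeritabilityModel(data, None, formulation="null").fit()
from pediherit.selection import compare_fits
sel = compare_fits(result, null)
print(f"\ndelta DIC = {sel.delta_dic:.1f}  -> genetic component "
      f"{'retained' if sel.selected else 'rejected'}")
```

Output:

```
Bayesian animal model fit
  formulation: direct    engine: grid
  n = 488
  h2 mode = 0.337   mean = 0.288   95% CrI = (0.000, 0.500)
  DIC (conditional) = 1268.24   pD = 118.69
  fixed effects (original scale):
    intercept    -0.3153  (sd 0.1147)
    age           0.0060  (sd 0.0018)
    gender        0.0975  (sd 0.0834)

delta DIC = 57.7  -> genetic component retained
```

The truth behind this dataset is h² = 0.5 with age and gender effects of
0.01/year and 0.1; the 95% credible interval covers it and the ΔDIC rule
retains the genetic component decisively. `result.plot_h2_posterior()` draws
the full h² posterior; `model.fit(engine="gibbs", seed=0)` cross-checks the
deterministic grid posterior with a blocked Gibbs sampler and returns the
retained draws in `result.samples`.

### Genome scan

```python
from pediherit.scan import scan, summarize, cross_timepoint
from pediherit.simulate import simulate_methylome

mats, truth = simulate_methylome(ped, config, covariates=covariates,
                                 kinship=kinship)      # two time points
results = scan(mats["pre"], kinship, covariates, seed=0)
print(summarize(results))                              # counts, medians, IQR
n_both, r = cross_timepoint(results,
                            scan(mats["post"], kinship, covariates, seed=1))
```

The same pipeline is available from the shell:

```bash
pediherit simulate --config sim.yaml --out-dir data/
pediherit preprocess --beta data/beta.tsv --exclude snp_probes.txt --out data/m.tsv
pediherit scan --m-values data/m_pre.tsv --ped data/ped.fam \
               --covar data/covar.tsv --out scan.tsv --summary summary.json
pediherit fit --ped data/ped.fam --pheno pheno.tsv --trait bmi
```

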