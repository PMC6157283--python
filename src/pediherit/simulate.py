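"""Synthetic pedigrees, covariates, traits and methylomes with known truth.

The generator emulates a family study of extended (three-generation)
pedigrees: per family, two grandparental couples, a father and mother who
are their offspring, and a sibship of grandchildren. Phenotypes follow the
animal model run generatively,

    y = X beta + u + e,   u ~ N(0, 2 sigma_g^2 K),   e ~ N(0, sigma_e^2 I),

with sigma_g^2 = h2 * total_variance and sigma_e^2 = (1 - h2) *
total_variance; since diag(2K) = 1 for non-inbred pedigrees, each
individual's genetic variance is exactly sigma_g^2 and the nominal h2 is
the realized one. Covariates are age (drawn per generation) and gender.

Methylomes are site-by-sample matrices of M-values whose per-site true h2
follows a zero-inflated right-skewed mixture: zero with probability pi0,
otherwise Beta(a, b) (defaults give mode 0.3). Two time points are coupled
through a Gaussian copula on the per-site mixture draws plus a shared
genetic white-noise vector, inducing a tunable cross-time-point correlation
of true (and hence estimated) h2.

All randomness descends from one master seed through named
``numpy.random.SeedSequence`` streams (master -> purpose -> site), so any
site or family is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import KinshipMatrix, kinship_matrix
from .methylation import MethylationMatrix
from .model import TraitData
from .pedigree import Individual, Pedigree

__all__ = ["SimulationConfig", "simulate_pedigree", "simulate_covariates",
           "simulate_phenotype", "simulate_methylome", "write_dataset"]

# age ranges (years) by generation depth: grandparents, parents, children
_AGE_RANGES = [(60.0, 80.0), (35.0, 55.0), (10.0, 30.0)]


def _stream(seed: int, *keys) -> np.random.Generator:
    """Named child RNG: deterministic function of (master seed, keys)."""
    ints = [seed] + [k if isinstance(k, int) else zlib.crc32(str(k).encode())
                     for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass
class SimulationConfig:
    """Generative truth for one synthetic dataset."""

    n_families: int = 50
    family_template: str = "three_generation_default"  # or "full_sib_pairs"
    mean_children: float = 3.0          # grandchildren ~ 1 + Poisson(mean - 1)... see below
    true_h2: float = 0.5
    total_variance: float = 1.0
    beta0: float = 0.0
    beta_age: float | None = None       # default 0.01 * sqrt(total_variance) per year
    beta_gender: float | None = None    # default 0.1 * sqrt(total_variance)
    zero_inflation_pi0: float = 0.05
    nonzero_h2_beta: tuple[float, float] = (2.5, 4.5)  # mode 0.3, right-skewed
    n_sites: int = 448
    timepoint_correlation: float = 0.6
    site_mean_range: tuple[float, float] = (-4.0, 4.0)  # baseline M-value per site
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.zero_inflation_pi0 <= 1:
            raise ValueError("zero_inflation_pi0 must be in [0, 1]")
        if not 0 <= self.timepoint_correlation <= 1:
            raise ValueError("timepoint_correlation must be in [0, 1]")
        if self.total_variance <= 0:
            raise ValueError("total_variance must be positive")
        if isinstance(self.true_h2, float) and not 0 <= self.true_h2 <= 1:
            raise ValueError("true_h2 must be in [0, 1]")

    @property
    def effect_age(self) -> float:
        sd = np.sqrt(self.total_variance)
        return 0.01 * sd if self.beta_age is None else self.beta_age

    @property
    def effect_gender(self) -> float:
        sd = np.sqrt(self.total_variance)
        return 0.1 * sd if self.beta_gender is None else self.beta_gender


# ----------------------------------------------------------------------
# pedigree
# ----------------------------------------------------------------------

def _three_generation_family(fam: str, rng: np.random.Generator) -> list[Individual]:
    """4 grandparents, 2 parents (one offspring of each grandparental couple),
    and 1 + Poisson(3) grandchildren: roughly 8-16 members."""
    gp = [Individual(f"{fam}_gp{k}", None, None,
                     "male" if k % 2 == 0 else "female", fam) for k in range(4)]
    father = Individual(f"{fam}_f", gp[0].id, gp[1].id, "male", fam)
    mother = Individual(f"{fam}_m", gp[2].id, gp[3].id, "female", fam)
    n_kids = 1 + rng.poisson(3)
    kids = [Individual(f"{fam}_c{k}", father.id, mother.id,
                       "male" if rng.random() < 0.5 else "female", fam)
            for k in range(n_kids)]
    return [*gp, father, mother, *kids]


def _full_sib_family(fam: str, rng: np.random.Generator) -> list[Individual]:
    """2 founder parents and exactly 2 full sibs (4 members)."""
    f = Individual(f"{fam}_f", None, None, "male", fam)
    m = Individual(f"{fam}_m", None, None, "female", fam)
    sibs = [Individual(f"{fam}_s{k}", f.id, m.id,
                       "male" if rng.random() < 0.5 else "female", fam)
            for k in range(2)]
    return [f, m, *sibs]


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Generate ``n_families`` independent families under the chosen template."""
    templates = {"three_generation_default": _three_generation_family,
                 "full_sib_pairs": _full_sib_family}
    if config.family_template not in templates:
        raise ValueError(f"unknown family template: {config.family_template!r}")
    make = templates[config.family_template]
    records: list[Individual] = []
    for k in range(config.n_families):
        rng = _stream(config.seed, "family", k)
        records.extend(make(f"F{k:04d}", rng))
    return Pedigree(records)


def simulate_covariates(ped: Pedigree, seed: int) -> pd.DataFrame:
    """Age (uniform within generation) and gender (from the pedigree) per individual."""
    rng = _stream(seed, "covariates")
    depth = ped.generation_depth()
    rows = []
    for rec in ped.records:
        lo, hi = _AGE_RANGES[min(depth[rec.id], len(_AGE_RANGES) - 1)]
        gender = {"male": 0, "female": 1}.get(rec.sex)
        if gender is None:
            gender = int(rng.random() < 0.5)
        rows.append({"id": rec.id, "age": rng.uniform(lo, hi), "gender": gender})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def _genetic_sqrt(K: KinshipMatrix) -> np.ndarray:
    """PSD square root of A = 2K via the cached eigendecomposition."""
    lam, U = K.eig()
    return U * np.sqrt(np.clip(lam, 0.0, None))[None, :]


def simulate_phenotype(ped: Pedigree, config: SimulationConfig,
                       covariates: pd.DataFrame | None = None,
                       kinship: KinshipMatrix | None = None,
                       key: str = "trait") -> tuple[TraitData, dict]:
    """Draw one trait under the animal model; returns (data, truth record).

    ``kinship``/``covariates`` may be passed to amortize across repeated
    draws on the same pedigree. ``key`` names the random stream so distinct
    traits/replicates on one pedigree are independent.
    """
    K = kinship if kinship is not None else kinship_matrix(ped)
    cov = covariates if covariates is not None else simulate_covariates(ped, config.seed)
    cov = cov.set_index("id").loc[ped.ids].reset_index()
    h2 = float(config.true_h2)
    sg2 = h2 * config.total_variance
    se2 = (1.0 - h2) * config.total_variance
    if np.any(np.abs(np.diag(K.relationship()) - 1.0) > 1e-9):
        import warnings
        warnings.warn("inbred pedigree: diag(2K) != 1, realized h2 differs from nominal")
    rng = _stream(config.seed, "phenotype", key)
    n = len(ped)
    u = np.sqrt(sg2) * (_genetic_sqrt(K) @ rng.standard_normal(n)) if sg2 > 0 else np.zeros(n)
    e = np.sqrt(se2) * rng.standard_normal(n)
    age = cov["age"].to_numpy()
    gender = cov["gender"].to_numpy(float)
    y = (config.beta0 + config.effect_age * (age - age.mean())
         + config.effect_gender * gender + u + e)
    X = np.column_stack([np.ones(n), age, gender])
    data = TraitData(y, X, ped.ids, covariate_names=["intercept", "age", "gender"])
    truth = {"true_h2": h2, "sigma_g_sq": sg2, "sigma_e_sq": se2, "u": u,
             "beta0": config.beta0, "beta_age": config.effect_age,
             "beta_gender": config.effect_gender}
    return data, truth


# ----------------------------------------------------------------------
# methylomes
# ----------------------------------------------------------------------

def _mixture_h2_pair(config: SimulationConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Zero-inflated Beta true-h2 pair for the two time points.

    A Gaussian copula with correlation ``timepoint_correlation`` couples the
    uniform draws feeding both the zero-inflation indicator and the Beta
    quantile, so rho=1 gives identical truths and rho=0 independent ones.
    """
    rho = config.timepoint_correlation
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]])
    uu = stats.norm.cdf(z)
    a, b = config.nonzero_h2_beta
    out = []
    for u in uu:
        if u < config.zero_inflation_pi0:
            out.append(0.0)
        else:
            q = (u - config.zero_inflation_pi0) / (1 - config.zero_inflation_pi0)
            out.append(float(stats.beta.ppf(q, a, b)))
    return tuple(out)


def simulate_methylome(ped: Pedigree, config: SimulationConfig,
                       covariates: pd.DataFrame | None = None,
                       kinship: KinshipMatrix | None = None,
                       ) -> tuple[dict[str, MethylationMatrix], pd.DataFrame]:
    """Two time points of site-by-sample M-values plus the per-site truth table.

    Each site's genetic standard-normal vector is shared across time points
    (scaled by each time point's own sigma_g), so correlated true h2
    produces correlated genetic values as well as correlated estimates.
    """
    K = kinship if kinship is not None else kinship_matrix(ped)
    cov = covariates if covariates is not None else simulate_covariates(ped, config.seed)
    cov = cov.set_index("id").loc[ped.ids].reset_index()
    age = cov["age"].to_numpy()
    gender = cov["gender"].to_numpy(float)
    fixed = (config.effect_age * (age - age.mean()) + config.effect_gender * gender)
    G = _genetic_sqrt(K)
    n = len(ped)
    site_ids = [f"cg{k:08d}" for k in range(config.n_sites)]
    mats = {tp: np.empty((config.n_sites, n)) for tp in ("pre", "post")}
    truth_rows = []
    for k, sid in enumerate(site_ids):
        rng = _stream(config.seed, "site", k)
        h2_pre, h2_post = _mixture_h2_pair(config, rng)
        mu_site = rng.uniform(*config.site_mean_range)
        z_gen = rng.standard_normal(n)        # shared genetic draw
        for tp, h2 in (("pre", h2_pre), ("post", h2_post)):
            sg2 = h2 * config.total_variance
            se2 = (1 - h2) * config.total_variance
            u = np.sqrt(sg2) * (G @ z_gen)
            e = np.sqrt(se2) * rng.standard_normal(n)
            mats[tp][k] = mu_site + fixed + u + e
        truth_rows.append({"site_id": sid, "true_h2_pre": h2_pre,
                           "true_h2_post": h2_post,
                           "nonzero_pre": h2_pre > 0, "nonzero_post": h2_post > 0})
    out = {tp: MethylationMatrix(site_ids, ped.ids, mats[tp], scale="M")
           for tp in ("pre", "post")}
    return out, pd.DataFrame(truth_rows)


# ----------------------------------------------------------------------
# file output
# ----------------------------------------------------------------------

def write_dataset(out_dir: str | Path, ped: Pedigree, covariates: pd.DataFrame,
                  methylomes: dict[str, MethylationMatrix] | None = None,
                  truth: pd.DataFrame | None = None) -> None:
    """Write ped.fam, covar.tsv and (optionally) m_<tp>.tsv + truth.tsv."""
    from .methylation import write_methylation_tsv
    from .pedigree import write_pedigree
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pedigree(ped, out / "ped.fam")
    covariates.to_csv(out / "covar.tsv", sep="\t", index=False)
    if methylomes:
        for tp, m in methylomes.items():
            write_methylation_tsv(m, out / f"m_{tp}.tsv")
    if truth is not None:
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
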