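"""Bayesian animal model for narrow-sense heritability.

The model for a quantitative trait (or one CpG site's M-values) on n
pedigree members is

    y_i | eta_i, sigma_e^2 ~ N(eta_i, sigma_e^2),
    eta_i = beta_0 + x_i' beta + u_i,
    u | sigma_g^2 ~ N(0, 2 sigma_g^2 K),

with K the pedigree kinship matrix, so A = 2K is the additive relationship
matrix and narrow-sense heritability is h^2 = sigma_g^2 / (sigma_g^2 +
sigma_e^2). Each variance component's precision gets a Gamma(1, 0.00005)
prior by default; fixed effects get vague independent Gaussians, which
keeps the marginal likelihood of the variances available in closed form.

Two posterior engines are provided:

* ``grid`` — deterministic evaluation of the joint posterior of
  (log sigma_g^2, log sigma_e^2) on a 2-D grid, normalized by the
  trapezoid rule; the h^2 posterior follows by the change of variables
  h^2 = sigma_g^2/(sigma_g^2 + sigma_e^2).
* ``gibbs`` — blocked conjugate Gibbs sampler alternating a joint Gaussian
  draw of (beta, u) with inverse-gamma draws of the two variances.

Three formulations:

* ``direct`` — the model above.
* ``reparameterized`` — observation variance fixed at a small nuisance
  sigma_0^2 (default 4.54e-5 = exp(-10)) with both u and a residual effect
  epsilon ~ N(0, sigma_e^2 I) latent; equivalent to ``direct`` up to
  O(sigma_0^2) and the formulation under which the full h^2 posterior is
  directly accessible in latent-Gaussian software.
* ``null`` — no genetic component (eta_i = beta_0 + x_i' beta), used as the
  comparison model for DIC selection.

All variance integration is on the log-variance scale with explicit
Jacobians. Likelihood evaluations use the cached eigendecomposition of A,
costing O(n p) per grid point after a one-time O(n^3) factorization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import gaussian_kde

from .kinship import KinshipMatrix

__all__ = [
    "PriorSpec", "TraitData", "GridSpec",
    "HeritabilityModel", "HeritabilityResults",
    "marginal_loglik", "fit_grid", "fit_gibbs", "fit_null",
    "fit_reparameterized", "h2_summary",
]

logger = logging.getLogger(__name__)

_EIG_CLIP = 1e-8  # relationship-matrix eigenvalues below this are treated as null space
DEFAULT_SIGMA0_SQ = 4.54e-5  # exp(-10), nuisance observation variance


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the animal model.

    Each variance component's *precision* 1/sigma^2 has a
    Gamma(precision_shape, precision_rate) prior (shape-rate
    parameterization; the default Gamma(1, 0.00005) is the conventional
    vague choice for latent Gaussian models). Fixed effects are iid
    N(0, fixed_effect_prior_sd^2) on standardized covariates.
    """

    precision_shape: float = 1.0
    precision_rate: float = 0.00005
    fixed_effect_prior_sd: float = 1000.0

    def __post_init__(self):
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ValueError("Gamma prior shape and rate must be positive")
        if self.fixed_effect_prior_sd <= 0:
            raise ValueError("fixed_effect_prior_sd must be positive")

    def log_variance_logpdf(self, log_var: np.ndarray) -> np.ndarray:
        """Log prior density of t = log sigma^2 implied by the Gamma precision prior.

        With lambda = exp(-t) ~ Gamma(a, b), the Jacobian |dlambda/dt| = lambda
        gives p(t) = b^a/Gamma(a) * lambda^a * exp(-b lambda).
        """
        a, b = self.precision_shape, self.precision_rate
        lam = np.exp(-np.asarray(log_var, dtype=float))
        return a * np.log(b) - gammaln(a) - a * np.asarray(log_var) - b * lam


@dataclass(frozen=True)
class GridSpec:
    """Log-variance grid for the deterministic engine."""

    log_var_min: float = -12.0
    log_var_max: float = 6.0
    n_points: int = 81
    h2_bins: int = 512
    boundary_mass_tol: float = 0.01

    def axis(self) -> np.ndarray:
        return np.linspace(self.log_var_min, self.log_var_max, self.n_points)

    def widened(self) -> "GridSpec":
        return GridSpec(self.log_var_min - 6.0, self.log_var_max + 6.0,
                        self.n_points, self.h2_bins, self.boundary_mass_tol)


class TraitData:
    """Outcome vector plus covariate matrix aligned to sample ids.

    ``X`` must include an intercept column (added automatically by
    :meth:`from_dataframe`). Rows with missing values are dropped with a
    logged count.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, sample_ids: list[str],
                 covariate_names: list[str] | None = None):
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size or len(sample_ids) != y.size:
            raise ValueError("y, X and sample_ids must have matching lengths")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError("y and X must be finite (drop missing rows first)")
        if y.size < X.shape[1] + 2:
            raise ValueError("need at least p + 2 observations")
        self.y = y
        self.X = X
        self.sample_ids = list(sample_ids)
        self.covariate_names = covariate_names or [f"x{j}" for j in range(X.shape[1])]

    @property
    def n(self) -> int:
        return self.y.size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trait: str,
                       covariates: tuple[str, ...] = ("age", "gender"),
                       id_col: str = "id") -> "TraitData":
        cols = [id_col, trait, *covariates]
        sub = df[cols].copy()
        n0 = len(sub)
        sub = sub.dropna()
        if len(sub) < n0:
            logger.info("dropped %d rows with missing trait/covariate values", n0 - len(sub))
        X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in covariates])
        return cls(sub[trait].to_numpy(float), X, sub[id_col].astype(str).tolist(),
                   covariate_names=["intercept", *covariates])


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale non-intercept columns; returns (Xs, means, sds)."""
    Xs = X.copy()
    p = X.shape[1]
    means = np.zeros(p)
    sds = np.ones(p)
    for j in range(1, p):
        mu, sd = X[:, j].mean(), X[:, j].std()
        means[j] = mu
        if sd > 0:
            sds[j] = sd
        Xs[:, j] = (X[:, j] - mu) / sds[j]
    return Xs, means, sds


def _beta_to_original_scale(mean_std: np.ndarray, cov_std: np.ndarray,
                            means: np.ndarray, sds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map posterior moments of beta from standardized to original covariates."""
    p = mean_std.size
    T = np.zeros((p, p))
    T[0, 0] = 1.0
    for j in range(1, p):
        T[0, j] = -means[j] / sds[j]
        T[j, j] = 1.0 / sds[j]
    return T @ mean_std, T @ cov_std @ T.T


class _BatchDesign:
    """y-independent pieces of the batched marginal likelihood.

    For a fixed diagonal covariance batch D (G, n) and design X, precomputes
    D^-1, log|D| and the Cholesky pieces of M = X' D^-1 X + I/tau^2, so that
    evaluating many outcome vectors against the same kinship/covariate
    design (a genome scan) costs only O(G n) per outcome.
    """

    def __init__(self, D: np.ndarray, Xt: np.ndarray, tau2: float):
        n, p = Xt.shape
        self.n, self.p, self.tau2 = n, p, tau2
        self.Xt = Xt
        self.Dinv = 1.0 / D
        self.logdetD = np.sum(np.log(D), axis=1)
        S = np.einsum("gn,ni,nj->gij", self.Dinv, Xt, Xt)  # (G, p, p)
        M = S + np.eye(p)[None] / tau2
        L = np.linalg.cholesky(M)
        self.logdetM = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
        self.Minv = np.linalg.inv(M)

    def loglike(self, yt: np.ndarray, return_beta: bool = False):
        yD = yt[None, :] * self.Dinv                  # (G, n)
        t_yy = yD @ yt                                # (G,)
        b = yD @ self.Xt                              # (G, p)
        Minv_b = np.einsum("gij,gj->gi", self.Minv, b)
        quad = t_yy - np.sum(b * Minv_b, axis=1)
        ll = -0.5 * (self.n * np.log(2 * np.pi) + self.logdetD + self.logdetM
                     + self.p * np.log(self.tau2) + quad)
        if not return_beta:
            return ll
        return ll, Minv_b, self.Minv


class HeritabilityModel:
    """Animal model for one trait on a pedigree.

    Parameters
    ----------
    data
        Trait values and covariates.
    kinship
        Kinship matrix covering at least ``data.sample_ids``. May be None
        only for the ``null`` formulation.
    priors
        Variance-precision and fixed-effect priors.
    formulation
        ``"direct"``, ``"reparameterized"`` or ``"null"``.
    sigma0_sq
        Fixed nuisance observation variance for the reparameterized
        formulation (default exp(-10) = 4.54e-5).
    dic_kind
        Deviance used for DIC: ``"conditional"`` (default; deviance of y
        given the latent field, the convention of latent-Gaussian software)
        or ``"marginal"`` (latent field and fixed effects integrated out,
        deviance a function of the variances only). Both are computed and
        stored on the results; this chooses which one ``results.dic``
        reports and selection consumes.
    """

    def __init__(self, data: TraitData, kinship: KinshipMatrix | None = None,
                 priors: PriorSpec | None = None, formulation: str = "direct",
                 sigma0_sq: float | None = None,
                 design_cache: dict | None = None,
                 dic_kind: str = "conditional"):
        if formulation not in ("direct", "reparameterized", "null"):
            raise ValueError(f"unknown formulation: {formulation!r}")
        if dic_kind not in ("conditional", "marginal"):
            raise ValueError(f"unknown dic_kind: {dic_kind!r}")
        self.dic_kind = dic_kind
        if formulation != "null" and kinship is None:
            raise ValueError("a kinship matrix is required unless formulation='null'")
        self.data = data
        self.priors = priors or PriorSpec()
        self.formulation = formulation
        self.warnings: list[str] = []
        if formulation == "reparameterized":
            self.sigma0_sq = DEFAULT_SIGMA0_SQ if sigma0_sq is None else float(sigma0_sq)
            if self.sigma0_sq <= 0:
                raise ValueError("sigma0_sq must be positive")
            if self.sigma0_sq >= 0.01 * np.var(data.y):
                self.warnings.append("sigma0_large: nuisance variance may absorb signal")
        else:
            self.sigma0_sq = 0.0
        if np.var(data.y) < 1e-12:
            self.warnings.append("degenerate_variance: outcome is (numerically) constant")

        Xs, self._x_means, self._x_sds = _standardize(data.X)
        if formulation == "null" or kinship is None:
            # no rotation needed: residual covariance is isotropic
            self._lam = np.ones(data.n)
            self._yt, self._Xt = data.y.copy(), Xs
        else:
            missing = [s for s in data.sample_ids if s not in kinship.ids]
            if missing:
                raise KeyError(f"samples absent from kinship matrix: {missing[:5]}")
            Ksub = kinship.subset(data.sample_ids) if kinship.ids != data.sample_ids else kinship
            lam, U = Ksub.eig()
            self._lam = lam
            self._yt = U.T @ data.y
            self._Xt = U.T @ Xs
        self._tau2 = self.priors.fixed_effect_prior_sd ** 2
        # shared across sites in a scan (same kinship, covariates, grid)
        self._design_cache = design_cache if design_cache is not None else {}

    # ------------------------------------------------------------------
    # marginal likelihood
    # ------------------------------------------------------------------
    def _diag_cov(self, sg2: np.ndarray, se2: np.ndarray) -> np.ndarray:
        """Diagonal (in the eigenbasis) part of the marginal covariance, (G, n)."""
        sg2 = np.atleast_1d(np.asarray(sg2, dtype=float))
        se2 = np.atleast_1d(np.asarray(se2, dtype=float))
        if self.formulation == "null":
            return se2[:, None] * np.ones_like(self._lam)[None, :] + self.sigma0_sq
        return sg2[:, None] * self._lam[None, :] + se2[:, None] + self.sigma0_sq

    def _loglike_batch(self, D: np.ndarray, return_beta: bool = False):
        """Gaussian marginal log-likelihood of y (u, epsilon and beta integrated out).

        ``D`` is the (G, n) diagonal of the covariance in the eigenbasis; the
        vague Gaussian prior on beta adds a rank-p term handled by the
        Woodbury identity, so each evaluation is O(n p^2).
        """
        return _BatchDesign(D, self._Xt, self._tau2).loglike(self._yt, return_beta)

    def loglike(self, log_sg2: float, log_se2: float) -> float:
        """Marginal log-likelihood log p(y | sigma_g^2, sigma_e^2).

        For the null formulation ``log_sg2`` is ignored (pass anything finite).
        """
        if not (np.isfinite(log_sg2) and np.isfinite(log_se2)):
            raise ValueError("log-variances must be finite")
        D = self._diag_cov(np.exp(log_sg2), np.exp(log_se2))
        return float(self._loglike_batch(D)[0])

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def fit(self, engine: str = "grid", grid: GridSpec | None = None,
            n_iter: int = 10_000, burn_in: int = 2_000,
            seed: int | None = None) -> "HeritabilityResults":
        if engine == "grid":
            return self._fit_grid(grid or GridSpec())
        if engine == "gibbs":
            if self.formulation == "null":
                raise ValueError("gibbs engine is not implemented for the null formulation")
            if seed is None:
                raise ValueError("gibbs engine requires an explicit seed")
            return self._fit_gibbs(n_iter=n_iter, burn_in=burn_in, seed=seed)
        raise ValueError(f"unknown engine: {engine!r}")

    # -- grid engine ----------------------------------------------------
    def _grid_eval(self, grid: GridSpec):
        axis = grid.axis()
        if self.formulation == "null":
            tg = np.zeros(1)
            te = axis
        else:
            tg = axis
            te = axis
        TG, TE = np.meshgrid(tg, te, indexing="ij")
        log_sg2, log_se2 = TG.ravel(), TE.ravel()
        key = (grid.log_var_min, grid.log_var_max, grid.n_points,
               self.formulation, self.sigma0_sq)
        entry = self._design_cache.get(key)
        if entry is None:
            D = self._diag_cov(np.exp(log_sg2), np.exp(log_se2))
            design = _BatchDesign(D, self._Xt, self._tau2)
            entry = {"design": design,
                     "cond": self._conditional_pieces(design, log_sg2, log_se2)}
            self._design_cache[key] = entry
        design, cond = entry["design"], entry["cond"]
        ll, beta_mean, beta_cov = design.loglike(self._yt, return_beta=True)
        lp = ll + self.priors.log_variance_logpdf(log_se2)
        if self.formulation != "null":
            lp = lp + self.priors.log_variance_logpdf(log_sg2)
        # trapezoid quadrature weights per axis
        def trap_w(ax):
            w = np.ones_like(ax)
            if ax.size > 1:
                w[0] = w[-1] = 0.5
            return w
        W = np.outer(trap_w(tg), trap_w(te)).ravel()
        w = W * np.exp(lp - lp.max())
        w /= w.sum()
        # mass on the outermost ring of the grid
        shape = (tg.size, te.size)
        mask = np.zeros(shape, dtype=bool)
        if self.formulation != "null":
            mask[0, :] = mask[-1, :] = True
        mask[:, 0] = mask[:, -1] = True
        boundary_mass = w[mask.ravel()].sum()
        return dict(log_sg2=log_sg2, log_se2=log_se2, loglik=ll, weights=w,
                    beta_mean=beta_mean, beta_cov=beta_cov, cond=cond,
                    boundary_mass=float(boundary_mass), grid=grid)

    def _latent_noise_split(self, sg2: np.ndarray, se2: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Per-coordinate latent prior variance d (G, n) and observation
        noise variance (G,) for the conditional deviance.

        The latent field is u (direct), u + epsilon (reparameterized) or
        empty (null); the observation noise is sigma_e^2 except under the
        reparameterized formulation, where it is the fixed sigma_0^2.
        """
        lam = self._lam[None, :]
        if self.formulation == "direct":
            return sg2[:, None] * lam, se2
        if self.formulation == "reparameterized":
            return sg2[:, None] * lam + se2[:, None], np.full_like(se2, self.sigma0_sq)
        return np.zeros((se2.size, lam.size)), se2

    def _conditional_pieces(self, design: "_BatchDesign",
                            log_sg2: np.ndarray, log_se2: np.ndarray) -> dict:
        """y-independent ingredients of the conditional deviance.

        Given the variances, the latent contribution to the fit is a
        per-coordinate shrinkage k = d/(d + noise) of the residual toward
        the data, with conditional variance v = d*noise/(d + noise); q is
        the predictive variance of the fixed-effect part x' beta.
        """
        d, noise = self._latent_noise_split(np.exp(log_sg2), np.exp(log_se2))
        tot = d + noise[:, None]
        k = d / tot
        v_sum = (d * noise[:, None] / tot).sum(axis=1)
        q = np.einsum("ni,gij,nj->gn", design.Xt, design.Minv, design.Xt)
        return {"k": k, "v_sum": v_sum, "q": q, "noise": noise}

    def _conditional_dic_grid(self, g: dict) -> tuple[float, float]:
        """(DIC, pD) on the conditional deviance, by grid quadrature."""
        cond, w = g["cond"], g["weights"]
        yt, n = self._yt, self._yt.size
        k, q, v_sum, noise = cond["k"], cond["q"], cond["v_sum"], cond["noise"]
        Xmu = g["beta_mean"] @ self._Xt.T                      # (G, n)
        r = yt[None, :] - Xmu
        one_mk2 = (1.0 - k) ** 2
        equad = v_sum + np.sum(one_mk2 * (r ** 2 + q), axis=1)
        d_bar = float(w @ (n * np.log(2 * np.pi * noise) + equad / noise))
        m_bar = ((w[:, None] * (1 - k)) * Xmu).sum(axis=0) + (w @ k) * yt
        noise_bar = float(np.exp(w @ np.log(noise)))
        d_hat = n * np.log(2 * np.pi * noise_bar) + np.sum((yt - m_bar) ** 2) / noise_bar
        p_d = d_bar - d_hat
        return d_bar + p_d, p_d

    def _fit_grid(self, grid: GridSpec) -> "HeritabilityResults":
        g = self._grid_eval(grid)
        warnings = list(self.warnings)
        if g["boundary_mass"] > grid.boundary_mass_tol:
            g = self._grid_eval(grid.widened())
            if g["boundary_mass"] > grid.boundary_mass_tol:
                warnings.append("grid_boundary: >1% posterior mass on grid edge")
        w = g["weights"]
        # beta posterior: mixture over grid cells
        mu, cov = g["beta_mean"], g["beta_cov"]
        b_mean = w @ mu
        b_second = np.einsum("g,gij->ij", w, cov + np.einsum("gi,gj->gij", mu, mu))
        b_cov = b_second - np.outer(b_mean, b_mean)
        b_mean, b_cov = _beta_to_original_scale(b_mean, b_cov, self._x_means, self._x_sds)

        # marginal-deviance DIC; theta_bar on the log-variance scale
        dev = -2.0 * g["loglik"]
        d_bar = float(w @ dev)
        if self.formulation == "null":
            theta_bar = (None, float(w @ g["log_se2"]))
            ll_bar = self.loglike(0.0, theta_bar[1])
        else:
            theta_bar = (float(w @ g["log_sg2"]), float(w @ g["log_se2"]))
            ll_bar = self.loglike(*theta_bar)
        d_hat = -2.0 * ll_bar
        p_d_marg = d_bar - d_hat
        dic_marg = d_bar + p_d_marg
        dic_cond, p_d_cond = self._conditional_dic_grid(g)
        dic, p_d = ((dic_cond, p_d_cond) if self.dic_kind == "conditional"
                    else (dic_marg, p_d_marg))

        if self.formulation == "null":
            h2_mode = h2_mean = h2_ci = None
            se2_post = _weighted_summary(np.exp(g["log_se2"]), w)
        else:
            sg2 = np.exp(g["log_sg2"])
            se2 = np.exp(g["log_se2"])
            h2 = sg2 / (sg2 + se2)
            h2_mode = _weighted_hist_mode(h2, w, grid.h2_bins)
            h2_mean = float(w @ h2)
            h2_ci = _weighted_quantiles(h2, w, (0.025, 0.975))
            se2_post = _weighted_summary(se2, w)

        return HeritabilityResults(
            model=self, engine="grid", formulation=self.formulation,
            h2_mode=h2_mode, h2_mean=h2_mean, h2_ci95=h2_ci,
            beta_mean=b_mean, beta_cov=b_cov,
            dic=float(dic), p_d=float(p_d), dic_kind=self.dic_kind,
            dic_marginal=float(dic_marg), p_d_marginal=float(p_d_marg),
            dic_conditional=float(dic_cond), p_d_conditional=float(p_d_cond),
            theta_bar=theta_bar, sigma_e_sq_summary=se2_post,
            grid_representation=g, warnings=warnings,
        )

    # -- Gibbs engine -----------------------------------------------------
    def _fit_gibbs(self, n_iter: int, burn_in: int, seed: int) -> "HeritabilityResults":
        rng = np.random.default_rng(seed)
        yt, Xt, tau2 = self._yt, self._Xt, self._tau2
        n, p = Xt.shape
        lam = self._lam
        active = lam > _EIG_CLIP   # null space of A carries no genetic variance
        n_eff = int(active.sum())
        a0, b0 = self.priors.precision_shape, self.priors.precision_rate
        reparam = self.formulation == "reparameterized"
        s0 = self.sigma0_sq

        sg2, se2 = np.var(yt) / 2 + 1e-6, np.var(yt) / 2 + 1e-6
        a = np.zeros(n)        # genetic effect in the eigenbasis
        eps = np.zeros(n)      # iid residual effect (reparameterized only)
        keep = n_iter
        out = np.empty((keep, 2 + p))
        dev_c_sum = 0.0
        f_sum = np.zeros(n)  # running mean of the fitted latent field
        for it in range(burn_in + keep):
            # (beta, u) joint block: beta from its variance-marginal
            # conditional, then u | beta — together one Gaussian block draw
            D = sg2 * lam + se2 + s0
            Dinv = 1.0 / D
            M = Xt.T @ (Xt * Dinv[:, None]) + np.eye(p) / tau2
            L = np.linalg.cholesky(M)
            mu = np.linalg.solve(M, Xt.T @ (yt * Dinv))
            beta = mu + np.linalg.solve(L.T, rng.standard_normal(p))
            r = yt - Xt @ beta
            if not reparam:
                v = np.zeros(n)
                v[active] = 1.0 / (1.0 / (sg2 * lam[active]) + 1.0 / se2)
                a = v * r / se2 + np.sqrt(v) * rng.standard_normal(n)
                resid = r - a
                rate_e = b0 + 0.5 * np.sum(resid ** 2)
                shape_e = a0 + 0.5 * n
            else:
                # joint 2x2 Gaussian draw of (a_i, eps_i) given beta
                lam_safe = np.where(active, lam, 1.0)
                pa = 1.0 / (sg2 * lam_safe)
                pe = 1.0 / se2
                p0 = 1.0 / s0
                det = (pa + p0) * (pe + p0) - p0 ** 2
                # posterior covariance entries; a_i pinned at 0 in the null space
                caa = np.where(active, (pe + p0) / det, 0.0)
                cae = np.where(active, -p0 / det, 0.0)
                cee = np.where(active, (pa + p0) / det, 1.0 / (pe + p0))
                ma = (caa + cae) * p0 * r
                me = (cae + cee) * p0 * r
                z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
                laa = np.sqrt(caa)
                lea = np.where(caa > 0, cae / np.where(caa > 0, laa, 1.0), 0.0)
                lee = np.sqrt(np.clip(cee - lea ** 2, 0.0, None))
                a = ma + laa * z1
                eps = me + lea * z1 + lee * z2
                rate_e = b0 + 0.5 * np.sum(eps ** 2)
                shape_e = a0 + 0.5 * n
            quad_g = np.sum(a[active] ** 2 / lam[active])
            sg2 = 1.0 / rng.gamma(a0 + 0.5 * n_eff, 1.0 / (b0 + 0.5 * quad_g))
            se2 = 1.0 / rng.gamma(shape_e, 1.0 / rate_e)
            if it >= burn_in:
                out[it - burn_in, 0] = sg2
                out[it - burn_in, 1] = se2
                out[it - burn_in, 2:] = beta
                if reparam:
                    resid0 = r - a - eps
                    dev_c_sum += n * np.log(2 * np.pi * s0) + np.sum(resid0 ** 2) / s0
                    f_sum += yt - resid0
                else:
                    resid0 = r - a
                    dev_c_sum += n * np.log(2 * np.pi * se2) + np.sum(resid0 ** 2) / se2
                    f_sum += yt - resid0

        sg2_s, se2_s, beta_s = out[:, 0], out[:, 1], out[:, 2:]
        h2_s = sg2_s / (sg2_s + se2_s)
        warnings = list(self.warnings)
        ess = _ess(h2_s)
        if ess < 100:
            warnings.append(f"low_ess: effective sample size for h2 is {ess:.0f}")
        b_mean_std = beta_s.mean(axis=0)
        b_cov_std = np.atleast_2d(np.cov(beta_s.T)).reshape(p, p)
        b_mean, b_cov = _beta_to_original_scale(b_mean_std, b_cov_std,
                                                self._x_means, self._x_sds)
        theta_bar = (float(np.mean(np.log(sg2_s))), float(np.mean(np.log(se2_s))))
        dev = -2.0 * self._loglike_batch(self._diag_cov(sg2_s, se2_s))
        d_bar = float(dev.mean())
        d_hat = -2.0 * self.loglike(*theta_bar)
        p_d_marg = d_bar - d_hat
        dic_marg = d_bar + p_d_marg
        # conditional-deviance DIC from the same draws
        noise_bar = s0 if reparam else float(np.exp(np.mean(np.log(se2_s))))
        d_bar_c = dev_c_sum / keep
        m_bar = f_sum / keep
        d_hat_c = n * np.log(2 * np.pi * noise_bar) + np.sum((yt - m_bar) ** 2) / noise_bar
        p_d_cond = d_bar_c - d_hat_c
        dic_cond = d_bar_c + p_d_cond
        dic, p_d = ((dic_cond, p_d_cond) if self.dic_kind == "conditional"
                    else (dic_marg, p_d_marg))
        samples = pd.DataFrame({"sigma_g_sq": sg2_s, "sigma_e_sq": se2_s, "h2": h2_s})
        lo, hi = np.quantile(h2_s, [0.025, 0.975])
        return HeritabilityResults(
            model=self, engine="gibbs", formulation=self.formulation,
            h2_mode=_kde_mode(h2_s), h2_mean=float(h2_s.mean()), h2_ci95=(float(lo), float(hi)),
            beta_mean=b_mean, beta_cov=b_cov,
            dic=float(dic), p_d=float(p_d), dic_kind=self.dic_kind,
            dic_marginal=float(dic_marg), p_d_marginal=float(p_d_marg),
            dic_conditional=float(dic_cond), p_d_conditional=float(p_d_cond),
            theta_bar=theta_bar,
            sigma_e_sq_summary=_sample_summary(se2_s),
            samples=samples, ess_h2=float(ess), warnings=warnings, seed=seed,
        )


# ----------------------------------------------------------------------
# posterior summaries
# ----------------------------------------------------------------------

def _weighted_quantiles(x: np.ndarray, w: np.ndarray, qs) -> tuple[float, ...]:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return tuple(float(np.interp(q, cw, x[order])) for q in qs)


def _weighted_hist_mode(h2: np.ndarray, w: np.ndarray, bins: int) -> float:
    hist, edges = np.histogram(h2, bins=bins, range=(0.0, 1.0), weights=w)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def _weighted_summary(x: np.ndarray, w: np.ndarray) -> dict:
    lo, med, hi = _weighted_quantiles(x, w, (0.025, 0.5, 0.975))
    return {"mean": float(w @ x), "median": med, "ci95": (lo, hi),
            "mode_log": float(np.exp(w @ np.log(x)))}


def _sample_summary(x: np.ndarray) -> dict:
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return {"mean": float(x.mean()), "median": float(med),
            "ci95": (float(lo), float(hi)),
            "mode_log": float(np.exp(np.mean(np.log(x))))}


def _kde_mode(samples: np.ndarray, n_grid: int = 512) -> float:
    if np.ptp(samples) < 1e-12:
        return float(samples[0])
    kde = gaussian_kde(samples)
    grid = np.linspace(0.0, 1.0, n_grid)
    return float(grid[int(np.argmax(kde(grid)))])


def _ess(x: np.ndarray) -> float:
    """Effective sample size via arviz (falls back to n on failure)."""
    try:
        import arviz as az
        return float(az.ess(np.asarray(x)[None, :]))
    except Exception:  # pragma: no cover
        return float(len(x))


@dataclass
class HeritabilityResults:
    """Posterior summaries from a fitted animal model.

    ``h2_*`` fields are None for null fits. ``dic`` uses the marginal
    (u- and beta-integrated) deviance with the posterior mean of the
    log-variances as the plug-in point.
    """

    model: HeritabilityModel
    engine: str
    formulation: str
    h2_mode: float | None
    h2_mean: float | None
    h2_ci95: tuple[float, float] | None
    beta_mean: np.ndarray
    beta_cov: np.ndarray
    dic: float
    p_d: float
    theta_bar: tuple[float | None, float]
    sigma_e_sq_summary: dict
    dic_kind: str = "conditional"
    dic_marginal: float | None = None
    p_d_marginal: float | None = None
    dic_conditional: float | None = None
    p_d_conditional: float | None = None
    grid_representation: dict | None = None
    samples: pd.DataFrame | None = None
    ess_h2: float | None = None
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def beta_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))

    def h2_summary(self) -> tuple[float, float, tuple[float, float]]:
        """(mode, mean, equal-tailed 95% credible interval) of h^2."""
        if self.formulation == "null":
            raise ValueError("h2 is not defined for the null model (no genetic component)")
        return self.h2_mode, self.h2_mean, self.h2_ci95

    def beta_summary(self) -> pd.DataFrame:
        names = self.model.data.covariate_names
        return pd.DataFrame({"mean": self.beta_mean, "sd": self.beta_sd}, index=names)

    def h2_posterior_density(self, bins: int = 512) -> tuple[np.ndarray, np.ndarray]:
        """(bin centers, density) of the marginal h^2 posterior."""
        if self.formulation == "null":
            raise ValueError("h2 is not defined for the null model")
        if self.samples is not None:
            hist, edges = np.histogram(self.samples["h2"], bins=bins,
                                       range=(0, 1), density=True)
        else:
            g = self.grid_representation
            sg2, se2 = np.exp(g["log_sg2"]), np.exp(g["log_se2"])
            h2 = sg2 / (sg2 + se2)
            hist, edges = np.histogram(h2, bins=bins, range=(0, 1),
                                       weights=g["weights"], density=True)
        return 0.5 * (edges[:-1] + edges[1:]), hist

    def plot_h2_posterior(self, ax=None):
        """Plot the marginal posterior density of h^2."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        centers, dens = self.h2_posterior_density()
        ax.plot(centers, dens)
        ax.axvline(self.h2_mode, ls="--", color="C1", label=f"mode = {self.h2_mode:.2f}")
        lo, hi = self.h2_ci95
        ax.axvspan(lo, hi, alpha=0.15, color="C0", label="95% CrI")
        ax.set_xlabel(r"$h^2$")
        ax.set_ylabel("posterior density")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Bayesian animal model fit",
            f"  formulation: {self.formulation}    engine: {self.engine}",
            f"  n = {self.model.data.n}",
        ]
        if self.formulation != "null":
            lo, hi = self.h2_ci95
            lines.append(f"  h2 mode = {self.h2_mode:.3f}   mean = {self.h2_mean:.3f}"
                         f"   95% CrI = ({lo:.3f}, {hi:.3f})")
        lines.append(f"  DIC ({self.dic_kind}) = {self.dic:.2f}   pD = {self.p_d:.2f}")
        lines.append("  fixed effects (original scale):")
        for name, m, s in zip(self.model.data.covariate_names, self.beta_mean, self.beta_sd):
            lines.append(f"    {name:<12} {m:> .4f}  (sd {s:.4f})")
        if self.warnings:
            lines.append("  warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "formulation": self.formulation, "engine": self.engine,
            "n": self.model.data.n,
            "h2_mode": self.h2_mode, "h2_mean": self.h2_mean,
            "h2_ci95": list(self.h2_ci95) if self.h2_ci95 else None,
            "beta": {n: {"mean": float(m), "sd": float(s)}
                     for n, m, s in zip(self.model.data.covariate_names,
                                        self.beta_mean, self.beta_sd)},
            "dic": self.dic, "p_d": self.p_d, "dic_kind": self.dic_kind,
            "dic_marginal": self.dic_marginal, "p_d_marginal": self.p_d_marginal,
            "dic_conditional": self.dic_conditional, "p_d_conditional": self.p_d_conditional,
            "warnings": self.warnings, "seed": self.seed,
        }
        if self.ess_h2 is not None:
            d["ess_h2"] = self.ess_h2
        return d


# ----------------------------------------------------------------------
# functional conveniences mirroring the Model/Results API
# ----------------------------------------------------------------------

def marginal_loglik(log_sg2: float, log_se2: float, data: TraitData,
                    kinship: KinshipMatrix, priors: PriorSpec | None = None) -> float:
    """Marginal log-likelihood of the direct animal model at given log-variances."""
    return HeritabilityModel(data, kinship, priors).loglike(log_sg2, log_se2)


def fit_grid(data: TraitData, kinship: KinshipMatrix,
             priors: PriorSpec | None = None,
             grid: GridSpec | None = None) -> HeritabilityResults:
    return HeritabilityModel(data, kinship, priors).fit(engine="grid", grid=grid)


def fit_gibbs(data: TraitData, kinship: KinshipMatrix,
              priors: PriorSpec | None = None, n_iter: int = 10_000,
              burn_in: int = 2_000, seed: int | None = None) -> HeritabilityResults:
    return HeritabilityModel(data, kinship, priors).fit(
        engine="gibbs", n_iter=n_iter, burn_in=burn_in, seed=seed)


def fit_null(data: TraitData, priors: PriorSpec | None = None,
             grid: GridSpec | None = None) -> HeritabilityResults:
    return HeritabilityModel(data, None, priors, formulation="null").fit(
        engine="grid", grid=grid)


def fit_reparameterized(data: TraitData, kinship: KinshipMatrix,
                        priors: PriorSpec | None = None,
                        sigma0_sq: float = DEFAULT_SIGMA0_SQ,
                        engine: str = "grid", seed: int | None = None,
                        **kwargs) -> HeritabilityResults:
    model = HeritabilityModel(data, kinship, priors,
                              formulation="reparameterized", sigma0_sq=sigma0_sq)
    return model.fit(engine=engine, seed=seed, **kwargs)


def h2_summary(fit: HeritabilityResults) -> tuple[float, float, tuple[float, float]]:
    return fit.h2_summary()
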