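import numpy as np
import pytest
from scipy import stats

import pediherit as ph
from pediherit.model import _standardize
from conftest import make_trait


# ----------------------------------------------------------------------
# priors
# ----------------------------------------------------------------------

def test_log_variance_prior_matches_gamma_change_of_variables():
    pr = ph.PriorSpec(precision_shape=1.3, precision_rate=0.02)
    t = np.linspace(-8, 4, 25)
    lam = np.exp(-t)
    # p(t) = Gamma(lam; a, rate b) * |dlam/dt| with |dlam/dt| = lam
    expected = stats.gamma.logpdf(lam, a=1.3, scale=1 / 0.02) + np.log(lam)
    np.testing.assert_allclose(pr.log_variance_logpdf(t), expected, atol=1e-10)


def test_log_variance_prior_integrates_to_one():
    pr = ph.PriorSpec()
    t = np.linspace(-40, 25, 20001)
    total = np.trapezoid(np.exp(pr.log_variance_logpdf(t)), t)
    assert total == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("kwargs", [
    dict(precision_shape=-1), dict(precision_rate=0), dict(fixed_effect_prior_sd=0)])
def test_prior_validation(kwargs):
    with pytest.raises(ValueError):
        ph.PriorSpec(**kwargs)


# ----------------------------------------------------------------------
# marginal likelihood
# ----------------------------------------------------------------------

def test_marginal_loglik_matches_dense_mvn_oracle(small_study):
    """Eigenbasis/Woodbury route vs direct dense multivariate normal."""
    data, K = small_study["data"], small_study["K"]
    priors = ph.PriorSpec(fixed_effect_prior_sd=10.0)
    model = ph.HeritabilityModel(data, K, priors)
    A = K.subset(data.sample_ids).relationship()
    Xs, _, _ = _standardize(data.X)
    rng = np.random.default_rng(5)
    for _ in range(20):
        tg, te = rng.uniform(-4, 2, size=2)
        V = np.exp(tg) * A + np.exp(te) * np.eye(data.n) + 100.0 * Xs @ Xs.T
        oracle = stats.multivariate_normal.logpdf(data.y, mean=np.zeros(data.n), cov=V)
        assert model.loglike(tg, te) == pytest.approx(oracle, abs=1e-8)


def test_zero_genetic_variance_limit_matches_null_model(small_study):
    data = small_study["data"]
    genetic = ph.HeritabilityModel(data, small_study["K"])
    null = ph.HeritabilityModel(data, None, formulation="null")
    assert genetic.loglike(-35.0, 0.3) == pytest.approx(null.loglike(0.0, 0.3), abs=1e-8)


def test_loglike_rejects_nonfinite_arguments(small_study):
    model = ph.HeritabilityModel(small_study["data"], small_study["K"])
    with pytest.raises(ValueError):
        model.loglike(np.inf, 0.0)


# ----------------------------------------------------------------------
# grid engine
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def grid_fit(three_gen):
    data, _ = make_trait(three_gen, 0.5, "modeltest")
    model = ph.HeritabilityModel(data, three_gen["K"],
                                 design_cache=three_gen["cache"])
    return data, model.fit(engine="grid")


def test_grid_fit_recovers_h2(grid_fit):
    _, res = grid_fit
    mode, mean, (lo, hi) = res.h2_summary()
    assert abs(mean - 0.5) < 0.15
    assert lo < 0.5 < hi
    assert 0 <= lo < hi <= 1


def test_grid_fit_recovers_fixed_effects(grid_fit):
    _, res = grid_fit
    beta = res.beta_summary()
    # generative effects: 0.01/year for age, 0.1 for gender
    assert abs(beta.loc["age", "mean"] - 0.01) < 3 * beta.loc["age", "sd"]
    assert abs(beta.loc["gender", "mean"] - 0.1) < 3 * beta.loc["gender", "sd"]


def test_posterior_density_normalized(grid_fit):
    _, res = grid_fit
    centers, dens = res.h2_posterior_density()
    assert np.trapezoid(dens, centers) == pytest.approx(1.0, abs=0.01)


def test_location_shift_leaves_h2_posterior_invariant(three_gen):
    """Adding a constant to y only moves the intercept."""
    data, _ = make_trait(three_gen, 0.5, "shift")
    shifted = ph.TraitData(data.y + 37.5, data.X, data.sample_ids)
    r1 = ph.HeritabilityModel(data, three_gen["K"], design_cache=three_gen["cache"]).fit()
    r2 = ph.HeritabilityModel(shifted, three_gen["K"], design_cache=three_gen["cache"]).fit()
    assert r2.h2_mode == pytest.approx(r1.h2_mode, abs=1e-6)
    assert r2.h2_mean == pytest.approx(r1.h2_mean, abs=1e-6)
    assert r2.beta_mean[0] == pytest.approx(r1.beta_mean[0] + 37.5, rel=1e-3)


def test_grid_widens_when_posterior_leaves_default_range(three_gen):
    """A tiny-variance outcome concentrates below the default grid floor;
    the engine must widen rather than silently truncate."""
    data, _ = make_trait(three_gen, 0.5, "scalecheck")
    tiny = ph.TraitData(data.y * 1e-4, data.X, data.sample_ids)
    res = ph.HeritabilityModel(tiny, three_gen["K"], design_cache=three_gen["cache"]).fit()
    g = res.grid_representation["grid"]
    assert g.log_var_min < ph.GridSpec().log_var_min
    assert res.grid_representation["boundary_mass"] <= 0.01


def test_scale_equivariance_of_h2(three_gen):
    """h2 is a variance ratio: rescaling y leaves its posterior unchanged."""
    data, _ = make_trait(three_gen, 0.5, "scalecheck")
    scaled = ph.TraitData(data.y * 3.0, data.X, data.sample_ids)
    r1 = ph.HeritabilityModel(data, three_gen["K"], design_cache=three_gen["cache"]).fit()
    r2 = ph.HeritabilityModel(scaled, three_gen["K"], design_cache=three_gen["cache"]).fit()
    # prior on the variances is not scale-free, so allow small movement
    assert abs(r2.h2_mean - r1.h2_mean) < 0.03


def test_agreement_with_sib_pair_anova_oracle():
    """On full-sib pairs, h2 ~ 2 * intraclass correlation of OLS residuals —
    a model-free oracle. Both estimators are averaged over 10 replicate
    traits on one 400-member pedigree to beat down their sampling noise."""
    cfg = ph.SimulationConfig(n_families=100, family_template="full_sib_pairs",
                              true_h2=0.5, seed=15)
    ped = ph.simulate_pedigree(cfg)
    K = ph.kinship_matrix(ped)
    cov = ph.simulate_covariates(ped, cfg.seed)
    cache = {}
    anova, post = [], []
    for rep in range(10):
        data, _ = ph.simulate_phenotype(ped, cfg, covariates=cov, kinship=K,
                                        key=f"sib{rep}")
        beta = np.linalg.lstsq(data.X, data.y, rcond=None)[0]
        r = data.y - data.X @ beta
        idx = {s: i for i, s in enumerate(data.sample_ids)}
        pairs = np.array([(r[idx[f"F{k:04d}_s0"]], r[idx[f"F{k:04d}_s1"]])
                          for k in range(100)])
        x = np.concatenate([pairs[:, 0], pairs[:, 1]])
        y = np.concatenate([pairs[:, 1], pairs[:, 0]])
        anova.append(2.0 * np.corrcoef(x, y)[0, 1])
        post.append(ph.HeritabilityModel(data, K, design_cache=cache).fit().h2_mean)
    assert abs(np.mean(anova) - np.mean(post)) < 0.1
    assert abs(np.mean(post) - 0.5) < 0.12


# ----------------------------------------------------------------------
# Gibbs engine
# ----------------------------------------------------------------------

def test_gibbs_agrees_with_grid(three_gen):
    data, _ = make_trait(three_gen, 0.5, "gibbscmp")
    model = ph.HeritabilityModel(data, three_gen["K"], design_cache=three_gen["cache"])
    rg = model.fit(engine="grid")
    rs = model.fit(engine="gibbs", seed=7)
    assert abs(rs.h2_mean - rg.h2_mean) < 0.03
    assert rs.ess_h2 > 100
    assert abs(rs.h2_ci95[0] - rg.h2_ci95[0]) < 0.08
    assert abs(rs.h2_ci95[1] - rg.h2_ci95[1]) < 0.08


def test_gibbs_is_reproducible_and_requires_seed(three_gen):
    data, _ = make_trait(three_gen, 0.5, "gibbscmp")
    model = ph.HeritabilityModel(data, three_gen["K"], design_cache=three_gen["cache"])
    r1 = model.fit(engine="gibbs", n_iter=500, burn_in=100, seed=3)
    r2 = model.fit(engine="gibbs", n_iter=500, burn_in=100, seed=3)
    assert r1.h2_mean == r2.h2_mean
    with pytest.raises(ValueError, match="seed"):
        model.fit(engine="gibbs")


# ----------------------------------------------------------------------
# reparameterized formulation
# ----------------------------------------------------------------------

def test_reparameterized_matches_direct(three_gen):
    data, _ = make_trait(three_gen, 0.5, "reparam")
    cache = three_gen["cache"]
    direct = ph.HeritabilityModel(data, three_gen["K"], design_cache=cache).fit()
    rep = ph.HeritabilityModel(data, three_gen["K"], formulation="reparameterized",
                               design_cache=cache).fit()
    assert abs(rep.h2_mode - direct.h2_mode) < 0.02
    assert abs(rep.h2_mean - direct.h2_mean) < 0.02


def test_reparameterized_default_nuisance_variance():
    assert ph.DEFAULT_SIGMA0_SQ == pytest.approx(np.exp(-10.0), rel=1e-2)


def test_large_nuisance_variance_warns(three_gen):
    data, _ = make_trait(three_gen, 0.5, "reparam")
    model = ph.HeritabilityModel(data, three_gen["K"], formulation="reparameterized",
                                 sigma0_sq=np.var(data.y))
    assert any(w.startswith("sigma0_large") for w in model.warnings)


# ----------------------------------------------------------------------
# null formulation & API
# ----------------------------------------------------------------------

def test_null_model_has_no_h2(three_gen):
    data, _ = make_trait(three_gen, 0.5, "nullfit")
    res = ph.fit_null(data)
    assert res.h2_mode is None
    with pytest.raises(ValueError, match="null"):
        res.h2_summary()


def test_functional_wrappers_match_methods(three_gen):
    data, _ = make_trait(three_gen, 0.5, "wrapper")
    via_fn = ph.fit_grid(data, three_gen["K"])
    via_obj = ph.HeritabilityModel(data, three_gen["K"]).fit(engine="grid")
    assert via_fn.h2_mode == via_obj.h2_mode
    assert ph.h2_summary(via_fn) == via_fn.h2_summary()
    ll = ph.marginal_loglik(-1.0, -1.0, data, three_gen["K"])
    assert ll == pytest.approx(
        ph.HeritabilityModel(data, three_gen["K"]).loglike(-1.0, -1.0))


def test_invalid_construction_rejected(three_gen):
    data, _ = make_trait(three_gen, 0.5, "wrapper")
    with pytest.raises(ValueError, match="formulation"):
        ph.HeritabilityModel(data, three_gen["K"], formulation="bogus")
    with pytest.raises(ValueError, match="kinship"):
        ph.HeritabilityModel(data, None, formulation="direct")
    with pytest.raises(ValueError, match="dic_kind"):
        ph.HeritabilityModel(data, three_gen["K"], dic_kind="bogus")
    with pytest.raises(ValueError, match="engine"):
        ph.HeritabilityModel(data, three_gen["K"]).fit(engine="vb")


def test_samples_missing_from_kinship_raise(three_gen):
    data, _ = make_trait(three_gen, 0.5, "wrapper")
    bad = ph.TraitData(data.y, data.X, ["ghost" + s for s in data.sample_ids])
    with pytest.raises(KeyError, match="absent"):
        ph.HeritabilityModel(bad, three_gen["K"])


def test_trait_data_validation():
    with pytest.raises(ValueError, match="finite"):
        ph.TraitData([1.0, np.nan, 2.0, 3.0], np.ones((4, 1)), list("abcd"))
    with pytest.raises(ValueError, match="matching"):
        ph.TraitData([1.0, 2.0], np.ones((3, 1)), list("ab"))
    with pytest.raises(ValueError, match="observations"):
        ph.TraitData([1.0, 2.0], np.ones((2, 1)), list("ab"))


def test_summary_text_mentions_key_quantities(grid_fit):
    _, res = grid_fit
    text = res.summary()
    assert "h2 mode" in text and "DIC" in text and "age" in text
    d = res.to_dict()
    assert set(d) >= {"h2_mode", "dic", "dic_marginal", "dic_conditional", "beta"}
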