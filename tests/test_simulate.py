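import numpy as np
import pytest

import pediherit as ph
from pediherit.simulate import simulate_methylome


def test_three_generation_family_structure():
    cfg = ph.SimulationConfig(n_families=10, seed=2)
    ped = ph.simulate_pedigree(cfg)
    fams = {rec.family for rec in ped.records}
    assert len(fams) == 10
    depth = ped.generation_depth()
    for fam in fams:
        members = [r for r in ped.records if r.family == fam]
        assert 7 <= len(members) <= 20
        depths = [depth[r.id] for r in members]
        assert depths.count(0) == 4  # exactly four grandparents
        assert depths.count(1) == 2  # father and mother
        assert depths.count(2) >= 1  # at least one grandchild
    # a grandchild is related to all four grandparents
    K = ph.kinship_matrix(ped)
    fam0 = sorted(fams)[0]
    child = next(r.id for r in ped.records if r.family == fam0 and depth[r.id] == 2)
    gps = [r.id for r in ped.records if r.family == fam0 and depth[r.id] == 0]
    assert all(K.phi(child, g) == 0.125 for g in gps)


def test_full_sib_template():
    cfg = ph.SimulationConfig(n_families=5, family_template="full_sib_pairs", seed=3)
    ped = ph.simulate_pedigree(cfg)
    assert len(ped) == 20
    K = ph.kinship_matrix(ped)
    assert K.phi("F0000_s0", "F0000_s1") == 0.25


def test_simulation_is_deterministic_in_seed():
    cfg = ph.SimulationConfig(n_families=3, seed=9)
    p1, p2 = ph.simulate_pedigree(cfg), ph.simulate_pedigree(cfg)
    assert p1.ids == p2.ids
    d1, _ = ph.simulate_phenotype(p1, cfg)
    d2, _ = ph.simulate_phenotype(p2, cfg)
    np.testing.assert_array_equal(d1.y, d2.y)
    d3, _ = ph.simulate_phenotype(p1, ph.SimulationConfig(n_families=3, seed=10))
    assert not np.array_equal(d1.y, d3.y)


def test_distinct_trait_keys_give_independent_draws():
    cfg = ph.SimulationConfig(n_families=3, seed=9)
    ped = ph.simulate_pedigree(cfg)
    da, _ = ph.simulate_phenotype(ped, cfg, key="a")
    db, _ = ph.simulate_phenotype(ped, cfg, key="b")
    assert not np.array_equal(da.y, db.y)


def test_covariates_respect_generations():
    cfg = ph.SimulationConfig(n_families=5, seed=1)
    ped = ph.simulate_pedigree(cfg)
    cov = ph.simulate_covariates(ped, cfg.seed).set_index("id")
    depth = ped.generation_depth()
    for rec in ped.records:
        lo, hi = [(60, 80), (35, 55), (10, 30)][depth[rec.id]]
        assert lo <= cov.loc[rec.id, "age"] <= hi
        assert cov.loc[rec.id, "gender"] == (1 if rec.sex == "female" else 0)


def test_phenotype_variance_partition():
    """Across many replicate traits, var(u) ~ sigma_g^2 and var(y - Xb) ~ total."""
    cfg = ph.SimulationConfig(n_families=40, true_h2=0.4, total_variance=2.0, seed=6)
    ped = ph.simulate_pedigree(cfg)
    K = ph.kinship_matrix(ped)
    cov = ph.simulate_covariates(ped, cfg.seed)
    u_vars, resid_vars = [], []
    for rep in range(30):
        data, truth = ph.simulate_phenotype(ped, cfg, covariates=cov, kinship=K,
                                            key=f"vp{rep}")
        u_vars.append(np.mean(truth["u"] ** 2))
        fixed = data.X @ np.array([truth["beta0"], truth["beta_age"],
                                   truth["beta_gender"]])
        age = data.X[:, 1]
        fixed -= truth["beta_age"] * age.mean()  # generator centers age
        resid_vars.append(np.mean((data.y - fixed) ** 2))
    assert np.mean(u_vars) == pytest.approx(0.4 * 2.0, rel=0.1)
    assert np.mean(resid_vars) == pytest.approx(2.0, rel=0.1)
    assert truth["sigma_g_sq"] == 0.8 and truth["sigma_e_sq"] == pytest.approx(1.2)


def test_zero_h2_has_no_genetic_component():
    cfg = ph.SimulationConfig(n_families=3, true_h2=0.0, seed=6)
    ped = ph.simulate_pedigree(cfg)
    _, truth = ph.simulate_phenotype(ped, cfg)
    np.testing.assert_array_equal(truth["u"], 0.0)


def test_methylome_truth_mixture_and_correlation():
    cfg = ph.SimulationConfig(n_families=20, n_sites=400,
                              zero_inflation_pi0=0.2,
                              timepoint_correlation=0.7, seed=13)
    ped = ph.simulate_pedigree(cfg)
    mats, truth = simulate_methylome(ped, cfg)
    assert mats["pre"].scale == "M" and mats["pre"].values.shape == (400, len(ped))
    pi0_hat = 1.0 - truth["nonzero_pre"].mean()
    assert abs(pi0_hat - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 400)
    nz = truth["true_h2_pre"][truth["nonzero_pre"]]
    assert 0.25 < nz.mean() < 0.45  # Beta(2.5, 4.5) mean ~ 0.357
    both = truth["nonzero_pre"] & truth["nonzero_post"]
    r = np.corrcoef(truth.loc[both, "true_h2_pre"],
                    truth.loc[both, "true_h2_post"])[0, 1]
    assert 0.4 < r < 0.9  # copula couples the two time points


def test_timepoint_correlation_extremes():
    base = dict(n_families=5, n_sites=200, seed=14)
    _, t1 = simulate_methylome(ph.simulate_pedigree(ph.SimulationConfig(**base)),
                               ph.SimulationConfig(timepoint_correlation=1.0, **base))
    np.testing.assert_allclose(t1["true_h2_pre"], t1["true_h2_post"], atol=1e-12)


def test_config_validation():
    for bad in (dict(zero_inflation_pi0=1.5), dict(timepoint_correlation=-0.1),
                dict(total_variance=0.0), dict(true_h2=1.2)):
        with pytest.raises(ValueError):
            ph.SimulationConfig(**bad)
    with pytest.raises(ValueError, match="template"):
        ph.simulate_pedigree(ph.SimulationConfig(family_template="nuclear"))


def test_write_dataset_round_trip(tmp_path):
    cfg = ph.SimulationConfig(n_families=3, n_sites=5, seed=8)
    ped = ph.simulate_pedigree(cfg)
    cov = ph.simulate_covariates(ped, cfg.seed)
    mats, truth = simulate_methylome(ped, cfg, covariates=cov)
    ph.write_dataset(tmp_path, ped, cov, methylomes=mats, truth=truth)
    back_ped = ph.read_pedigree(tmp_path / "ped.fam")
    assert back_ped.ids == ped.ids
    from pediherit.methylation import read_methylation_tsv
    back_m = read_methylation_tsv(tmp_path / "m_pre.tsv", scale="M")
    np.testing.assert_allclose(back_m.values, mats["pre"].values, atol=1e-9)
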