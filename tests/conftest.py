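import numpy as np
import pytest
from hypothesis import settings

import pediherit as ph

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def three_gen():
    """~500-member three-generation study: pedigree, kinship (factorized),
    covariates and a shared grid-design cache, reused across tests."""
    cfg = ph.SimulationConfig(n_families=50, true_h2=0.5, seed=21)
    ped = ph.simulate_pedigree(cfg)
    K = ph.kinship_matrix(ped)
    K.eig()
    cov = ph.simulate_covariates(ped, cfg.seed)
    return {"config": cfg, "ped": ped, "K": K, "cov": cov, "cache": {}}


@pytest.fixture(scope="session")
def small_study():
    """~80-member study for dense-matrix oracles."""
    cfg = ph.SimulationConfig(n_families=8, true_h2=0.5, seed=4)
    ped = ph.simulate_pedigree(cfg)
    K = ph.kinship_matrix(ped)
    cov = ph.simulate_covariates(ped, cfg.seed)
    data, truth = ph.simulate_phenotype(ped, cfg, covariates=cov, kinship=K)
    return {"config": cfg, "ped": ped, "K": K, "cov": cov, "data": data, "truth": truth}


def make_trait(three_gen, true_h2, key):
    """Fresh phenotype draw on the shared pedigree."""
    cfg = ph.SimulationConfig(n_families=50, true_h2=true_h2, seed=21)
    data, truth = ph.simulate_phenotype(
        three_gen["ped"], cfg, covariates=three_gen["cov"],
        kinship=three_gen["K"], key=key)
    return data, truth
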