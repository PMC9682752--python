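import numpy as np
import pandas as pd
import pytest

from apycore import (GenotypeMatrix, SimConfig, build_genotype_matrix, build_grm,
                     run_breeding_program)


@pytest.fixture
def toy2():
    """Two individuals at two opposite-homozygote markers."""
    return build_genotype_matrix([[0, 2], [2, 0]], ids=["1", "2"])


def random_counts(n, m, seed):
    """Realistic 0/1/2 genotype counts at Hardy-Weinberg-ish frequencies."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=m)
    return rng.binomial(2, p, size=(n, m))


def random_gm(n, m, seed):
    return build_genotype_matrix(random_counts(n, m, seed))


def gaussian_gm(n, m, seed, v=1.0):
    """Centred Gaussian rows wrapped as a GenotypeMatrix (algorithm fixtures)."""
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, m))
    W -= W.mean(axis=0)
    return GenotypeMatrix(ids=[str(i + 1) for i in range(n)], counts=None,
                          p=None, W=W, v=v)


@pytest.fixture(scope="session")
def tiny_sim():
    """A very small but structurally complete breeding-programme run."""
    cfg = SimConfig(n_chr=2, sites_per_chr=60, qtl_per_chr=10, snp_per_chr=40,
                    cohort_size=40, n_dams=20, n_sires=4, young_dams=10, old_dams=10,
                    young_sires=3, old_sires=1, n_generations=6, genotyped_cohorts=3,
                    seed=11)
    return run_breeding_program(cfg, keep_haplotypes=True)


@pytest.fixture(scope="session")
def tiny_sim_tables(tiny_sim):
    gm = tiny_sim.genotype_matrix()
    pheno = pd.DataFrame({"id": gm.ids,
                          "y": tiny_sim.phenotype[gm.ids].to_numpy()})
    return gm, pheno
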