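"""GBLUP with the full and APY inverses, and the validation statistics.

Fits y = 1*mu + Z a + e with a ~ N(0, G sigma2_a) on a simulated population,
once with the dense inverse of G and once with the APY inverse built on a
conditional core sized at the 98% eigenvalue threshold, then compares GEBV
and computes accuracy against the simulated true breeding values.
"""

import numpy as np
import pandas as pd

from apycore import (ModelSpec, apy_inverse, build_grm, build_mme,
                     core_size_for_threshold, full_inverse, run_breeding_program,
                     select_conditional, solve, spectral, validation_report)
from apycore.simbreed import SimConfig

cfg = SimConfig(n_chr=4, sites_per_chr=110, qtl_per_chr=10, snp_per_chr=100,
                cohort_size=300, n_dams=150, n_sires=10, young_dams=75, old_dams=75,
                young_sires=9, old_sires=1, n_generations=8, genotyped_cohorts=3,
                seed=5)
sim = run_breeding_program(cfg)
gm = sim.genotype_matrix()
rm = build_grm(gm, 0.01)
k98 = core_size_for_threshold(spectral(gm), 0.98)
core = select_conditional(gm, k98)
print(f"{gm.n} genotyped animals; conditional core of {k98} "
      f"(98% eigenvalue threshold)")

pheno = pd.DataFrame({"id": gm.ids, "y": sim.phenotype[gm.ids].to_numpy()})


def fit(kinv, label):
    res = solve(build_mme(ModelSpec(animal_ids=gm.ids, kinv=kinv,
                                    va=cfg.va, ve=cfg.ve), pheno))
    rep = res.solver_report
    print(f"  {label}: solved ({rep['method']}, residual {rep['residual']:.1e})")
    return res


res_full = fit(full_inverse(rm), "full inverse")
res_apy = fit(apy_inverse(rm, core), "APY inverse ")

val = sim.validation_ids
rep = validation_report(res_full.gebv[val].to_numpy(),
                        gebv_b=res_apy.gebv[val].to_numpy(),
                        tbv=sim.tbv[val].to_numpy(), k=9, ids=val)
r_all = np.corrcoef(res_full.gebv, res_apy.gebv)[0, 1]
acc_full = np.corrcoef(res_full.gebv[val], sim.tbv[val])[0, 1]

print(f"\ncorr(GEBV_full, GEBV_APY), all genotyped : {r_all:.4f}")
print(f"corr(GEBV_full, GEBV_APY), validation    : {rep.corr_full_apy:.4f}")
print(f"accuracy corr(GEBV, TBV): full {acc_full:.3f} / APY {rep.accuracy:.3f}")
print(f"overlap of top-9 sire candidates (full vs APY ranking): "
      f"{rep.topk_overlap}/9")
print("\nWith a core at the 98% threshold the APY approximation is practically")
print("indistinguishable from the full inverse, including for the ranking of")
print("selection candidates.")
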