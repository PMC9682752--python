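"""The four core-subset constructions, and why the conditional one is stable.

Random and weighted sampling give a different core every replicate; the
diagonal and conditional constructions are deterministic.  The conditional
algorithm additionally spreads the core across the population by always
picking the animal least explained by the current core.
"""

import numpy as np

from apycore import (build_grm, run_breeding_program, select_conditional,
                     select_diagonal, select_random, select_weighted)
from apycore.simbreed import SimConfig

cfg = SimConfig(n_chr=4, sites_per_chr=110, qtl_per_chr=10, snp_per_chr=100,
                cohort_size=200, n_dams=100, n_sires=8, young_dams=50, old_dams=50,
                young_sires=7, old_sires=1, n_generations=6, genotyped_cohorts=2,
                seed=2)
sim = run_breeding_program(cfg)
gm = sim.genotype_matrix()
rm = build_grm(gm, 0.01)
k = 10

for seed_pair in [(1, 2)]:
    ra = set(select_random(gm.ids, k, seed=seed_pair[0]).core_ids)
    rb = set(select_random(gm.ids, k, seed=seed_pair[1]).core_ids)
    wa = set(select_weighted(rm, k, seed=seed_pair[0]).core_ids)
    wb = set(select_weighted(rm, k, seed=seed_pair[1]).core_ids)
print(f"random   : {len(ra & rb)}/{k} animals shared between two replicates")
print(f"weighted : {len(wa & wb)}/{k} animals shared between two replicates")

da = select_diagonal(rm, k).core_ids
db = select_diagonal(rm, k).core_ids
ca = select_conditional(gm, k)
cb = select_conditional(gm, k)
print(f"diagonal : identical across runs: {da == db}")
print(f"conditional: identical across runs: {ca.core_ids == cb.core_ids}")

print("\nconditional picks (selection order) and their conditional variance")
print("at selection time - non-increasing because conditioning only removes")
print("variation:")
for a, v in zip(ca.core_ids, ca.selection_variances):
    print(f"  animal {a:>5}  variance {v:8.1f}")

# how many paternal half-sib families of the last cohort does each core touch?
ped = sim.pedigree.set_index("animal")
last_gen = sim.cfg.n_generations
def families(core_ids):
    sires = {ped.loc[int(a), "sire"] for a in core_ids
             if ped.loc[int(a), "generation"] == last_gen}
    return len(sires)
print(f"\nsire families touched by the {k}-animal core (last cohort only): "
      f"conditional {families(ca.core_ids)}, one random draw {families(ra)}")
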