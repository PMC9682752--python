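"""Forward simulator of a closed cattle-like breeding programme.

The default configuration emulates a simple dairy/beef-style scheme with
overlapping generations: a genome of 10 chromosomes x 1100 segregating
sites (100 QTL + 1000 SNP markers per chromosome, disjoint), an additive
trait with breeding-value variance 1.00 and residual variance 2.33
(heritability 0.30), cohorts of 3000 animals at an exact 50:50 sex ratio
produced by 1500 dams x 50 sires with two offspring per dam, dams replaced
at 50% per generation and selected on phenotype, sires (45 young + 5 old)
selected on true breeding value, 20 selection generations, and SNP
genotypes collected for the five most recent cohorts (15,000 animals, the
final cohort serving as validation).

Founders are generated as independent loci (allele frequency drawn per site
from a uniform law), optionally followed by a random-mating drift burn-in to
create linkage disequilibrium; no coalescent history is simulated, so
absolute levels of LD — and therefore absolute prediction accuracies — are
not calibrated to any particular real population.  Meiosis uses Poisson
crossovers with no interference (1 Morgan per chromosome by default),
implemented as independent Bernoulli haplotype switches between adjacent
sites, which is exactly equivalent and vectorises over a whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .relmat import GenotypeMatrix, build_genotype_matrix

__all__ = [
    "SimConfig",
    "SimState",
    "SimData",
    "simulate_founders",
    "simulate_trait",
    "advance_generation",
    "run_breeding_program",
    "scaled_study_config",
]

FEMALE, MALE = 0, 1


def scaled_study_config(seed: int | None = None) -> "SimConfig":
    """One-fifth-scale variant of the default design for desk-scale runs.

    Keeps the structure of the full scheme — ten chromosomes, disjoint
    QTL/SNP sets, 50% dam replacement, young/old sire mix, two offspring per
    dam, five genotyped cohorts with the last as validation — at 600 animals
    per cohort and 2000 SNP markers (about 3000 genotyped animals).
    """
    return SimConfig(n_chr=10, sites_per_chr=220, qtl_per_chr=20, snp_per_chr=200,
                     cohort_size=600, n_dams=300, n_sires=10, young_dams=150,
                     old_dams=150, young_sires=9, old_sires=1, n_generations=10,
                     genotyped_cohorts=5, seed=seed)


@dataclass(frozen=True)
class SimConfig:
    """Breeding-programme parameters (defaults are the study design)."""

    n_chr: int = 10
    sites_per_chr: int = 1100
    qtl_per_chr: int = 100
    snp_per_chr: int = 1000
    va: float = 1.00          # breeding-value variance, trait units^2
    ve: float = 2.33          # residual variance, trait units^2
    cohort_size: int = 3000
    n_dams: int = 1500
    n_sires: int = 50
    young_dams: int = 750
    old_dams: int = 750
    young_sires: int = 45
    old_sires: int = 5
    offspring_per_dam: int = 2
    n_generations: int = 20
    genotyped_cohorts: int = 5
    founder_mode: str = "independent"   # "independent" | "drift"
    burn_in_generations: int = 20       # drift mode only
    founder_freq_low: float = 0.05      # uniform law for founder allele frequency
    founder_freq_high: float = 0.95
    maf_floor: float = 0.01
    morgans_per_chr: float = 1.0        # expected crossovers per chromosome
    dam_criterion: str = "phenotype"    # "phenotype" | "tbv" | "random"
    sire_criterion: str = "tbv"
    seed: int | None = None

    @property
    def heritability(self) -> float:
        return self.va / (self.va + self.ve)

    @property
    def n_sites(self) -> int:
        return self.n_chr * self.sites_per_chr

    @property
    def n_snp(self) -> int:
        return self.n_chr * self.snp_per_chr

    @property
    def n_qtl(self) -> int:
        return self.n_chr * self.qtl_per_chr

    def validate(self):
        if self.qtl_per_chr + self.snp_per_chr > self.sites_per_chr:
            raise ValidationError("qtl_per_chr + snp_per_chr exceeds sites_per_chr")
        if self.young_dams + self.old_dams != self.n_dams:
            raise ValidationError("young_dams + old_dams must equal n_dams")
        if self.young_sires + self.old_sires != self.n_sires:
            raise ValidationError("young_sires + old_sires must equal n_sires")
        if self.n_dams * self.offspring_per_dam != self.cohort_size:
            raise ValidationError("n_dams * offspring_per_dam must equal cohort_size")
        if self.cohort_size % 2 != 0:
            raise ValidationError("cohort_size must be even (equal sex ratio)")
        half = self.cohort_size // 2
        if self.young_dams > half or self.young_sires > half:
            raise ValidationError("young parent numbers exceed per-sex cohort size")
        if self.n_dams > half or self.n_sires > half:
            raise ValidationError("parent numbers exceed per-sex cohort size")
        if self.founder_mode not in ("independent", "drift"):
            raise ValidationError(f"unknown founder_mode {self.founder_mode!r}")
        if not 0 < self.founder_freq_low <= self.founder_freq_high < 1:
            raise ValidationError("founder frequency bounds must satisfy 0 < lo <= hi < 1")
        for crit in (self.dam_criterion, self.sire_criterion):
            if crit not in ("phenotype", "tbv", "random"):
                raise ValidationError(f"unknown selection criterion {crit!r}")
        if self.va <= 0 or self.ve <= 0:
            raise ValidationError("va and ve must be > 0")


@dataclass
class _ParentPool:
    ids: np.ndarray            # int ids
    hap: np.ndarray            # (n, 2, sites) uint8
    tbv: np.ndarray
    phen: np.ndarray


@dataclass
class SimState:
    """Mutable simulation state: current cohort plus live parent pools."""

    cfg: SimConfig
    generation: int
    next_id: int
    qtl_idx: np.ndarray
    snp_idx: np.ndarray
    cohort: _ParentPool
    cohort_sex: np.ndarray                 # 0 female, 1 male
    dams: _ParentPool | None = None        # dams of the current cohort
    sires: _ParentPool | None = None
    young_sires: _ParentPool | None = None  # young subset of current sires
    qtl_effects: np.ndarray | None = None
    tbv_offset: float = 0.0
    pedigree_rows: list = field(default_factory=list)


@dataclass
class SimData:
    """Final simulator output."""

    cfg: SimConfig
    pedigree: pd.DataFrame     # animal, sire, dam, sex, generation (0 = founder/unknown)
    tbv: pd.Series             # per-animal true breeding value, trait units
    phenotype: pd.Series
    qtl_effects: np.ndarray
    genotyped_ids: list[str]
    genotypes: np.ndarray      # (n_genotyped, n_snp) uint8 allele counts at SNP sites
    marker_names: list[str]
    validation_ids: list[str]
    haplotypes: dict | None = None   # generation -> (ids, hap) when retained

    def is_genotyped(self, animal) -> bool:
        return str(animal) in set(self.genotyped_ids)

    def genotype_matrix(self, freqs=None) -> GenotypeMatrix:
        return build_genotype_matrix(self.genotypes, ids=self.genotyped_ids, freqs=freqs)


def _founder_haplotypes(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Independent-loci haplotypes with every site's realised MAF >= floor."""
    p = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, size=cfg.n_sites)
    hap = (rng.random((n, 2, cfg.n_sites), dtype=np.float32)
           < p.astype(np.float32)).astype(np.uint8)
    _refloor_sites(cfg, hap, rng)
    return hap

def _refloor_sites(cfg: SimConfig, hap: np.ndarray, rng: np.random.Generator):
    """Resample sites whose realised MAF fell below the floor, in place."""
    n2 = hap.shape[0] * 2
    for _ in range(100):
        freq = hap.sum(axis=(0, 1)) / n2
        maf = np.minimum(freq, 1.0 - freq)
        bad = np.flatnonzero(maf < cfg.maf_floor)
        if bad.size == 0:
            return
        p = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, size=bad.size)
        hap[:, :, bad] = (rng.random((hap.shape[0], 2, bad.size)) < p).astype(np.uint8)
    raise ValidationError("could not realise the MAF floor; population too small?")


def _meiosis(cfg: SimConfig, parent_hap: np.ndarray, parent_rows: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per offspring from the given parents, vectorised per chromosome.

    Crossovers form a Poisson process with ``morgans_per_chr`` expected events
    per chromosome; equivalently the carried haplotype switches independently
    between adjacent sites with probability (1 - exp(-2 lambda dx)) / 2.
    """
    n = parent_rows.size
    S = cfg.sites_per_chr
    if S > 1:
        p_switch = 0.5 * (1.0 - np.exp(-2.0 * cfg.morgans_per_chr / (S - 1)))
    else:
        p_switch = 0.0
    h = parent_hap[parent_rows]                      # (n, 2, sites)
    gamete = np.empty((n, cfg.n_sites), dtype=np.uint8)
    for c in range(cfg.n_chr):
        lo, hi = c * S, (c + 1) * S
        start = rng.integers(0, 2, size=(n, 1))
        if S > 1:
            switches = (rng.random((n, S - 1), dtype=np.float32)
                        < np.float32(p_switch))
            carried = np.empty((n, S), dtype=np.int8)
            carried[:, 0] = start[:, 0]
            carried[:, 1:] = (start + np.cumsum(switches, axis=1, dtype=np.int32)) % 2
        else:
            carried = start.astype(np.int8)
        block = h[:, :, lo:hi]
        gamete[:, lo:hi] = np.where(carried == 0, block[:, 0, :], block[:, 1, :])
    return gamete


def _tbv_phen(cfg: SimConfig, state: SimState, hap: np.ndarray,
              rng: np.random.Generator):
    counts = hap[:, 0, state.qtl_idx].astype(float) + hap[:, 1, state.qtl_idx]
    tbv = counts @ state.qtl_effects - state.tbv_offset
    phen = tbv + rng.normal(0.0, np.sqrt(cfg.ve), size=tbv.size)
    return tbv, phen


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimState:
    """Generation-0 founder population (haplotypes only; trait added separately)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    hap = _founder_haplotypes(cfg, cfg.cohort_size, rng)
    if cfg.founder_mode == "drift":
        sex = np.arange(cfg.cohort_size) % 2
        for _ in range(cfg.burn_in_generations):
            females = np.flatnonzero(sex == FEMALE)
            males = np.flatnonzero(sex == MALE)
            d = rng.choice(females, size=cfg.cohort_size)
            s = rng.choice(males, size=cfg.cohort_size)
            hap = np.stack([_meiosis(cfg, hap, s, rng),
                            _meiosis(cfg, hap, d, rng)], axis=1)
            sex = rng.integers(0, 2, size=cfg.cohort_size)
        _refloor_sites(cfg, hap, rng)

    # disjoint random QTL/SNP assignment within each chromosome
    qtl_idx, snp_idx = [], []
    for c in range(cfg.n_chr):
        perm = rng.permutation(cfg.sites_per_chr) + c * cfg.sites_per_chr
        qtl_idx.append(np.sort(perm[:cfg.qtl_per_chr]))
        snp_idx.append(np.sort(perm[cfg.qtl_per_chr:cfg.qtl_per_chr + cfg.snp_per_chr]))
    qtl_idx = np.concatenate(qtl_idx)
    snp_idx = np.concatenate(snp_idx)

    n = cfg.cohort_size
    ids = np.arange(1, n + 1)
    sex = np.arange(n) % 2               # deterministic alternation: exact 50:50
    state = SimState(
        cfg=cfg, generation=0, next_id=n + 1, qtl_idx=qtl_idx, snp_idx=snp_idx,
        cohort=_ParentPool(ids=ids, hap=hap, tbv=np.zeros(n), phen=np.zeros(n)),
        cohort_sex=sex)
    for i in range(n):
        state.pedigree_rows.append((int(ids[i]), 0, 0, "F" if sex[i] == FEMALE else "M", 0))
    return state


def simulate_trait(cfg: SimConfig, state: SimState,
                   rng: np.random.Generator) -> SimState:
    """Draw additive QTL effects and rescale so founder TBV sample variance = va."""
    effects = rng.standard_normal(cfg.n_qtl)
    counts = state.cohort.hap[:, 0, state.qtl_idx].astype(float) \
        + state.cohort.hap[:, 1, state.qtl_idx]
    raw = counts @ effects
    var = raw.var(ddof=1)
    if var <= 0:
        raise DegenerateDataError("zero genic variance at the QTL")
    effects *= np.sqrt(cfg.va / var)
    state.qtl_effects = effects
    raw = counts @ effects
    state.tbv_offset = float(raw.mean())
    state.cohort.tbv = raw - state.tbv_offset
    state.cohort.phen = state.cohort.tbv + rng.normal(0.0, np.sqrt(cfg.ve),
                                                      size=raw.size)
    return state


def _rank(values: np.ndarray, criterion: str, pool: _ParentPool,
          rng: np.random.Generator) -> np.ndarray:
    if criterion == "random":
        return rng.permutation(values.size)
    return np.argsort(-values, kind="stable")


def _take(pool: _ParentPool, rows: np.ndarray) -> _ParentPool:
    return _ParentPool(ids=pool.ids[rows], hap=pool.hap[rows],
                       tbv=pool.tbv[rows], phen=pool.phen[rows])


def _select_parents(cfg: SimConfig, state: SimState, rng: np.random.Generator):
    females = np.flatnonzero(state.cohort_sex == FEMALE)
    males = np.flatnonzero(state.cohort_sex == MALE)
    cohort = state.cohort

    if state.dams is None:
        # first parent generation: random choice among founders
        dams = _take(cohort, rng.choice(females, size=cfg.n_dams, replace=False))
        sires = _take(cohort, rng.choice(males, size=cfg.n_sires, replace=False))
        young = None
    else:
        if females.size < cfg.young_dams or males.size < cfg.young_sires:
            raise ValidationError("cohort too small for the configured parent numbers")
        fpool = _take(cohort, females)
        crit = fpool.phen if cfg.dam_criterion == "phenotype" else fpool.tbv
        young_d = _take(fpool, _rank(crit, cfg.dam_criterion, fpool, rng)[:cfg.young_dams])
        opool = state.dams
        if opool.ids.size < cfg.old_dams:
            raise ValidationError("old-dam pool smaller than old_dams")
        crit = opool.phen if cfg.dam_criterion == "phenotype" else opool.tbv
        old_d = _take(opool, _rank(crit, cfg.dam_criterion, opool, rng)[:cfg.old_dams])
        dams = _ParentPool(*[np.concatenate([getattr(young_d, f), getattr(old_d, f)])
                             for f in ("ids", "hap", "tbv", "phen")])

        mpool = _take(cohort, males)
        crit = mpool.tbv if cfg.sire_criterion == "tbv" else mpool.phen
        young = _take(mpool, _rank(crit, cfg.sire_criterion, mpool, rng)[:cfg.young_sires])
        spool = state.young_sires if state.young_sires is not None else state.sires
        if spool.ids.size < cfg.old_sires:
            raise ValidationError("old-sire pool smaller than old_sires")
        crit = spool.tbv if cfg.sire_criterion == "tbv" else spool.phen
        old_s = _take(spool, _rank(crit, cfg.sire_criterion, spool, rng)[:cfg.old_sires])
        sires = _ParentPool(*[np.concatenate([getattr(young, f), getattr(old_s, f)])
                              for f in ("ids", "hap", "tbv", "phen")])
    return dams, sires, young


def advance_generation(cfg: SimConfig, state: SimState,
                       rng: np.random.Generator) -> SimState:
    """Select parents, mate, and replace the cohort with its offspring.

    Dams: the best ``young_dams`` females of the current cohort plus the best
    ``old_dams`` of the previous dam pool, ranked on phenotype.  Sires: the
    best ``young_sires`` males of the current cohort plus the best
    ``old_sires`` of the previous young sires, ranked on true breeding value.
    Each dam produces exactly ``offspring_per_dam`` offspring by a uniformly
    random sire; offspring sex alternates within a dam's litter so the cohort
    sex ratio is exactly 50:50.
    """
    if state.qtl_effects is None:
        raise ValidationError("simulate_trait must run before advancing generations")
    dams, sires, young = _select_parents(cfg, state, rng)

    opd = cfg.offspring_per_dam
    n_off = cfg.n_dams * opd
    dam_rows = np.repeat(np.arange(cfg.n_dams), opd)
    sire_assign = rng.integers(0, cfg.n_sires, size=cfg.n_dams)
    sire_rows = np.repeat(sire_assign, opd)

    pat = _meiosis(cfg, sires.hap, sire_rows, rng)
    mat = _meiosis(cfg, dams.hap, dam_rows, rng)
    hap = np.stack([pat, mat], axis=1)

    ids = np.arange(state.next_id, state.next_id + n_off)
    sex = np.tile(np.arange(opd) % 2, cfg.n_dams)    # F, M within each litter
    tbv, phen = _tbv_phen(cfg, state, hap, rng)

    gen = state.generation + 1
    for i in range(n_off):
        state.pedigree_rows.append(
            (int(ids[i]), int(sires.ids[sire_rows[i]]), int(dams.ids[dam_rows[i]]),
             "F" if sex[i] == FEMALE else "M", gen))

    state.generation = gen
    state.next_id += n_off
    state.cohort = _ParentPool(ids=ids, hap=hap, tbv=tbv, phen=phen)
    state.cohort_sex = sex
    state.dams, state.sires, state.young_sires = dams, sires, young
    return state


def run_breeding_program(cfg: SimConfig, seed: int | None = None,
                         store_genotypes: bool = True,
                         keep_haplotypes: bool = False) -> SimData:
    """Run the full programme and collect outputs.

    SNP genotypes are extracted for the ``genotyped_cohorts`` most recent
    cohorts; the final cohort is flagged as the validation subset.  Pass
    ``store_genotypes=False`` when only the pedigree/trait trajectory is
    needed (e.g. design checks), and ``keep_haplotypes=True`` on small
    configurations to retain per-generation haplotypes for inspection.
    """
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    state = simulate_founders(cfg, rng)
    simulate_trait(cfg, state, rng)

    tbv_map: dict[int, float] = {}
    phen_map: dict[int, float] = {}
    geno_chunks, geno_ids = [], []
    haplo = {} if keep_haplotypes else None
    first_genotyped = cfg.n_generations - cfg.genotyped_cohorts + 1

    def record(state: SimState):
        for i, a in enumerate(state.cohort.ids):
            tbv_map[int(a)] = float(state.cohort.tbv[i])
            phen_map[int(a)] = float(state.cohort.phen[i])
        if store_genotypes and state.generation >= first_genotyped:
            counts = (state.cohort.hap[:, 0, state.snp_idx]
                      + state.cohort.hap[:, 1, state.snp_idx]).astype(np.uint8)
            geno_chunks.append(counts)
            geno_ids.extend(str(int(a)) for a in state.cohort.ids)
        if keep_haplotypes:
            haplo[state.generation] = (state.cohort.ids.copy(),
                                       state.cohort.hap.copy())

    record(state)
    for _ in range(cfg.n_generations):
        advance_generation(cfg, state, rng)
        record(state)

    pedigree = pd.DataFrame(state.pedigree_rows,
                            columns=["animal", "sire", "dam", "sex", "generation"])
    ids_all = pedigree["animal"].astype(str)
    validation_ids = [str(int(a)) for a in state.cohort.ids]
    genotypes = (np.vstack(geno_chunks) if geno_chunks
                 else np.empty((0, cfg.n_snp), dtype=np.uint8))
    return SimData(
        cfg=cfg, pedigree=pedigree,
        tbv=pd.Series([tbv_map[a] for a in pedigree["animal"]], index=ids_all.values),
        phenotype=pd.Series([phen_map[a] for a in pedigree["animal"]],
                            index=ids_all.values),
        qtl_effects=state.qtl_effects,
        genotyped_ids=geno_ids, genotypes=genotypes,
        marker_names=[f"snp_{j + 1}" for j in range(cfg.n_snp)],
        validation_ids=validation_ids, haplotypes=haplo)
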