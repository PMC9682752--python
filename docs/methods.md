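# Methods

This note records the models, algorithms and numerical conventions the
package implements, the choices made where the design was open, and what the
bundled simulator does and does not emulate.

## Genomic relationship matrix

Genotypes are alternative-allele counts in {0, 1, 2}; missing values are
rejected rather than imputed.  With observed (or externally supplied) allele
frequencies `p`, the centred matrix is `W = counts − 2p` and
`G = W W' / v`, `v = 2 Σ pⱼ(1 − pⱼ)`.  Monomorphic markers are retained —
their `W` column is zero and contributes nothing — so marker indexing stays
stable; only fully monomorphic input (v = 0) is an error.

To guarantee positive definiteness `G` is blended with the identity.  The
default is the weighted convention `G = (1 − w)·G_raw + w·I` with
`w = 0.01`; an additive convention `G_raw + w·I` is available via
`blend_mode="additive"`.  Both preserve the intent (a strictly positive
spectrum); the weighted form keeps the average inbreeding level unchanged to
first order and is the default because it is the more common reading of
"blending".

The spectrum of `G` is always computed from the thin SVD `W = U D V'` of the
n×m matrix (cost O(m²n)), never from the n×n eigenproblem: eigenvalues of
the **unblended** `G` are `D²/v`.  Core sizes for a captured-variance
threshold f are the smallest k with `(Σ first k eigenvalues)/trace ≥ f`.
Thresholds deliberately use the unblended spectrum — blending adds a flat
`w` to every eigenvalue and would distort the variance fractions.

Numerical conventions: symmetry and orthogonality are checked at 1e−8
relative tolerance; eigenvalues within −1e−10 of zero are clamped to zero;
assembled symmetric matrices are re-symmetrised as `(A + A')/2` to remove
accumulation noise.

## Core-subset constructions

All constructions receive the core size k (typically from an eigenvalue
threshold) and return an ordered subset:

* **random** — uniform without replacement, seeded.
* **diagonal** — k largest `g_ii`; ties broken by lowest input index.
* **weighted** — sequential sampling without replacement with probability
  proportional to `g_ii`, renormalised after each draw.  (Replacement
  semantics were an open choice; sequential-without-replacement matches the
  intent of covering many families and never repeats an animal.)
* **conditional** — the greedy loop: start from the animal with the largest
  diagonal of `W W'` (the farthest edge of the domain; deterministic), then
  repeatedly select the animal with the largest conditional variance given
  the current core and condition on it.  Two algebraically identical routes
  are provided: a covariance route updating
  `C ← C − C e (e'Ce)⁻¹ e'C` (kept as the small-n oracle) and the production
  genotype route updating `W ← W − W a'a` with `a = w/‖w‖`, tracking
  conditional variances incrementally as row squared norms
  (`d ← d − (W a)²`) so the n×n covariance is never materialised.  The
  rank-1 downdate runs in place through BLAS `dger` on the F-ordered
  transpose.  Argmax ties break to the lowest input index everywhere, so
  repeated runs are bit-identical.

A pick whose conditional variance falls below `1e−10 ×` the initial maximum
variance means the remaining animals are numerically dependent on the core;
the selection raises a rank-exhausted error reporting how many animals were
selectable, rather than silently returning dependent animals (which would
make `G_cc` singular downstream).

**Min-max / min-average extension.**  Each pick minimises the maximum (or
mean) conditional variance of the *other* animals after conditioning on the
candidate.  The inner candidate loop makes it O(n) times slower than the
base algorithm; it exists for small problems and comparison only.  When two
candidates score equally (e.g. they span the same direction), the tie breaks
to the larger own conditional variance — consistent with the base
algorithm's preference for extreme animals — then to the lower index.

**Reduced-rank selection.**  `W_r = U_r D_r` with r chosen by an eigenvalue
threshold gives the best rank-r approximation of `W W'` (truncation error =
sum of discarded eigenvalues × v) and can stand in for `W` in the
conditional algorithm to cut time on large data.

**Core expansion.**  Given new genotype data, the combined matrix
`[old core rows; new rows]` — centred on the *old* allele frequencies, which
callers must pass explicitly — is conditioned on each old core animal in its
original selection order, and the greedy loop then appends `k_new` animals
(old animals are excluded from re-selection).  Sequential conditioning on
the old core reproduces the internal state of the one-shot algorithm, so
when the old core is a conditional prefix of the combined data the expansion
is *exactly* the continuation of the combined optimisation; this is the
property the tests verify.  For an old core selected from a different
population the expansion is the natural greedy continuation but no longer
provably coincides with a from-scratch reselection.

## APY inverse

For a core/non-core partition the inverse is stored in factored blocks —
`Gcc⁻¹` (dense, via Cholesky), the cross factor `−Gcc⁻¹ Gcn`, and the
diagonal `Mnn` of non-core conditional variances `g_ii − g_ic Gcc⁻¹ g_ci` —
and assembled densely or streamed as sparse 1-based lower-triangle triplets
only on demand, in the original id order with an explicit permutation
record.  A non-positive-definite `G_cc` or a non-positive `Mnn` entry is an
error, never a silent pseudo-inverse: both indicate an unblended or
rank-deficient `G`.  The testing oracle `implied_G_apy` returns the
relationship matrix whose exact inverse the APY formula produces (`G` with
the non-core block replaced by `Gnc Gcc⁻¹ Gcn + diag(Mnn)`); the product of
the assembled inverse with it is the identity to machine precision, and the
inverse is exact at the two partition extremes (core = all; single non-core
animal).

## GBLUP

The mixed model equations for `y = X b + Z a (+ Z_l l) + e` are

```
[X'X    X'Z           X'Z_l ]  [b]   [X'y ]
[Z'X    Z'Z + K⁻¹λa   Z'Z_l ]  [a] = [Z'y ]
[Z_l'X  Z_l'Z         Z_l'Z_l + Iλl]  [l]   [Z_l'y]
```

with `λa = σ²e/σ²a`, `λl = σ²e/σ²l`, and `K⁻¹` either the dense full inverse
or the factored APY inverse (used through matvec/diagonal accessors, never
densified for the iterative path).  Variance components are supplied, never
estimated.  Fixed categorical effects are reference-level coded (first
sorted level dropped); a rank-deficient fixed design is an error naming the
confounded columns.  Animals present in `K` without phenotypes simply get
zero incidence and receive GEBV through the relationship coupling.

Solvers: `direct` is a dense Cholesky of the (symmetric positive definite)
coefficient matrix; `pcg` is conjugate gradient with a Jacobi (diagonal)
preconditioner to relative residual 1e−12 by default, with the iteration
trace kept for the solver report and carried on the non-convergence error.

Validation statistics: Pearson correlation between GEBV vectors; accuracy
(correlation with true breeding values); predictive ability (correlation
with fixed-effect-adjusted phenotypes `y − X b̂`); dispersion slope
`cov(y_adj, GEBV)/var(GEBV)` (below 1 ⇒ inflated GEBV); top-k overlap with
ties broken by animal id.  The adjustment `b̂` is taken from the
full-inverse fit so every APY variant is compared on one common adjustment.
The experiment runner fits the intercept + animal model; richer fixed-effect
models are fitted through the `gblup` module directly.

## Breeding-programme simulator

The generator emulates a closed nucleus programme with overlapping
generations.  Defaults (the study conditions): genome of 10 chromosomes ×
1100 segregating sites, of which 100 QTL and 1000 SNP markers per chromosome
(disjoint, randomly placed); additive trait with QTL effects drawn normal
and rescaled so the founder TBV sample variance is exactly σ²a = 1.00;
residual variance σ²e = 2.33, hence heritability 0.30; cohorts of 3000 at an
exact 50:50 sex ratio from 1500 dams × 50 sires, two offspring per dam with
deterministic F/M sex alternation within each litter; dams replaced at 50%
per generation (best 750 young cohort females + best 750 of the previous
dam pool, ranked on phenotype); sires = best 45 young males on true breeding
value + best 5 of the previous generation's young sires (mimicking accurate
selection; the first selection generation draws parents at random from the
founders); 20 selection generations; SNP genotypes collected for the five
most recent cohorts (15,000 animals), the final cohort being the validation
subset.  Sires are assigned to dams uniformly at random; with 1500 dams per
50 sires every sire is used with overwhelming probability, so the final
generation contains exactly 50 paternal half-sib families.

Founders are **independent loci**: per-site allele frequency drawn from
Uniform(0.05, 0.95), haplotypes Bernoulli, and any site whose realised MAF
falls below 0.01 resampled.  An optional drift mode adds a random-mating
recombination burn-in to create linkage disequilibrium (sites fixed during
burn-in are re-drawn, which locally resets their LD).  No coalescent
demography is simulated: founder LD is therefore weaker than in a real
livestock population, which matters for *absolute* prediction accuracies but
not for the counts forced by the design, the algebraic properties of APY, or
the relative comparison of core constructions — which is what the tests
assert.  Passing tests consequently show correctness of the machinery and
the design-driven structure, not calibration to any real population.

Meiosis: crossovers per chromosome are Poisson with mean 1 (1 Morgan per
chromosome, configurable) and no interference.  This is implemented as
independent Bernoulli haplotype switches between adjacent sites with
`p = (1 − e^(−2λ/(S−1)))/2` — exactly the parity of a Poisson count in each
inter-site interval — which vectorises over all meioses of a generation.
No mutation occurs after the founders.

**Scaled study configuration.**  `scaled_study_config()` is a one-fifth
scale variant (cohorts of 600, 10 sires, 2000 SNPs, 10 generations, ~3000
genotyped animals) preserving the structure of the full design; it is the
problem size used by the end-to-end fidelity checks and the acceptance
script, chosen so the whole pipeline (simulation, SVD, conditional
selection, two GBLUP fits) runs in well under a minute on one CPU.

## Known limitations

* No missing-genotype handling, quality control, or imputation.
* No pedigree `A` matrix or single-step `H`; evaluation covers genotyped
  animals only.
* The min-max/min-average selection variants are quadratic-time and
  intended for small n.
* Expansion requires centring new animals on the old allele frequencies;
  evaluations that continually update frequencies must freeze them
  explicitly when they rebuild the core.
* Founder LD is not calibrated to a real population (see above), so
  absolute accuracies from the simulator should not be read as predictions
  for any specific breed.
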