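"""APY core-subset construction.

Four strategies for choosing the core animals whose relationship block is
densely inverted in APY:

* ``random`` — uniform sampling without replacement (the common baseline);
* ``diagonal`` — the animals with the largest diagonal of G (farthest from
  the genotype centroid);
* ``weighted`` — random sampling weighted by the G diagonal;
* ``conditional`` — the greedy algorithm that repeatedly picks the animal
  with the largest conditional variance given the animals already chosen,
  then conditions the genotype (or covariance) structure on it.

The conditional algorithm is deterministic and spreads the core across the
domain of genotyped animals.  It supports a covariance-matrix route (the
small-n oracle) and a genotype-matrix route that never materialises the
n x n covariance, a reduced-rank variant, expansion of an existing core with
new genotype data, and a slower min-max / min-average extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import blas

from .errors import RankExhaustedError, ValidationError
from .relmat import GenotypeMatrix, RelationshipMatrix, core_size_for_threshold, spectral

__all__ = [
    "CoreSubset",
    "ReducedGenotypes",
    "select_random",
    "select_diagonal",
    "select_weighted",
    "select_conditional",
    "select_conditional_min",
    "expand_core",
    "reduced_rank",
]

#: a pick whose conditional variance falls below this multiple of the initial
#: maximum variance is numerically dependent on the current core
VARIANCE_FLOOR = 1e-10


@dataclass
class CoreSubset:
    """An ordered core subset with its construction provenance.

    ``selection_variances`` holds, for conditional methods, the conditional
    variance of each chosen animal at the moment it was selected (NaN for
    animals inherited as a fixed prefix during expansion).
    """

    core_ids: list[str]
    method: str
    seed: int | None = None
    selection_variances: np.ndarray | None = None

    def __post_init__(self):
        self.core_ids = [str(a) for a in self.core_ids]
        if len(set(self.core_ids)) != len(self.core_ids):
            raise ValidationError("core ids are not unique")

    @property
    def k(self) -> int:
        return len(self.core_ids)


@dataclass
class ReducedGenotypes:
    """Reduced-rank stand-in for a genotype matrix: W_r = U_r D_r (n x r)."""

    ids: list[str]
    W: np.ndarray
    v: float

    @property
    def n(self) -> int:
        return self.W.shape[0]


def _check_k(k: int, n: int):
    if not 0 <= k <= n:
        raise ValidationError(f"core size k={k} outside [0, {n}]")


def select_random(ids, k: int, seed: int | None = None) -> CoreSubset:
    """k animals sampled uniformly without replacement."""
    ids = [str(a) for a in ids]
    _check_k(k, len(ids))
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(ids), size=k, replace=False)
    return CoreSubset(core_ids=[ids[i] for i in picks], method="random", seed=seed)


def select_diagonal(rm: RelationshipMatrix, k: int) -> CoreSubset:
    """The k animals with the largest diagonal of G; ties to the lowest index."""
    _check_k(k, rm.n)
    order = np.argsort(-np.diag(rm.G), kind="stable")
    return CoreSubset(core_ids=[rm.ids[i] for i in order[:k]], method="diagonal")


def select_weighted(rm: RelationshipMatrix, k: int, seed: int | None = None) -> CoreSubset:
    """Sequential sampling without replacement, weight proportional to diag(G)."""
    _check_k(k, rm.n)
    w = np.diag(rm.G).astype(float).copy()
    if (w < 0).any():
        raise ValidationError("negative diagonal elements cannot serve as weights")
    if int((w > 0).sum()) < k:
        raise ValidationError(
            f"only {int((w > 0).sum())} animals have positive weight; cannot sample {k}")
    rng = np.random.default_rng(seed)
    picks: list[int] = []
    for _ in range(k):
        i = int(rng.choice(rm.n, p=w / w.sum()))
        picks.append(i)
        w[i] = 0.0
    return CoreSubset(core_ids=[rm.ids[i] for i in picks], method="weighted", seed=seed)


def _greedy_genotype(Wc: np.ndarray, d: np.ndarray, k: int, floor_ref: float,
                     forbidden: np.ndarray | None = None):
    """Greedy max-conditional-variance loop on a (conditioned) genotype matrix.

    Mutates ``Wc`` and ``d`` in place; ``d`` must equal the row squared norms
    of ``Wc`` on entry.  Returns (picks, variances).
    """
    floor = VARIANCE_FLOOR * floor_ref
    picks: list[int] = []
    variances: list[float] = []
    # work on the F-ordered transpose so the rank-1 downdate runs in place
    WT = Wc.T if Wc.T.flags.f_contiguous else np.asfortranarray(Wc.T)
    for step in range(k):
        d_eff = d if forbidden is None else np.where(forbidden, -np.inf, d)
        i = int(np.argmax(d_eff))
        if d[i] <= floor:
            raise RankExhaustedError(
                f"conditional variance exhausted after {step} of {k} requested core "
                f"animals (remaining max {d[i]:.3e} <= floor {floor:.3e})",
                n_selected=step)
        picks.append(i)
        variances.append(float(d[i]))
        a = WT[:, i] / np.sqrt(d[i])
        t = a @ WT
        d -= t * t
        WT = blas.dger(-1.0, a, t, a=WT, overwrite_a=1)  # WT -= a t'
        np.maximum(d, 0.0, out=d)
        d[i] = 0.0
    return picks, variances


def select_conditional(gm, k: int, mode: str = "genotype") -> CoreSubset:
    """Greedy conditional-variance core selection (deterministic).

    Starts from the animal with the largest diagonal of W W' and at each step
    picks the animal with the largest current conditional variance, then
    conditions on it.  ``mode="genotype"`` updates the centred marker matrix
    W <- W - W a' a with a = w/||w|| and reads conditional variances off the
    row squared norms; ``mode="covariance"`` updates the n x n covariance
    C <- C - C e (e'Ce)^-1 e'C directly.  The two routes return identical
    subsets; the covariance route is kept as the small-n testing oracle.
    """
    n = len(gm.ids)
    if not 1 <= k <= n:
        raise ValidationError(f"core size k={k} outside [1, {n}]")
    if mode == "genotype":
        Wc = np.array(gm.W, dtype=float, copy=True)
        d = np.einsum("ij,ij->i", Wc, Wc)
        floor_ref = float(d.max())
        if floor_ref <= 0.0:
            raise RankExhaustedError("all centred genotypes are zero", n_selected=0)
        picks, variances = _greedy_genotype(Wc, d, k, floor_ref)
    elif mode == "covariance":
        C = np.array(gm.W, dtype=float) @ np.array(gm.W, dtype=float).T
        d = np.diag(C).copy()
        floor_ref = float(d.max())
        if floor_ref <= 0.0:
            raise RankExhaustedError("all centred genotypes are zero", n_selected=0)
        floor = VARIANCE_FLOOR * floor_ref
        picks, variances = [], []
        for step in range(k):
            i = int(np.argmax(d))
            if d[i] <= floor:
                raise RankExhaustedError(
                    f"conditional variance exhausted after {step} of {k} requested "
                    f"core animals", n_selected=step)
            picks.append(i)
            variances.append(float(d[i]))
            c = C[:, i].copy()
            C -= np.outer(c, c) / c[i]
            d = np.diag(C).copy()
            np.maximum(d, 0.0, out=d)
            d[picks] = 0.0
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return CoreSubset(core_ids=[gm.ids[i] for i in picks], method="conditional",
                      selection_variances=np.array(variances))


def select_conditional_min(gm, k: int, criterion: str = "max") -> CoreSubset:
    """Min-max / min-average extension of the conditional algorithm.

    Each pick is the candidate whose conditioning minimises the maximum
    (``criterion="max"``) or mean (``"mean"``) conditional variance of the
    other animals.  The inner loop over candidates makes this O(n) times
    slower than ``select_conditional``; it exists for small problems and as
    a point of comparison, not for production use.
    """
    if criterion not in ("max", "mean"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    n = len(gm.ids)
    if not 1 <= k <= n:
        raise ValidationError(f"core size k={k} outside [1, {n}]")
    Wc = np.array(gm.W, dtype=float, copy=True)
    d = np.einsum("ij,ij->i", Wc, Wc)
    floor_ref = float(d.max())
    if floor_ref <= 0.0:
        raise RankExhaustedError("all centred genotypes are zero", n_selected=0)
    floor = VARIANCE_FLOOR * floor_ref
    chosen = np.zeros(n, dtype=bool)
    picks: list[int] = []
    variances: list[float] = []
    for step in range(k):
        candidates = np.flatnonzero(~chosen & (d > floor))
        if candidates.size == 0:
            raise RankExhaustedError(
                f"conditional variance exhausted after {step} of {k} requested "
                f"core animals", n_selected=step)
        # among candidates with equal criterion score (e.g. animals spanning
        # the same direction), prefer the largest own conditional variance,
        # matching the base algorithm's preference for extreme animals
        best, best_score = -1, np.inf
        tol = 1e-12 * max(float(d.max()), 1.0)
        for j in candidates:
            t = Wc @ (Wc[j] / np.sqrt(d[j]))
            d_after = np.maximum(d - t * t, 0.0)
            others = ~chosen
            others[j] = False
            if not others.any():
                score = 0.0
            elif criterion == "max":
                score = float(d_after[others].max())
            else:
                score = float(d_after[others].mean())
            if score < best_score - tol or \
                    (abs(score - best_score) <= tol and d[j] > d[best] + tol):
                best, best_score = int(j), score
        picks.append(best)
        variances.append(float(d[best]))
        chosen[best] = True
        a = Wc[best] / np.sqrt(d[best])
        t = Wc @ a
        d -= t * t
        Wc -= np.outer(t, a)
        np.maximum(d, 0.0, out=d)
        d[best] = 0.0
    return CoreSubset(core_ids=[gm.ids[i] for i in picks],
                      method=f"conditional_min{'imax' if criterion == 'max' else 'avg'}",
                      selection_variances=np.array(variances))


def expand_core(old_core_W, new_W, k_new: int, *,
                old_core_ids=None, new_ids=None) -> CoreSubset:
    """Append k_new animals to an existing core when new genotype data arrive.

    The combined centred matrix ``[old core rows; new rows]`` is conditioned
    on each old core animal in its original selection order, then the greedy
    conditional loop appends ``k_new`` animals.  The old core is retained as
    a prefix of the result.  When the old core is itself a conditional-
    algorithm prefix of the combined data, this reproduces exactly what a
    fresh combined run would select.

    Both matrices must be centred on the SAME marker set and allele
    frequencies (pass the old reference frequencies to
    :func:`~apycore.relmat.build_genotype_matrix` when centring new animals).
    """
    old_core_W = np.asarray(old_core_W, dtype=float)
    new_W = np.asarray(new_W, dtype=float)
    if old_core_W.ndim != 2 or new_W.ndim != 2:
        raise ValidationError("old_core_W and new_W must be 2-D")
    if old_core_W.shape[1] != new_W.shape[1]:
        raise ValidationError(
            f"marker sets differ: old has {old_core_W.shape[1]} markers, "
            f"new has {new_W.shape[1]}")
    n_old = old_core_W.shape[0]
    if old_core_ids is None:
        old_core_ids = [f"old_{i + 1}" for i in range(n_old)]
    if new_ids is None:
        new_ids = [f"new_{i + 1}" for i in range(new_W.shape[0])]
    old_core_ids = [str(a) for a in old_core_ids]
    new_ids = [str(a) for a in new_ids]

    Wc = np.vstack([old_core_W, new_W])
    d = np.einsum("ij,ij->i", Wc, Wc)
    floor_ref = float(d.max()) if d.size else 0.0
    # condition on the old core, one animal at a time, in selection order
    for i in range(n_old):
        if d[i] <= VARIANCE_FLOOR * floor_ref:
            continue  # numerically dependent on earlier core animals
        a = Wc[i] / np.sqrt(d[i])
        t = Wc @ a
        d -= t * t
        Wc -= np.outer(t, a)
        np.maximum(d, 0.0, out=d)
        d[i] = 0.0
    if k_new == 0:
        return CoreSubset(core_ids=old_core_ids, method="conditional",
                          selection_variances=np.full(n_old, np.nan))
    forbidden = np.zeros(Wc.shape[0], dtype=bool)
    forbidden[:n_old] = True
    picks, variances = _greedy_genotype(Wc, d, k_new, floor_ref, forbidden=forbidden)
    all_ids = old_core_ids + new_ids
    return CoreSubset(
        core_ids=old_core_ids + [all_ids[i] for i in picks],
        method="conditional",
        selection_variances=np.concatenate([np.full(n_old, np.nan), variances]))


def reduced_rank(gm: GenotypeMatrix, fraction: float) -> ReducedGenotypes:
    """Reduced-rank marker matrix W_r = U_r D_r.

    ``r`` is the number of leading eigenvalues capturing ``fraction`` of the
    variation in G; W_r W_r' is the best rank-r approximation of W W', with
    approximation error trace equal to the sum of the discarded eigenvalues
    times v.  Used to speed up conditional core selection on large data.
    """
    spec = spectral(gm)
    r = core_size_for_threshold(spec, fraction)
    Wr = spec.left_vectors[:, :r] * spec.singular_values[:r]
    return ReducedGenotypes(ids=list(gm.ids), W=Wr, v=gm.v)
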