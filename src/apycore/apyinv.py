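"""APY sparse inverse of the genomic relationship matrix.

With genotyped animals split into core (c) and non-core (n) subsets, the APY
inverse is

    G_APY^-1 = [[Gcc^-1, 0], [0, 0]]
             + [[-Gcc^-1 Gcn], [I]] Mnn^-1 [[-Gnc Gcc^-1, I]],

where Mnn is diagonal with entries g_ii - g_ic Gcc^-1 g_ci (the conditional
variance of each non-core animal given the core).  Only Gcc is densely
inverted; non-core animals are conditionally independent given the core, so
the non-core block of the inverse is diagonal apart from terms flowing
through the core.  The inverse is stored in factored blocks and assembled
densely (or streamed as triplets) only on demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .coreselect import CoreSubset
from .errors import FactorizationError, ValidationError
from .relmat import RelationshipMatrix

__all__ = ["APYInverse", "mnn_diagonal", "apy_inverse", "implied_G_apy", "full_inverse"]


def _chol(A: np.ndarray, what: str):
    """Cholesky factor, failure is an error — never a silent pseudo-inverse."""
    try:
        return scipy.linalg.cho_factor(A, lower=True)
    except scipy.linalg.LinAlgError as e:
        raise FactorizationError(f"{what} is not positive definite: {e}") from e


@dataclass
class APYInverse:
    """Factored APY inverse.

    ``cross_factor`` is -Gcc^-1 Gcn (|c| x |n|); ``Mnn`` the positive
    diagonal of non-core conditional variances.  ``core_idx``/``noncore_idx``
    record the permutation back to the original id order.
    """

    ids: list[str]
    core_ids: list[str]
    noncore_ids: list[str]
    core_idx: np.ndarray
    noncore_idx: np.ndarray
    Gcc_inv: np.ndarray
    cross_factor: np.ndarray
    Mnn: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """G_APY^-1 @ x without assembling the dense inverse (original id order)."""
        x = np.asarray(x, dtype=float)
        xc = x[self.core_idx]
        xn = x[self.noncore_idx]
        # t = Mnn^-1 (xn - Gnc Gcc^-1 xc) = Mnn^-1 (xn + cross_factor' xc)
        t = (xn + self.cross_factor.T @ xc) / self.Mnn
        yc = self.Gcc_inv @ xc + self.cross_factor @ t
        yn = t
        y = np.empty_like(x)
        y[self.core_idx] = yc
        y[self.noncore_idx] = yn
        return y

    def diagonal(self) -> np.ndarray:
        """Diagonal of G_APY^-1 in the original id order (for preconditioning)."""
        F = self.cross_factor
        Minv = 1.0 / self.Mnn
        out = np.empty(self.n)
        out[self.core_idx] = np.diag(self.Gcc_inv) + np.einsum("ij,ij->i", F * Minv, F)
        out[self.noncore_idx] = Minv
        return out

    def to_dense(self) -> np.ndarray:
        """Assemble the dense inverse in the original id order."""
        nc = len(self.core_ids)
        n = self.n
        out = np.zeros((n, n))
        F = self.cross_factor                      # -Gcc^-1 Gcn
        Minv = 1.0 / self.Mnn
        cc = self.Gcc_inv + (F * Minv) @ F.T
        cn = F * Minv
        ci, ni = self.core_idx, self.noncore_idx
        out[np.ix_(ci, ci)] = cc
        out[np.ix_(ci, ni)] = cn
        out[np.ix_(ni, ci)] = cn.T
        out[np.ix_(ni, ni)] = np.diag(Minv) if nc < n else np.zeros((0, 0))
        return out

    def triplets(self):
        """Yield lower-triangle (i, j, value) triplets, 1-based, original id order.

        Structural zeros of the non-core x non-core block are not emitted —
        the whole point of APY is that this block is diagonal.
        """
        nc = len(self.core_ids)
        F = self.cross_factor
        Minv = 1.0 / self.Mnn
        cc = self.Gcc_inv + (F * Minv) @ F.T
        cn = F * Minv
        ci, ni = self.core_idx, self.noncore_idx
        for a in range(nc):
            for b in range(a + 1):
                i, j = int(ci[a]), int(ci[b])
                yield (max(i, j) + 1, min(i, j) + 1, float(cc[a, b]))
        for a in range(nc):
            for b in range(len(ni)):
                i, j = int(ci[a]), int(ni[b])
                yield (max(i, j) + 1, min(i, j) + 1, float(cn[a, b]))
        for b in range(len(ni)):
            i = int(ni[b])
            yield (i + 1, i + 1, float(Minv[b]))


def _partition(rm: RelationshipMatrix, core: CoreSubset | list):
    core_ids = list(core.core_ids) if isinstance(core, CoreSubset) else [str(a) for a in core]
    core_set = set(core_ids)
    if len(core_set) != len(core_ids):
        raise ValidationError("core ids are not unique")
    core_idx = rm.index_of(core_ids)
    noncore = [(i, a) for i, a in enumerate(rm.ids) if a not in core_set]
    noncore_idx = np.array([i for i, _ in noncore], dtype=int)
    noncore_ids = [a for _, a in noncore]
    return core_ids, core_idx, noncore_ids, noncore_idx


def mnn_diagonal(rm: RelationshipMatrix, core) -> np.ndarray:
    """Non-core conditional variances M_ii = g_ii - g_ic Gcc^-1 g_ci."""
    core_ids, ci, _, ni = _partition(rm, core)
    if len(core_ids) == 0:
        raise ValidationError("core subset is empty")
    Gcc = rm.G[np.ix_(ci, ci)]
    Gcn = rm.G[np.ix_(ci, ni)]
    cf = _chol(Gcc, f"core block Gcc (animals {core_ids[:5]}...)")
    S = scipy.linalg.cho_solve(cf, Gcn)            # Gcc^-1 Gcn
    diag_nn = np.diag(rm.G)[ni]
    return diag_nn - np.einsum("ij,ij->j", Gcn, S)


def apy_inverse(rm: RelationshipMatrix, core) -> APYInverse:
    """Build the factored APY inverse for a given core subset."""
    core_ids, ci, noncore_ids, ni = _partition(rm, core)
    if len(core_ids) == 0:
        raise ValidationError("core subset is empty")
    Gcc = rm.G[np.ix_(ci, ci)]
    Gcn = rm.G[np.ix_(ci, ni)]
    cf = _chol(Gcc, "core block Gcc")
    S = scipy.linalg.cho_solve(cf, Gcn)            # Gcc^-1 Gcn
    Mnn = np.diag(rm.G)[ni] - np.einsum("ij,ij->j", Gcn, S)
    if (Mnn <= 0).any():
        bad = [noncore_ids[i] for i in np.flatnonzero(Mnn <= 0)[:5]]
        raise FactorizationError(
            f"non-positive conditional variance M_nn for non-core animals {bad}; "
            "is G blended/positive definite?")
    Gcc_inv = scipy.linalg.cho_solve(cf, np.eye(len(core_ids)))
    Gcc_inv = 0.5 * (Gcc_inv + Gcc_inv.T)
    return APYInverse(ids=list(rm.ids), core_ids=core_ids, noncore_ids=noncore_ids,
                      core_idx=ci, noncore_idx=ni, Gcc_inv=Gcc_inv,
                      cross_factor=-S, Mnn=Mnn)


def implied_G_apy(rm: RelationshipMatrix, core) -> np.ndarray:
    """The relationship matrix whose exact inverse the APY formula produces.

    Equals G with the non-core block replaced by Gnc Gcc^-1 Gcn + diag(Mnn):
    off-diagonal non-core relationships are approximated by what flows
    through the core.  Testing oracle; returned in the original id order.
    """
    core_ids, ci, _, ni = _partition(rm, core)
    if len(core_ids) == 0:
        raise ValidationError("core subset is empty")
    Gcc = rm.G[np.ix_(ci, ci)]
    Gcn = rm.G[np.ix_(ci, ni)]
    cf = _chol(Gcc, "core block Gcc")
    S = scipy.linalg.cho_solve(cf, Gcn)
    nn = Gcn.T @ S
    Mnn = np.diag(rm.G)[ni] - np.diag(nn)
    nn[np.diag_indices_from(nn)] += Mnn
    out = rm.G.copy()
    out[np.ix_(ni, ni)] = nn
    return 0.5 * (out + out.T)


def full_inverse(rm: RelationshipMatrix) -> np.ndarray:
    """Dense symmetric inverse of G via Cholesky (the baseline)."""
    cf = _chol(rm.G, "G")
    inv = scipy.linalg.cho_solve(cf, np.eye(rm.n))
    return 0.5 * (inv + inv.T)
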