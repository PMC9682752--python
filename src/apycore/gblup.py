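"""GBLUP via Henderson's mixed model equations.

Supports the two model forms used for genomic evaluation here:

    y = 1 mu + Za a + e                    (simulated cattle analysis)
    y = X b + Za a + Zl l + e              (fixed effects + litter effect)

with a ~ N(0, G sigma2_a), l ~ N(0, I sigma2_l), e ~ N(0, I sigma2_e).
Variance components are supplied, never estimated.  The inverse relationship
operator K^-1 may be the dense full inverse or a factored APY inverse; the
MME are solved either directly (Cholesky) or with a Jacobi-preconditioned
conjugate gradient, and breeding values are returned for every animal in the
relationship matrix, phenotyped or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse.linalg

from .apyinv import APYInverse
from .errors import (ConvergenceError, FactorizationError, UndefinedStatisticError,
                     ValidationError)

__all__ = [
    "ModelSpec",
    "MMESystem",
    "GEBVResult",
    "ValidationReport",
    "build_mme",
    "solve",
    "adjusted_phenotypes",
    "validation_report",
    "topk_overlap",
]


@dataclass
class ModelSpec:
    """Model description for one GBLUP fit.

    ``fixed_terms`` are categorical phenotype-table columns (an intercept is
    always included; the first level of each term is dropped for
    identifiability).  ``kinv`` is the inverse relationship operator over
    ``animal_ids`` — a dense ndarray or an :class:`~apycore.apyinv.APYInverse`.
    ``extra_random`` names an i.i.d. random term column (e.g. litter).
    """

    animal_ids: list[str]
    kinv: object
    va: float
    ve: float
    fixed_terms: list[str] = field(default_factory=list)
    extra_random: str | None = None
    vl: float | None = None

    def __post_init__(self):
        if self.va <= 0 or self.ve <= 0:
            raise ValidationError("variances sigma2_a and sigma2_e must be > 0")
        if self.extra_random is not None and (self.vl is None or self.vl <= 0):
            raise ValidationError("extra_random term requires sigma2_l > 0")


@dataclass
class MMESystem:
    """Assembled mixed model equations.

    Unknown order: fixed effects, then one breeding value per animal in
    ``animal_ids``, then extra-random levels.
    """

    spec: ModelSpec
    X: np.ndarray
    fixed_names: list[str]
    Z: np.ndarray
    Zl: np.ndarray | None
    extra_levels: list
    y: np.ndarray
    rhs: np.ndarray

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_animals(self) -> int:
        return len(self.spec.animal_ids)

    @property
    def n_extra(self) -> int:
        return 0 if self.Zl is None else self.Zl.shape[1]

    @property
    def size(self) -> int:
        return self.n_fixed + self.n_animals + self.n_extra

    def _kinv_dense(self) -> np.ndarray:
        k = self.spec.kinv
        return k.to_dense() if isinstance(k, APYInverse) else np.asarray(k, dtype=float)

    def _kinv_matvec(self, x: np.ndarray) -> np.ndarray:
        k = self.spec.kinv
        return k.matvec(x) if isinstance(k, APYInverse) else np.asarray(k) @ x

    def _kinv_diag(self) -> np.ndarray:
        k = self.spec.kinv
        return k.diagonal() if isinstance(k, APYInverse) else np.diag(np.asarray(k))

    @property
    def lambda_a(self) -> float:
        return self.spec.ve / self.spec.va

    @property
    def lambda_l(self) -> float:
        return self.spec.ve / self.spec.vl

    def dense(self) -> np.ndarray:
        """Assemble the dense symmetric coefficient matrix."""
        nf, na, ne = self.n_fixed, self.n_animals, self.n_extra
        A = np.zeros((self.size, self.size))
        X, Z = self.X, self.Z
        A[:nf, :nf] = X.T @ X
        A[:nf, nf:nf + na] = X.T @ Z
        A[nf:nf + na, :nf] = A[:nf, nf:nf + na].T
        A[nf:nf + na, nf:nf + na] = Z.T @ Z + self._kinv_dense() * self.lambda_a
        if ne:
            Zl = self.Zl
            A[:nf, nf + na:] = X.T @ Zl
            A[nf + na:, :nf] = A[:nf, nf + na:].T
            A[nf:nf + na, nf + na:] = Z.T @ Zl
            A[nf + na:, nf:nf + na] = A[nf:nf + na, nf + na:].T
            A[nf + na:, nf + na:] = Zl.T @ Zl + np.eye(ne) * self.lambda_l
        return A

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """Coefficient-matrix product without densifying K^-1."""
        nf, na, ne = self.n_fixed, self.n_animals, self.n_extra
        xf, xa = x[:nf], x[nf:nf + na]
        xl = x[nf + na:] if ne else None
        fit = self.X @ xf + self.Z @ xa
        if ne:
            fit = fit + self.Zl @ xl
        out = np.empty_like(x)
        out[:nf] = self.X.T @ fit
        out[nf:nf + na] = self.Z.T @ fit + self.lambda_a * self._kinv_matvec(xa)
        if ne:
            out[nf + na:] = self.Zl.T @ fit + self.lambda_l * xl
        return out

    def diag(self) -> np.ndarray:
        nf, na, ne = self.n_fixed, self.n_animals, self.n_extra
        d = np.empty(self.size)
        d[:nf] = np.einsum("ij,ij->j", self.X, self.X)
        d[nf:nf + na] = np.einsum("ij,ij->j", self.Z, self.Z) \
            + self.lambda_a * self._kinv_diag()
        if ne:
            d[nf + na:] = np.einsum("ij,ij->j", self.Zl, self.Zl) + self.lambda_l
        return d


@dataclass
class GEBVResult:
    fixed_solutions: pd.Series
    gebv: pd.Series
    extra_random_solutions: pd.Series | None
    solver_report: dict


@dataclass
class ValidationReport:
    corr_full_apy: float | None = None
    accuracy: float | None = None
    predictive_ability: float | None = None
    dispersion_slope: float | None = None
    topk_overlap: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _design_categorical(values: pd.Series, term: str):
    """Reference-level dummy coding: first (sorted) level dropped."""
    levels = sorted(pd.unique(values.astype(str)))
    cols = np.column_stack([(values.astype(str) == lv).to_numpy(float)
                            for lv in levels[1:]]) if len(levels) > 1 \
        else np.empty((len(values), 0))
    names = [f"{term}={lv}" for lv in levels[1:]]
    return cols, names


def build_mme(spec: ModelSpec, data: pd.DataFrame) -> MMESystem:
    """Assemble the MME for phenotype table ``data`` (columns: id, y, terms).

    Every phenotyped animal must appear in ``spec.animal_ids``; animals in
    the relationship matrix without phenotypes simply get zero incidence and
    receive GEBV through the K^-1 coupling.
    """
    for col in ("id", "y"):
        if col not in data.columns:
            raise ValidationError(f"phenotype table lacks required column {col!r}")
    y = data["y"].to_numpy(float)
    n_obs = len(data)

    blocks = [np.ones((n_obs, 1))]
    names = ["intercept"]
    for term in spec.fixed_terms:
        if term not in data.columns:
            raise ValidationError(f"fixed term {term!r} not in phenotype table")
        cols, cnames = _design_categorical(data[term], term)
        blocks.append(cols)
        names.extend(cnames)
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            f"fixed-effect design is rank deficient (confounded levels among {names})")

    pos = {a: i for i, a in enumerate(spec.animal_ids)}
    try:
        col_idx = np.array([pos[str(a)] for a in data["id"]], dtype=int)
    except KeyError as e:
        raise ValidationError(
            f"phenotyped animal {e.args[0]!r} has no genotype/relationship entry") from None
    Z = np.zeros((n_obs, len(spec.animal_ids)))
    Z[np.arange(n_obs), col_idx] = 1.0

    Zl, levels = None, []
    if spec.extra_random is not None:
        if spec.extra_random not in data.columns:
            raise ValidationError(f"random term {spec.extra_random!r} not in table")
        levels = sorted(pd.unique(data[spec.extra_random].astype(str)))
        lpos = {lv: i for i, lv in enumerate(levels)}
        Zl = np.zeros((n_obs, len(levels)))
        Zl[np.arange(n_obs),
           [lpos[str(v)] for v in data[spec.extra_random]]] = 1.0

    nf, na = X.shape[1], len(spec.animal_ids)
    rhs = np.empty(nf + na + (0 if Zl is None else Zl.shape[1]))
    rhs[:nf] = X.T @ y
    rhs[nf:nf + na] = Z.T @ y
    if Zl is not None:
        rhs[nf + na:] = Zl.T @ y
    return MMESystem(spec=spec, X=X, fixed_names=names, Z=Z, Zl=Zl,
                     extra_levels=levels, y=y, rhs=rhs)


def solve(system: MMESystem, method: str = "direct", tol: float = 1e-12,
          max_iter: int = 5000) -> GEBVResult:
    """Solve the MME.

    ``direct`` uses a dense Cholesky factorisation of the coefficient matrix
    (which is symmetric positive definite when the fixed design has full
    rank).  ``pcg`` uses Jacobi-preconditioned conjugate gradient to relative
    residual ``tol`` (default 1e-12) without densifying K^-1.
    """
    if method == "direct":
        A = system.dense()
        try:
            cf = scipy.linalg.cho_factor(A, lower=True)
        except scipy.linalg.LinAlgError as e:
            raise FactorizationError(f"MME coefficient matrix not positive definite: {e}") from e
        sol = scipy.linalg.cho_solve(cf, system.rhs)
        res = float(np.linalg.norm(A @ sol - system.rhs) / np.linalg.norm(system.rhs))
        report = {"method": "direct", "iterations": 1, "residual": res}
    elif method == "pcg":
        op = scipy.sparse.linalg.LinearOperator(
            (system.size, system.size), matvec=system.matvec, dtype=float)
        d = system.diag()
        if (d <= 0).any():
            raise FactorizationError("non-positive diagonal in MME; cannot precondition")
        M = scipy.sparse.linalg.LinearOperator(
            (system.size, system.size), matvec=lambda x: x / d, dtype=float)
        trace: list[float] = []
        bnorm = np.linalg.norm(system.rhs)

        def cb(xk):
            trace.append(float(np.linalg.norm(system.matvec(xk) - system.rhs) / bnorm))

        sol, info = scipy.sparse.linalg.cg(op, system.rhs, rtol=tol, atol=0.0,
                                           maxiter=max_iter, M=M, callback=cb)
        if info != 0:
            raise ConvergenceError(
                f"PCG did not reach tol={tol:g} in {max_iter} iterations "
                f"(last residual {trace[-1] if trace else float('nan'):.3e})",
                residuals=trace)
        report = {"method": "pcg", "iterations": len(trace),
                  "residual": trace[-1] if trace else 0.0}
    else:
        raise ValidationError(f"unknown solver method {method!r}")

    nf, na = system.n_fixed, system.n_animals
    fixed = pd.Series(sol[:nf], index=system.fixed_names)
    gebv = pd.Series(sol[nf:nf + na], index=[str(a) for a in system.spec.animal_ids])
    extra = None
    if system.n_extra:
        extra = pd.Series(sol[nf + na:], index=system.extra_levels)
    return GEBVResult(fixed_solutions=fixed, gebv=gebv,
                      extra_random_solutions=extra, solver_report=report)


def adjusted_phenotypes(system: MMESystem, result: GEBVResult) -> np.ndarray:
    """Phenotypes adjusted for the fitted fixed effects: y - X b_hat."""
    return system.y - system.X @ result.fixed_solutions.to_numpy()


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedStatisticError("correlation undefined for a zero-variance vector")
    return float(np.corrcoef(a, b)[0, 1])


def topk_overlap(gebv_a, gebv_b, k: int, ids=None) -> int:
    """Shared animals between the top-k rankings of two GEBV vectors.

    Ties are broken by animal id (ascending) for repeatability.
    """
    a = np.asarray(gebv_a, dtype=float)
    b = np.asarray(gebv_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("GEBV vectors are not aligned")
    if not 0 < k <= a.size:
        raise ValidationError(f"k={k} outside [1, {a.size}]")
    if ids is None:
        ids = np.arange(a.size)
    ids = np.asarray(ids)
    top_a = set(ids[np.lexsort((ids, -a))[:k]].tolist())
    top_b = set(ids[np.lexsort((ids, -b))[:k]].tolist())
    return len(top_a & top_b)


def validation_report(gebv_a, gebv_b=None, tbv=None, adjusted_y=None,
                      k: int | None = None, ids=None) -> ValidationReport:
    """Validation statistics for a GEBV vector (``gebv_b`` if given, else ``gebv_a``).

    * ``corr_full_apy``: Pearson correlation of the two GEBV vectors;
    * ``accuracy``: correlation of the evaluated GEBV with true breeding values;
    * ``predictive_ability``: correlation with fixed-effect-adjusted phenotypes;
    * ``dispersion_slope``: regression of adjusted phenotypes on GEBV,
      cov(y_adj, gebv)/var(gebv) — a slope below 1 signals inflated GEBV;
    * ``topk_overlap``: shared animals in the two top-k rankings.

    All vectors must be aligned on the same animals by the caller.
    """
    a = np.asarray(gebv_a, dtype=float)
    evaluated = a if gebv_b is None else np.asarray(gebv_b, dtype=float)
    rep = ValidationReport()
    if gebv_b is not None:
        rep.corr_full_apy = _corr(a, evaluated)
        if k is not None:
            rep.topk_overlap = topk_overlap(a, evaluated, k, ids=ids)
    if tbv is not None:
        rep.accuracy = _corr(evaluated, np.asarray(tbv, dtype=float))
    if adjusted_y is not None:
        ya = np.asarray(adjusted_y, dtype=float)
        rep.predictive_ability = _corr(evaluated, ya)
        var = float(np.var(evaluated, ddof=1))
        if var == 0:
            raise UndefinedStatisticError("dispersion slope undefined: zero-variance GEBV")
        cov = float(np.cov(ya, evaluated, ddof=1)[0, 1])
        rep.dispersion_slope = cov / var
    return rep
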