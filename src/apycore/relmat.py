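"""Genomic relationship matrices and their spectrum.

Builds the centred marker matrix ``W`` and the VanRaden genomic relationship
matrix ``G = W W' / v`` with ``v = 2 * sum_j p_j (1 - p_j)``, optionally blended
with the identity to guarantee positive definiteness.  The spectrum of the
(unblended) ``G`` is obtained through the SVD of the n x m matrix ``W`` rather
than the n x n eigenproblem, and is used to size APY core subsets by
captured-variance thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import DegenerateDataError, InvalidGenotypeError, ValidationError

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "SpectralSummary",
    "build_genotype_matrix",
    "build_grm",
    "spectral",
    "core_size_for_threshold",
    "realised_variation",
    "pca_coordinates",
]

_EIG_CLAMP = -1e-10


@dataclass
class GenotypeMatrix:
    """Marker data for n individuals at m biallelic sites.

    Attributes
    ----------
    ids : list of str
        Ordered individual identifiers.
    counts : (n, m) ndarray
        Alternative-allele counts coded 0/1/2.
    p : (m,) ndarray
        Alternative-allele frequency per marker, in [0, 1].
    W : (n, m) ndarray
        Centred matrix, ``counts - 2 p`` per column.
    v : float
        Scaling constant ``2 * sum_j p_j (1 - p_j)``.
    """

    ids: list[str]
    counts: np.ndarray
    p: np.ndarray
    W: np.ndarray
    v: float

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    def index_of(self, ids) -> np.ndarray:
        """Positions of ``ids`` in this matrix's ordering."""
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown individual id: {e.args[0]!r}") from None


@dataclass
class RelationshipMatrix:
    """Symmetric genomic relationship matrix with blending provenance."""

    ids: list[str]
    G: np.ndarray
    blended: bool = False
    blend_weight: float = 0.0
    blend_mode: str = "weighted"

    @property
    def n(self) -> int:
        return self.G.shape[0]

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown individual id: {e.args[0]!r}") from None


@dataclass
class SpectralSummary:
    """Spectrum of the unblended G, from the SVD ``W = U D V'``.

    ``eigenvalues`` are the descending eigenvalues of ``G_raw = W W' / v``,
    i.e. squared singular values of W divided by v, clamped at zero.
    """

    eigenvalues: np.ndarray
    singular_values: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray
    total: float = field(init=False)

    def __post_init__(self):
        self.total = float(np.sum(self.eigenvalues))


def build_genotype_matrix(counts, ids=None, freqs=None) -> GenotypeMatrix:
    """Validate 0/1/2 allele counts and derive p, W and v.

    Allele frequencies are observed column means / 2 unless ``freqs`` is
    supplied (needed when centring new animals on an older reference
    population, as core-subset expansion requires).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValidationError("counts must be a 2-D individuals x markers matrix")
    n, m = counts.shape
    if ids is None:
        ids = [str(i + 1) for i in range(n)]
    else:
        ids = [str(a) for a in ids]
        if len(ids) != n:
            raise ValidationError(f"{len(ids)} ids for {n} genotype rows")
        if len(set(ids)) != n:
            raise ValidationError("duplicate individual ids")
    if not np.isfinite(counts).all():
        raise InvalidGenotypeError("missing or non-finite genotype entries")
    if not np.isin(counts, (0.0, 1.0, 2.0)).all():
        bad = counts[~np.isin(counts, (0.0, 1.0, 2.0))]
        raise InvalidGenotypeError(f"genotype entries outside {{0,1,2}}: e.g. {bad.flat[0]!r}")

    if freqs is None:
        p = counts.mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (m,):
            raise ValidationError(f"freqs must have length {m}")
        if (p < 0).any() or (p > 1).any():
            raise ValidationError("allele frequencies must lie in [0, 1]")

    W = counts - 2.0 * p
    v = float(2.0 * np.sum(p * (1.0 - p)))
    if v <= 0.0:
        raise DegenerateDataError("all markers are monomorphic (v = 0)")
    return GenotypeMatrix(ids=ids, counts=counts, p=p, W=W, v=v)


def build_grm(gm: GenotypeMatrix, blend_weight: float = 0.01,
              blend_mode: str = "weighted") -> RelationshipMatrix:
    """VanRaden G from the centred marker matrix, blended with the identity.

    ``weighted`` blending returns ``(1 - w) * G_raw + w * I`` (default,
    w = 0.01); ``additive`` returns ``G_raw + w * I``.  Either guarantees
    positive definiteness for w > 0.
    """
    if gm.v <= 0:
        raise DegenerateDataError("cannot build a GRM from monomorphic data (v = 0)")
    if not 0.0 <= blend_weight < 1.0:
        raise ValidationError("blend_weight must lie in [0, 1)")
    if blend_mode not in ("weighted", "additive"):
        raise ValidationError(f"unknown blend_mode {blend_mode!r}")
    G = gm.W @ gm.W.T / gm.v
    if blend_weight > 0.0:
        if blend_mode == "weighted":
            G *= 1.0 - blend_weight
        G[np.diag_indices_from(G)] += blend_weight
    # enforce exact symmetry against accumulated rounding
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(ids=list(gm.ids), G=G, blended=blend_weight > 0.0,
                              blend_weight=blend_weight, blend_mode=blend_mode)


def spectral(gm: GenotypeMatrix) -> SpectralSummary:
    """Spectrum of the unblended G via the thin SVD of W (never the n x n eigenproblem)."""
    if gm.v <= 0:
        raise DegenerateDataError("spectral analysis requires v > 0")
    U, D, Vt = scipy.linalg.svd(gm.W, full_matrices=False)
    eig = D ** 2 / gm.v
    eig[(eig < 0) & (eig > _EIG_CLAMP)] = 0.0
    return SpectralSummary(eigenvalues=eig, singular_values=D,
                           left_vectors=U, right_vectors=Vt.T)


def core_size_for_threshold(spec: SpectralSummary, fraction: float) -> int:
    """Smallest k with (sum of the k largest eigenvalues) / total >= fraction."""
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must lie in (0, 1]")
    eig = np.asarray(spec.eigenvalues, dtype=float)
    if eig.size == 0 or spec.total <= 0:
        raise ValidationError("empty spectrum")
    cum = np.cumsum(eig) / spec.total
    # guard against cum[-1] = 1 - eps never reaching fraction = 1.0
    cum[-1] = max(cum[-1], 1.0)
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def realised_variation(rm: RelationshipMatrix, core_ids) -> float:
    """trace(G_cc) / trace(G): share of relationship variance carried by the core.

    Returns 0.0 for an empty core (empty-sum convention).
    """
    core_ids = list(core_ids)
    if len(core_ids) == 0:
        return 0.0
    idx = rm.index_of(core_ids)
    diag = np.diag(rm.G)
    return float(diag[idx].sum() / diag.sum())


def pca_coordinates(gm: GenotypeMatrix, dims: int):
    """Classical PCA coordinates of individuals: first ``dims`` columns of U D.

    Returns ``(coords, captured)`` where ``captured[k]`` is the fraction of
    total marker variance carried by axis k.
    """
    spec = spectral(gm)
    rank = int(np.sum(spec.singular_values > spec.singular_values[0] * 1e-12)) \
        if spec.singular_values.size else 0
    if dims < 1 or dims > rank:
        raise ValidationError(f"dims must lie in [1, rank={rank}]")
    coords = spec.left_vectors[:, :dims] * spec.singular_values[:dims]
    captured = spec.eigenvalues[:dims] / spec.total
    return coords, captured
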