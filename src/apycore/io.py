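"""Readers and writers for the plain-text formats the tool exchanges.

Genotypes come in either a PLINK ``.raw``-style dialect (header row
``FID IID PAT MAT SEX PHENOTYPE`` followed by one 0/1/2 column per marker)
or a plain delimited matrix whose first column is the individual id.
Relationship matrices and their inverses are written densely (small n) or as
sparse lower-triangle ``i j value`` triplets with 1-based indices in the
original id order, the convention common BLUP solvers expect.  Core subsets
are one id per line with ``#`` metadata comments.  All user-facing indices
are 1-based.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from .coreselect import CoreSubset
from .errors import InvalidGenotypeError, ValidationError
from .relmat import GenotypeMatrix, RelationshipMatrix, build_genotype_matrix

__all__ = [
    "read_plink_raw", "write_plink_raw",
    "read_genotype_table", "write_genotype_table",
    "read_grm_dense", "write_grm_dense", "write_grm_triplets",
    "write_apy_triplets",
    "read_core", "write_core",
    "read_phenotypes", "write_gebv", "write_report",
    "load_config",
]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_plink_raw(path, freqs=None) -> GenotypeMatrix:
    """PLINK .raw dialect: whitespace-delimited, IID is the individual id."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _PLINK_META if c not in df.columns]
    if missing:
        raise ValidationError(f"not a PLINK .raw file: missing columns {missing}")
    markers = [c for c in df.columns if c not in _PLINK_META]
    if not markers:
        raise ValidationError("PLINK .raw file has no marker columns")
    block = df[markers]
    if block.isna().any().any():
        raise InvalidGenotypeError("missing genotypes (NA) are not supported")
    return build_genotype_matrix(block.to_numpy(), ids=df["IID"].astype(str).tolist(),
                                 freqs=freqs)


def write_plink_raw(path, counts, ids, marker_names=None):
    counts = np.asarray(counts)
    if marker_names is None:
        marker_names = [f"snp_{j + 1}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts.astype(int), columns=marker_names)
    for col, val in zip(reversed(_PLINK_META),
                        [-9, 0, 0, 0, [str(a) for a in ids], [str(a) for a in ids]]):
        df.insert(0, col, val)
    df.to_csv(path, sep=" ", index=False)


def read_genotype_table(path, sep="\t", freqs=None) -> GenotypeMatrix:
    """Plain delimited matrix: first column individual id, then one column per marker."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValidationError("genotype table needs an id column plus marker columns")
    ids = df.iloc[:, 0].astype(str).tolist()
    block = df.iloc[:, 1:]
    if block.isna().any().any():
        raise InvalidGenotypeError("missing genotypes are not supported")
    return build_genotype_matrix(block.to_numpy(), ids=ids, freqs=freqs)


def write_genotype_table(path, counts, ids, marker_names=None, sep="\t"):
    counts = np.asarray(counts)
    if marker_names is None:
        marker_names = [f"snp_{j + 1}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts.astype(int), columns=marker_names)
    df.insert(0, "id", [str(a) for a in ids])
    df.to_csv(path, sep=sep, index=False)


def write_grm_dense(path, rm: RelationshipMatrix, sep="\t"):
    df = pd.DataFrame(rm.G, columns=rm.ids)
    df.insert(0, "id", rm.ids)
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_grm_dense(path, sep="\t") -> RelationshipMatrix:
    df = pd.read_csv(path, sep=sep)
    ids = df.iloc[:, 0].astype(str).tolist()
    G = df.iloc[:, 1:].to_numpy(float)
    if G.shape[0] != G.shape[1]:
        raise ValidationError("dense GRM file is not square")
    return RelationshipMatrix(ids=ids, G=0.5 * (G + G.T))


def write_grm_triplets(path, rm: RelationshipMatrix):
    """Sparse lower-triangle text triplets 'i j value', 1-based."""
    with open(path, "w") as fh:
        for i in range(rm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1} {j + 1} {rm.G[i, j]:.10g}\n")


def write_apy_triplets(path, apy):
    """Assembled APY inverse as lower-triangle triplets in original id order."""
    with open(path, "w") as fh:
        for i, j, val in apy.triplets():
            fh.write(f"{i} {j} {val:.10g}\n")


def write_core(path, core: CoreSubset, **meta):
    with open(path, "w") as fh:
        fh.write(f"# method: {core.method}\n")
        fh.write(f"# k: {core.k}\n")
        if core.seed is not None:
            fh.write(f"# seed: {core.seed}\n")
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        for a in core.core_ids:
            fh.write(f"{a}\n")


def read_core(path) -> CoreSubset:
    ids, meta = [], {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, val = line[1:].split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            ids.append(line)
    seed = meta.get("seed")
    return CoreSubset(core_ids=ids, method=meta.get("method", "unknown"),
                      seed=int(seed) if seed is not None else None)


def read_phenotypes(path, sep="\t") -> pd.DataFrame:
    """Delimited table with at least columns ``id`` and ``y``."""
    df = pd.read_csv(path, sep=sep)
    for col in ("id", "y"):
        if col not in df.columns:
            raise ValidationError(f"phenotype file lacks column {col!r}")
    df["id"] = df["id"].astype(str)
    return df


def write_gebv(path, result, sep="\t"):
    df = pd.DataFrame({"id": result.gebv.index, "gebv": result.gebv.values})
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def write_report(path, report: dict):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def load_config(path) -> dict:
    """Flat key-value YAML config; CLI flags take precedence over file values."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config file must be a flat key-value mapping")
    return cfg
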