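"""Plain-text persistence for pedigrees, genotypes, phenotypes and matrices.

Formats are deliberately simple: 3-column pedigree CSV (0 = unknown parent),
whitespace-delimited allele counts with a leading sire-ID column, phenotype
CSV with a header, and symmetric matrices as 1-based upper-triangle
coordinate text (i, j, value) with an ID sidecar file.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix, Pedigree, PhenotypeTable

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_matrix",
    "read_matrix",
]


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.df.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path)
    if not {"generation", "sex"}.issubset(df.columns):
        # minimal 3-column file: infer generations by parent depth, sexes by use
        df["generation"] = 0
        sires = set(df["sire"]) - {0}
        df["sex"] = np.where(df["animal"].isin(sires), "M", "F")
    return Pedigree(df)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sire_id " + " ".join(map(str, geno.snp_ids)) + "\n")
        for i, a in enumerate(geno.ids):
            fh.write(str(a) + " " + " ".join(map(str, geno.X[i])) + "\n")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        snp_ids = np.array(header[1:])
        ids, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(int(parts[0]))
            rows.append([int(v) for v in parts[1:]])
    return GenotypeMatrix(np.array(ids), snp_ids, np.array(rows, dtype=np.int8))


def write_phenotypes(phenos: PhenotypeTable, path: str | Path) -> None:
    phenos.df.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path))


def write_matrix(M: np.ndarray, ids, path: str | Path) -> None:
    """Upper-triangle coordinate text plus an ``<path>.ids`` sidecar."""
    path = Path(path)
    iu = np.triu_indices(M.shape[0])
    with open(path, "w") as fh:
        for i, j in zip(*iu):
            v = M[i, j]
            if v != 0.0:
                fh.write(f"{i + 1} {j + 1} {v!r}\n")
    with open(path.with_suffix(path.suffix + ".ids"), "w") as fh:
        fh.write("\n".join(map(str, ids)) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    ids = np.array(
        [int(x) for x in path.with_suffix(path.suffix + ".ids").read_text().split()]
    )
    n = len(ids)
    M = np.zeros((n, n))
    with open(path) as fh:
        for line in fh:
            i, j, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            M[i, j] = M[j, i] = float(v)
    return M, ids
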