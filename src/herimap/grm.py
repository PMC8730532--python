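"""Genotype standardization, the genetic relationship matrix, and ancestry PCs.

The GRM is A = W W' / M over standardized dosages
w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)), with the alt-allele frequency
p_j estimated from the sample itself (GCTA's default behavior; no external
reference panel). With missing calls, entry (k, l) is averaged over the
variants observed in both samples (pairwise-complete denominator), which
coincides with W W' / M on complete data.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "GRM",
    "CovariateMatrix",
    "standardize_genotypes",
    "compute_grm",
    "grm_pca",
    "make_covariates",
    "prune_related",
    "write_gcta_grm",
    "read_gcta_grm",
]


@dataclass
class GRM:
    values: np.ndarray  # N x N symmetric
    samples: list[str]
    pair_snp_counts: np.ndarray  # N x N, variants contributing to each entry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("GRM not symmetric")
        if (np.diag(self.values) <= 0).any():
            raise ValueError("GRM diagonal entries must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class CovariateMatrix:
    """Fixed-effect design matrix; always carries an intercept column."""

    values: np.ndarray  # N x C
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("covariate shape/name mismatch")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("covariate matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path, samples: list[str]) -> None:
        df = pd.DataFrame(self.values, index=samples, columns=self.names)
        df.index.name = "sample"
        df.to_csv(path, sep="\t", float_format="%.10g")


def standardize_genotypes(g: GenotypeMatrix) -> np.ndarray:
    """Center and scale each variant; missing dosages impute to the mean (0).

    Raises if any variant is monomorphic over its observed calls (QC should
    have removed those).
    """
    p = g.alt_freq()
    mono = ~((p > 0) & (p < 1))
    if mono.any():
        bad = g.variants[int(np.flatnonzero(mono)[0])].id
        raise ValueError(f"monomorphic variant {bad}: cannot standardize")
    w = (g.dosages - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return np.nan_to_num(w, nan=0.0)


def compute_grm(g: GenotypeMatrix) -> GRM:
    """A_kl = (1/M_kl) sum_j w_kj w_lj over variants observed in both samples."""
    w = standardize_genotypes(g)
    observed = (~np.isnan(g.dosages)).astype(float)
    counts = observed @ observed.T
    if (counts == 0).any():
        raise ValueError("sample pair with zero jointly observed variants")
    values = (w @ w.T) / counts
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return GRM(values, list(g.samples), counts.astype(np.int64))


def grm_pca(a: GRM, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenvectors of the GRM as population-structure PCs.

    Returns ``(eigenvalues, eigenvectors)`` with columns ordered by
    descending eigenvalue (ties broken by original eigh index), unit norm,
    sign fixed so each column's largest-magnitude element is positive.
    """
    if k >= a.n_samples:
        raise ValueError(f"k = {k} must be < N = {a.n_samples}")
    evals, evecs = np.linalg.eigh(a.values)
    order = np.argsort(-evals, kind="stable")[:k]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return evals, evecs


def make_covariates(
    covariates: pd.DataFrame | None,
    pcs: np.ndarray | None = None,
    n_samples: int | None = None,
) -> CovariateMatrix:
    """Assemble intercept + observed covariates + ancestry PCs."""
    blocks = []
    names = ["intercept"]
    if covariates is not None:
        n_samples = len(covariates)
        blocks.append(covariates.to_numpy(dtype=float))
        names += [str(c) for c in covariates.columns]
    if pcs is not None:
        n_samples = pcs.shape[0] if n_samples is None else n_samples
        blocks.append(np.asarray(pcs, dtype=float))
        names += [f"PC{i + 1}" for i in range(pcs.shape[1])]
    if n_samples is None:
        raise ValueError("cannot infer sample count")
    values = np.column_stack([np.ones(n_samples)] + blocks) if blocks else np.ones((n_samples, 1))
    return CovariateMatrix(values, names)


def prune_related(a: GRM, threshold: float = 0.25) -> np.ndarray:
    """Greedily drop one member of each pair with relatedness > threshold.

    Returns indices of retained samples. For every flagged pair the member
    with the larger number of remaining flagged partners is dropped first
    (ties: larger index), a common greedy heuristic for relatedness pruning.
    """
    n = a.n_samples
    off = a.values.copy()
    np.fill_diagonal(off, 0.0)
    flagged = off > threshold
    keep = np.ones(n, dtype=bool)
    while True:
        degree = (flagged & keep[None, :] & keep[:, None]).sum(axis=1)
        if degree.max(initial=0) == 0:
            break
        drop = int(np.flatnonzero(degree == degree.max())[-1])
        keep[drop] = False
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# GCTA binary GRM format (.grm.bin / .grm.N.bin / .grm.id) and TSV
# ---------------------------------------------------------------------------

def write_gcta_grm(a: GRM, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = a.n_samples
    tril = [(i, j) for i in range(n) for j in range(i + 1)]
    vals = np.array([a.values[i, j] for i, j in tril], dtype="<f4")
    counts = np.array([a.pair_snp_counts[i, j] for i, j in tril], dtype="<f4")
    Path(str(prefix) + ".grm.bin").write_bytes(vals.tobytes())
    Path(str(prefix) + ".grm.N.bin").write_bytes(counts.tobytes())
    with Path(str(prefix) + ".grm.id").open("w") as fh:
        for s in a.samples:
            fh.write(f"{s}\t{s}\n")


def read_gcta_grm(prefix) -> GRM:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in Path(str(prefix) + ".grm.id").read_text().splitlines() if line.strip()]
    n = len(ids)
    n_pairs = n * (n + 1) // 2
    vals = np.frombuffer(Path(str(prefix) + ".grm.bin").read_bytes(), dtype="<f4")
    counts = np.frombuffer(Path(str(prefix) + ".grm.N.bin").read_bytes(), dtype="<f4")
    if len(vals) != n_pairs:
        raise ValueError(f"{prefix}.grm.bin holds {len(vals)} values, expected {n_pairs}")
    values = np.zeros((n, n))
    cts = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1):
            values[i, j] = values[j, i] = vals[k]
            cts[i, j] = cts[j, i] = counts[k] if k < len(counts) else 0
            k += 1
    return GRM(values, ids, cts.astype(np.int64))


def write_grm_tsv(a: GRM, path) -> None:
    df = pd.DataFrame(a.values, index=a.samples, columns=a.samples)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.10g")
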