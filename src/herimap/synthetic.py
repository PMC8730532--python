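"""Synthetic genotypes, covariates, and voxel phenotypes with known truth.

Genotypes use a family-block design: each block shares two simulated
parents, so within-block pairs are full siblings (expected relatedness
0.5) and across-block pairs are unrelated. Blocks widen the GRM eigenvalue
spread, which keeps desk-scale heritability recovery tests tight; this is a
test-design choice, not a claim about any particular cohort.

Voxel phenotypes follow the variance-component model per voxel: inside
each spherical "blob" the genetic factor g = L z (L a matrix square root of
the GRM, z shared across the blob's voxels) contributes true_h2 of the unit
total variance; independent Gaussian noise supplies the rest. Sharing z
within a blob makes blob-average traits at least as heritable as member
voxels. Voxels outside an ellipsoidal brain mask are exactly 0 for every
subject, exercising background filtering downstream.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, VariantRecord
from .grm import compute_grm
from .voxelmap import BrainMap

__all__ = [
    "Blob",
    "SimulationDesign",
    "simulate_genotypes",
    "simulate_voxel_phenotypes",
    "make_toy_atlas",
    "default_mask",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Blob:
    """Spherical heritable signal with a soft edge.

    True heritability is ``true_h2`` inside ``radius`` and falls linearly
    to 0 over a shell of width ``taper`` — registered, upstream-smoothed
    tracer images do not have voxel-sharp effect boundaries. The blob's
    ground-truth mask is the full-signal core (distance <= radius).
    """

    center: tuple[float, float, float]
    radius: float
    true_h2: float
    taper: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_h2 <= 1.0:
            raise ValueError("true_h2 must be in [0, 1]")
        if self.taper < 0:
            raise ValueError("taper must be >= 0")


@dataclass
class SimulationDesign:
    n_samples: int = 400
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_family_blocks: int = 50
    family_block_size: int = 8
    volume_shape: tuple[int, int, int] = (16, 16, 16)
    blobs: list[Blob] = field(
        default_factory=lambda: [
            Blob(center=(5.5, 5.5, 6.5), radius=2.5, true_h2=0.8),
            Blob(center=(10.5, 10.5, 9.5), radius=2.5, true_h2=0.6),
        ]
    )
    background_h2: float = 0.0
    noise_sd: float = 1.0  # overall phenotype scale
    baseline_offset: float = 1.0  # mimics positive tracer-uptake values
    age_beta: float = 0.01
    sex_beta: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = np.array(self.volume_shape)
        for b in self.blobs:
            c = np.array(b.center)
            extent = b.radius + b.taper
            if (c - extent < 0).any() or (c + extent > shape - 1).any():
                raise ValueError(f"blob at {b.center} extends outside the volume")
        if self.n_family_blocks * self.family_block_size > self.n_samples:
            raise ValueError("family blocks exceed n_samples")


def default_mask(shape) -> np.ndarray:
    """Ellipsoidal brain-shaped mask inscribed in the volume."""
    shape = np.array(shape)
    center = (shape - 1) / 2.0
    radii = shape / 2.0 - 1.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


def simulate_genotypes(design: SimulationDesign, seed: int | None = None) -> GenotypeMatrix:
    """Draw biallelic dosages with family-block relatedness structure.

    Per variant the MAF is uniform over ``maf_range``; within a block every
    sample inherits one allele from each of two shared parental haplotype
    pairs (independently per variant), remaining samples are unrelated
    Hardy-Weinberg draws.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n, m = design.n_samples, design.n_variants
    mafs = rng.uniform(design.maf_range[0], design.maf_range[1], size=m)
    dosages = np.empty((n, m))
    row = 0
    for _ in range(design.n_family_blocks):
        haps = (rng.random((4, m)) < mafs).astype(float)  # mother x2, father x2
        for _ in range(design.family_block_size):
            mat = haps[rng.integers(0, 2, size=m), np.arange(m)]
            pat = haps[2 + rng.integers(0, 2, size=m), np.arange(m)]
            dosages[row] = mat + pat
            row += 1
    if row < n:
        dosages[row:] = (
            (rng.random((n - row, m)) < mafs).astype(float)
            + (rng.random((n - row, m)) < mafs).astype(float)
        )
    if design.missing_rate > 0:
        miss = rng.random((n, m)) < design.missing_rate
        dosages[miss] = np.nan
    samples = [f"S{i:04d}" for i in range(n)]
    variants = [
        VariantRecord(id=f"rs{j}", chrom="1", pos=j + 1, ref_allele="A",
                      alt_allele="C", maf=float(min(mafs[j], 1 - mafs[j])))
        for j in range(m)
    ]
    return GenotypeMatrix(dosages, samples, variants)


def _grm_sqrt(a: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(a)
    if evals.min() < 0:
        log.info("clipping %d negative GRM eigenvalues at 0 (min %.3g)",
                 int((evals < 0).sum()), float(evals.min()))
        evals = np.clip(evals, 0.0, None)
    return evecs * np.sqrt(evals)


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age (years) and sex (1 = male) with cohort-typical moments."""
    age = rng.normal(76.9, 7.5, size=n)
    sex = (rng.random(n) < 0.54).astype(float)
    return pd.DataFrame({"age": age, "sex": sex})


def simulate_voxel_phenotypes(
    g: GenotypeMatrix,
    design: SimulationDesign,
    seed: int | None = None,
):
    """Generate subject volumes with spatially structured true heritability.

    Returns ``(volumes, truth_map, blob_masks, covariates)`` where
    ``volumes`` is (N, X, Y, Z), ``truth_map`` is the per-voxel true-h2
    BrainMap, ``blob_masks`` are boolean volumes (one per blob, intersected
    with the brain mask) and ``covariates`` is the age/sex DataFrame.
    """
    rng = np.random.default_rng((design.seed + 1) if seed is None else seed)
    n = g.n_samples
    shape = tuple(design.volume_shape)
    mask = default_mask(shape)
    coords = np.argwhere(mask)
    v = len(coords)

    # monomorphic draws (possible in small family designs where few founder
    # haplotypes exist) carry no relatedness information; drop them here
    freq = g.alt_freq()
    poly = np.flatnonzero((freq > 0) & (freq < 1))
    if len(poly) < g.n_variants:
        log.info("GRM for phenotype simulation uses %d/%d polymorphic variants",
                 len(poly), g.n_variants)
        g = g.subset(variant_idx=poly)
    a = compute_grm(g).values
    chol_like = _grm_sqrt(a)

    truth = np.zeros(shape)
    truth[mask] = design.background_h2
    blob_masks = []
    blob_of_voxel = np.full(v, -1)
    h2_vox = np.full(v, design.background_h2, dtype=float)
    for b_i, blob in enumerate(design.blobs):
        d = np.sqrt(((coords - np.array(blob.center)) ** 2).sum(axis=1))
        if blob.taper > 0:
            profile = np.clip((blob.radius + blob.taper - d) / blob.taper, 0.0, 1.0)
        else:
            profile = (d <= blob.radius).astype(float)
        touched = profile > 0
        blob_of_voxel[touched] = b_i  # overlapping tapers: later blob wins
        h2_vox[touched] = blob.true_h2 * profile[touched]
        core = np.zeros(shape, dtype=bool)
        core[tuple(coords[d <= blob.radius].T)] = True
        blob_masks.append(core)
    truth[mask] = h2_vox

    covars = simulate_covariates(n, rng)
    fixed = (
        design.baseline_offset
        + design.age_beta * (covars["age"].to_numpy() - covars["age"].mean())
        + design.sex_beta * covars["sex"].to_numpy()
    )

    n_blobs = len(design.blobs)
    blob_factors = (
        chol_like @ rng.standard_normal((n, n_blobs)) if n_blobs else np.zeros((n, 0))
    )
    noise = rng.standard_normal((n, v))
    genetic = np.zeros((n, v))
    if design.background_h2 > 0:
        z_bg = rng.standard_normal((n, v))
        genetic[:] = chol_like @ z_bg
    for b_i in range(len(design.blobs)):
        cols = blob_of_voxel == b_i
        genetic[:, cols] = blob_factors[:, [b_i]]
    values = fixed[:, None] + design.noise_sd * (
        np.sqrt(h2_vox) * genetic + np.sqrt(1.0 - h2_vox) * noise
    )

    volumes = np.zeros((n,) + shape)
    volumes[:, mask] = values
    truth_map = BrainMap(truth, semantics="heritability", background_fill=0.0)
    return volumes, truth_map, blob_masks, covars


def make_toy_atlas(
    shape,
    n_regions: int,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> BrainMap:
    """Partition the in-mask volume into contiguous labels by multi-source BFS.

    Random seed voxels grow breadth-first (26-neighborhood), so every label
    is connected and the labels partition the mask exactly.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if mask is None:
        mask = default_mask(shape)
    coords = np.argwhere(mask)
    if n_regions > len(coords):
        raise ValueError("more regions than mask voxels")
    rng = np.random.default_rng(seed)
    seeds = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    labels = np.zeros(tuple(shape), dtype=np.int64)
    queue = deque()
    for lab, c in enumerate(seeds, start=1):
        labels[tuple(c)] = lab
        queue.append(tuple(c))
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
    shape = tuple(shape)
    while queue:
        i, j, k = queue.popleft()
        lab = labels[i, j, k]
        for di, dj, dk in offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                if mask[ni, nj, nk] and labels[ni, nj, nk] == 0:
                    labels[ni, nj, nk] = lab
                    queue.append((ni, nj, nk))
    return BrainMap(labels, semantics="label", background_fill=0.0)
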