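"""Spatially connected region extraction from significance maps.

The pipeline order is fixed: smooth the full p-value volume (background
filled with 1), threshold / top-fraction select voxels, then label maximal
connected components under a 6/18/26 neighborhood. Region quantitative
traits are unweighted means of member-voxel traits per subject.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .voxelmap import BrainMap, VoxelIndex, VoxelQTMatrix

__all__ = [
    "RegionSet",
    "RegionQTMatrix",
    "smooth_pmap",
    "select_voxels",
    "connected_components",
    "region_qts",
    "atlas_regions",
]

_STRUCTURE_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class RegionSet:
    labels: BrainMap  # semantics = label, 0 = unassigned
    region_ids: list[int]
    voxels: dict[int, np.ndarray]  # region id -> (k, 3) lexicographic coords
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = self.labels.volume
        for rid in self.region_ids:
            coords = self.voxels[rid]
            if len(coords) == 0:
                raise ValueError(f"region {rid} is empty")
            if not (lab[tuple(coords.T)] == rid).all():
                raise ValueError(f"label volume inconsistent with voxel list of region {rid}")
        n_labeled = int((lab != 0).sum())
        if n_labeled != sum(len(v) for v in self.voxels.values()):
            raise ValueError("region voxel lists do not partition the labeled voxels")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def sizes(self) -> dict[int, int]:
        return {rid: len(v) for rid, v in self.voxels.items()}

    def export(self, nifti_path, json_path, affine=None) -> None:
        from .voxelmap import save_map

        save_map(self.labels, nifti_path, affine)
        payload = {
            "provenance": self.provenance,
            "region_ids": self.region_ids,
            "sizes": {str(k): v for k, v in self.sizes().items()},
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass
class RegionQTMatrix:
    values: np.ndarray  # N x R
    samples: list[str]
    region_ids: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.region_ids)):
            raise ValueError("region QT shape mismatch")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.samples,
                          columns=[f"region{r}" for r in self.region_ids])
        df.index.name = "sample"
        df.to_csv(path, sep="\t", float_format="%.10g")


def smooth_pmap(pmap: BrainMap, sigma: float = 0.5) -> BrainMap:
    """Gaussian-smooth a p-value volume (separable, truncated at 4 sigma,
    reflect boundary); output clamped to (0, 1]."""
    if pmap.semantics != "p_value":
        raise ValueError("smooth_pmap expects a p-value map")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = ndimage.gaussian_filter(pmap.volume, sigma=sigma, mode="reflect", truncate=4.0)
    out = np.clip(out, np.finfo(float).tiny, 1.0)
    return BrainMap(out, semantics="p_value", background_fill=pmap.background_fill)


def select_voxels(
    pmap_smoothed: BrainMap,
    index: VoxelIndex,
    alpha: float = 0.05,
    top_fraction: float = 1.0,
    arm: str = "significant",
) -> BrainMap:
    """Mark the top fraction of (in)significant in-mask voxels.

    significant arm: candidates have p < alpha, ranked by ascending p;
    insignificant arm: candidates have p >= alpha, ranked by descending p.
    The first ceil(top_fraction * n_candidates) are kept; ties at the cut
    are broken lexicographically by coordinate.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if arm not in ("significant", "insignificant"):
        raise ValueError(f"unknown arm {arm!r}")
    coords = index.coords
    p = pmap_smoothed.volume[tuple(coords.T)]
    if arm == "significant":
        cand = p < alpha
        key = p
    else:
        cand = p >= alpha
        key = -p
    if not cand.any():
        raise ValueError(f"no candidate voxels for arm={arm} at alpha={alpha}")
    cand_idx = np.flatnonzero(cand)
    # sort by rank key, then lexicographically by coordinate
    c = coords[cand_idx]
    order = np.lexsort((c[:, 2], c[:, 1], c[:, 0], key[cand_idx]))
    n_keep = int(np.ceil(top_fraction * len(cand_idx)))
    chosen = cand_idx[order[:n_keep]]
    vol = np.zeros(index.shape)
    vol[tuple(coords[chosen].T)] = 1.0
    return BrainMap(vol, semantics="label", background_fill=0.0)


def connected_components(binary: BrainMap, connectivity: int = 26) -> RegionSet:
    """Label maximal connected components of 1-voxels.

    Labels start at 1 in first-encounter order under a lexicographic scan;
    an all-zero map yields an empty RegionSet.
    """
    if connectivity not in _STRUCTURE_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    mask = np.asarray(binary.volume) != 0
    structure = ndimage.generate_binary_structure(3, _STRUCTURE_RANK[connectivity])
    raw, n = ndimage.label(mask, structure=structure)
    # relabel in first-encounter (lexicographic scan) order
    flat = raw.ravel()
    first_seen = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earliest index wins
    first_seen[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_seen[1:], kind="stable")  # old label-1 -> rank
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[order + 1] = np.arange(1, n + 1)
    labels = remap[raw]
    voxels = {}
    for rid in range(1, n + 1):
        voxels[rid] = np.argwhere(labels == rid)
    return RegionSet(
        labels=BrainMap(labels.astype(np.int64), semantics="label", background_fill=0.0),
        region_ids=list(range(1, n + 1)),
        voxels=voxels,
        provenance={"connectivity": connectivity},
    )


def region_qts(rs: RegionSet, vqt: VoxelQTMatrix) -> RegionQTMatrix:
    """Per-subject unweighted mean of member-voxel traits for each region.

    Region voxels outside the phenotype mask are dropped with a warning; a
    region with no in-mask voxel is an error.
    """
    pos_to_col = {p: c for c, p in enumerate(vqt.index.flat_positions())}
    cols = []
    n_dropped = 0
    for rid in rs.region_ids:
        flat = np.ravel_multi_index(rs.voxels[rid].T, vqt.index.shape)
        members = [pos_to_col[p] for p in flat if p in pos_to_col]
        n_dropped += len(flat) - len(members)
        if not members:
            raise ValueError(f"region {rid} has no voxels inside the phenotype mask")
        cols.append(vqt.values[:, members].mean(axis=1))
    if n_dropped:
        warnings.warn(f"{n_dropped} region voxels outside the phenotype mask were dropped")
    return RegionQTMatrix(np.column_stack(cols), list(vqt.samples), list(rs.region_ids))


def atlas_regions(atlas: BrainMap, vqt: VoxelQTMatrix) -> tuple[RegionSet, RegionQTMatrix]:
    """One region per nonzero atlas label, intersected with the phenotype mask."""
    if atlas.volume.shape != vqt.index.shape:
        raise ValueError("atlas shape does not match phenotype volume shape")
    lab = np.asarray(np.rint(atlas.volume), dtype=np.int64)
    mask = vqt.index.mask()
    inter = np.where(mask, lab, 0)
    ids = [int(v) for v in np.unique(inter) if v != 0]
    if not ids:
        raise ValueError("no atlas label overlaps the phenotype mask")
    skipped = sorted(set(int(v) for v in np.unique(lab) if v != 0) - set(ids))
    if skipped:
        warnings.warn(f"atlas labels entirely outside the mask omitted: {skipped}")
    voxels = {rid: np.argwhere(inter == rid) for rid in ids}
    rs = RegionSet(
        labels=BrainMap(inter, semantics="label", background_fill=0.0),
        region_ids=ids,
        voxels=voxels,
        provenance={"arm": "atlas"},
    )
    return rs, region_qts(rs, vqt)
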