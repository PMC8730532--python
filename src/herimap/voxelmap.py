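"""Conversions between 3D volumes and the subject x voxel matrix.

Background voxels — exactly zero in every subject — are dropped during
vectorization; the surviving voxels are kept in lexicographic coordinate
order and the mapping is carried by a VoxelIndex so per-voxel statistics can
be painted back into volumes. Coordinates are 0-based array indices; any
NIfTI affine is passed through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelIndex",
    "VoxelQTMatrix",
    "BrainMap",
    "vectorize",
    "devectorize",
    "load_volumes",
    "save_map",
    "read_voxel_index",
    "write_voxel_index",
]

_DEFAULT_FILL = {"p_value": 1.0, "heritability": 0.0, "label": 0.0}
_SEMANTICS = tuple(_DEFAULT_FILL)


@dataclass
class VoxelIndex:
    """Bijection between vector positions and 3D voxel coordinates."""

    shape: tuple[int, int, int]
    coords: np.ndarray  # (V, 3) int

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 3)
        if (self.coords < 0).any() or (self.coords >= np.array(self.shape)).any():
            raise ValueError("voxel coordinates outside volume shape")
        if len(np.unique(self.flat_positions())) != len(self.coords):
            raise ValueError("duplicate voxel coordinates")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def flat_positions(self) -> np.ndarray:
        return np.ravel_multi_index(self.coords.T, self.shape)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.coords.T)] = True
        return m


@dataclass
class VoxelQTMatrix:
    values: np.ndarray  # N x V
    samples: list[str]
    index: VoxelIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.index)):
            raise ValueError("values shape does not match samples x voxel index")
        if not np.isfinite(self.values).all():
            raise ValueError("voxel QT matrix must be finite")

    @property
    def n_voxels(self) -> int:
        return len(self.index)


@dataclass
class BrainMap:
    volume: np.ndarray
    semantics: str
    background_fill: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.semantics not in _SEMANTICS:
            raise ValueError(f"semantics must be one of {_SEMANTICS}")
        self.volume = np.asarray(self.volume)
        if self.volume.ndim != 3:
            raise ValueError("BrainMap volume must be 3-D")
        if np.isnan(self.background_fill):
            self.background_fill = _DEFAULT_FILL[self.semantics]


def vectorize(volumes, samples: list[str] | None = None) -> VoxelQTMatrix:
    """Stack subject volumes into N x V, dropping all-zero background voxels.

    ``volumes`` is an (N, X, Y, Z) array or a sequence of 3-D arrays sharing
    one shape. A voxel is background only if it is exactly 0 in *every*
    subject; retained voxels are ordered lexicographically by coordinate.
    """
    vols = [np.asarray(v, dtype=float) for v in volumes]
    if not vols:
        raise ValueError("need at least one subject volume")
    shape = vols[0].shape
    for i, v in enumerate(vols):
        if v.shape != shape:
            raise ValueError(f"subject {i}: shape {v.shape} != {shape}")
    stack = np.stack(vols)
    in_mask = (stack != 0).any(axis=0)
    coords = np.argwhere(in_mask)  # argwhere is lexicographic (C order)
    idx = VoxelIndex(shape, coords)
    values = stack[:, in_mask]  # boolean indexing follows C order too
    if samples is None:
        samples = [f"S{i}" for i in range(len(vols))]
    return VoxelQTMatrix(values, list(samples), idx)


def devectorize(values, index: VoxelIndex, fill: float | None = None,
                semantics: str = "heritability") -> BrainMap:
    """Paint a per-voxel vector back into a 3-D volume.

    Voxels outside the mask take ``fill`` (default: 1 for p-value maps so
    the background is never significant, 0 for heritability/label maps).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(index),):
        raise ValueError(f"{values.shape[0]} values for a {len(index)}-voxel index")
    if fill is None:
        fill = _DEFAULT_FILL[semantics]
    vol = np.full(index.shape, float(fill))
    vol[tuple(index.coords.T)] = values
    return BrainMap(vol, semantics=semantics, background_fill=float(fill))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_volumes(paths) -> tuple[np.ndarray, np.ndarray]:
    """Read NIfTI volumes; returns (N,X,Y,Z) data and the first file's affine."""
    imgs = [nib.load(str(p)) for p in paths]
    data = np.stack([np.asarray(img.get_fdata(), dtype=float) for img in imgs])
    return data, imgs[0].affine


def save_map(bmap: BrainMap, path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(bmap.volume, dtype=np.float64), affine), str(path))


def load_map(path, semantics: str) -> BrainMap:
    vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    return BrainMap(vol, semantics=semantics)


def write_voxel_index(index: VoxelIndex, path) -> None:
    df = pd.DataFrame(index.coords, columns=["i", "j", "k"])
    df.index.name = "vector_pos"
    df.to_csv(path, sep="\t")


def read_voxel_index(path, shape) -> VoxelIndex:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return VoxelIndex(tuple(shape), df[["i", "j", "k"]].to_numpy())
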