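"""Volume I/O, isotropic resampling, seed derivation and patch extraction.

CT scans arrive with anisotropic voxels (slice thickness usually exceeds the
in-plane resolution), so every scan is resampled with trilinear interpolation
to an isotropic grid (1 mm by default) before fixed-size cubic patches are
cut around lesion seed points.  Seeds come either from the midpoint of a
RECIST diameter or from the centre of mass of a 3D contour mask.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import SimpleITK as sitk

from .types import HU_MIN, HU_MAX, HU_RANGE, Patch, SeedPoint, VolumeGrid

PathLike = Union[str, Path]


def _sitk_to_grid(img: sitk.Image) -> VolumeGrid:
    # SimpleITK arrays come back (z, y, x); transpose to our (x, y, z) order.
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float32)
    return VolumeGrid(arr, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def _grid_to_sitk(vol: VolumeGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.intensities.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def read_volume(path: PathLike) -> VolumeGrid:
    """Read a NIfTI (.nii/.nii.gz) or NRRD volume into a :class:`VolumeGrid`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - backend specific message
        raise ValueError(f"could not read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D volume, got {img.GetDimension()}D: {path}")
    return _sitk_to_grid(img)


def write_volume(vol: VolumeGrid, path: PathLike) -> Path:
    """Write a volume as NIfTI or NRRD (format chosen by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_grid_to_sitk(vol), str(path))
    return path


def resample_isotropic(vol: VolumeGrid, target: float = 1.0) -> VolumeGrid:
    """Trilinear resampling onto an isotropic grid of ``target`` mm voxels.

    Physical extent is preserved within one voxel; an input already on the
    target grid is returned unchanged up to interpolation round-off.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if vol.is_isotropic() and abs(vol.spacing[0] - target) < 1e-9:
        return VolumeGrid(vol.intensities.copy(), spacing=vol.spacing, origin=vol.origin)
    img = _grid_to_sitk(vol)
    new_size = [max(1, int(round(n * s / target))) for n, s in zip(img.GetSize(), img.GetSpacing())]
    res = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        sitk.sitkLinear,
        img.GetOrigin(),
        (target, target, target),
        img.GetDirection(),
        float(HU_MIN),
        sitk.sitkFloat32,
    )
    return _sitk_to_grid(res)


def seed_from_recist(p1: Sequence[float], p2: Sequence[float]) -> SeedPoint:
    """Seed point at the midpoint of a RECIST diameter given its endpoints (mm)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != (3,) or p2.shape != (3,):
        raise ValueError("RECIST endpoints must be 3-vectors")
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
        raise ValueError("RECIST endpoints must be finite")
    return SeedPoint(tuple((p1 + p2) / 2.0))


def seed_from_mask(
    mask: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> SeedPoint:
    """Seed point at the unweighted centre of mass of a binary lesion mask."""
    mask = np.asarray(mask)
    idx = np.argwhere(mask > 0)
    if idx.size == 0:
        raise ValueError("mask has no foreground voxels")
    centroid_idx = idx.mean(axis=0)
    pos = np.asarray(origin, dtype=float) + centroid_idx * np.asarray(spacing, dtype=float)
    return SeedPoint(tuple(pos))


def extract_patch(
    vol: VolumeGrid,
    seed: SeedPoint,
    edge_voxels: int = 50,
    fill: float = HU_MIN,
) -> Patch:
    """Cut an ``edge_voxels``-cube centred on ``seed``.

    The seed lands in the centre voxel at index ``edge_voxels // 2`` on each
    axis (one voxel asymmetric for even edges).  Regions outside the volume
    are padded with ``fill`` (air, -1024 HU, by default) so border lesions
    still yield full-size patches.
    """
    if not vol.is_isotropic():
        raise ValueError("extract_patch requires an isotropic volume; resample first")
    L = int(edge_voxels)
    if L <= 0:
        raise ValueError("edge_voxels must be positive")
    center = np.rint(vol.world_to_index(seed.xyz)).astype(int)
    half = L // 2
    start = center - half
    stop = start + L

    shape = np.asarray(vol.shape)
    if np.all((stop <= 0) | (start >= shape)):
        warnings.warn("seed falls entirely outside the volume; returning a filled patch")
    out = np.full((L, L, L), float(fill), dtype=np.float32)
    src_lo = np.clip(start, 0, shape)
    src_hi = np.clip(stop, 0, shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.all(src_hi > src_lo):
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = vol.intensities[
            src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
        ]
    return Patch(out, edge_voxels=L, normalized=False, source=("", tuple(seed.xyz)))


def normalize_intensity(patch: Patch, lo: float = HU_MIN, hi: float = HU_MAX) -> Patch:
    """Clip HU to ``[lo, hi]`` and map linearly onto [0, 1].

    With the defaults this subtracts -1024 and divides by 3072, so air maps
    to exactly 0 and the densest bone to exactly 1.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if patch.normalized:
        raise ValueError("patch is already normalized")
    v = np.clip(patch.values, lo, hi)
    v = (v - lo) / (hi - lo)
    return Patch(v.astype(np.float32), edge_voxels=patch.edge_voxels, normalized=True, source=patch.source)


def patch_window(center_index: Sequence[int], edge_voxels: int) -> Tuple[np.ndarray, np.ndarray]:
    """Half-open index window ``[start, stop)`` of a patch around a voxel index."""
    c = np.asarray(center_index, dtype=int)
    start = c - edge_voxels // 2
    return start, start + edge_voxels
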