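"""Lesion extraction, size grouping, volume normalisation and cube embedding.

Connected hyperintense components are lifted out of a co-registered
volume/mask pair, screened by a minimum physical volume, partitioned into a
small and a large size group at a voxel-count cutoff, isotropically rescaled
to a common target volume and centred in fixed-size cubes for the shape
transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Lesion3D",
    "SizeGroups",
    "extract_lesions",
    "split_by_size",
    "rescale_to_target_volume",
    "embed_in_cube",
    "lesion_table",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Lesion3D:
    """One connected lesion component with its voxel coordinates and intensities."""

    subject_id: str
    lesion_id: int
    coords: np.ndarray  # (k, 3) integer voxel coordinates
    intensities: np.ndarray  # (k,) intensities sampled from the volume
    centroid: tuple[float, float, float]
    volume_voxels: int
    volume_mm3: float

    def mask_in(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.coords.T)] = True
        return m


@dataclass
class SizeGroups:
    cutoff: int
    group_small: list[Lesion3D]
    group_large: list[Lesion3D]


def extract_lesions(
    volume: np.ndarray,
    mask: np.ndarray,
    min_volume_mm3: float = 30.0,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    connectivity: int = 26,
    subject_id: str = "",
) -> list[Lesion3D]:
    """Connected components of ``mask`` strictly larger than ``min_volume_mm3``.

    The centroid is the unweighted mean of the component's voxel coordinates;
    intensities are sampled from ``volume`` at the component's voxels.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must be binary")
    labels, n = ndimage.label(mask.astype(bool), structure=_STRUCTS[connectivity])
    vox_mm3 = float(np.prod(voxel_size_mm))
    lesions: list[Lesion3D] = []
    lesion_id = 0
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        vol_mm3 = coords.shape[0] * vox_mm3
        if vol_mm3 <= min_volume_mm3:
            continue
        lesion_id += 1
        lesions.append(
            Lesion3D(
                subject_id=subject_id,
                lesion_id=lesion_id,
                coords=coords,
                intensities=volume[tuple(coords.T)].astype(float),
                centroid=tuple(coords.mean(axis=0)),
                volume_voxels=coords.shape[0],
                volume_mm3=vol_mm3,
            )
        )
    return lesions


def split_by_size(lesions: list[Lesion3D], cutoff_voxels: int = 250) -> SizeGroups:
    """Partition lesions at the cutoff; the boundary goes to the small group."""
    small = [le for le in lesions if le.volume_voxels <= cutoff_voxels]
    large = [le for le in lesions if le.volume_voxels > cutoff_voxels]
    return SizeGroups(cutoff=cutoff_voxels, group_small=small, group_large=large)


def rescale_to_target_volume(
    lesion: Lesion3D,
    target_voxels: int,
    interpolation: str = "tricubic",
) -> np.ndarray:
    """Rescale a lesion's binary occupancy to roughly ``target_voxels``.

    The shape is zoomed isotropically by ``(v' / v)**(1/3)`` with tricubic
    (or trilinear) interpolation of the binary field, then binarised at the
    intensity level whose foreground count lands closest to the target;
    ties pick the lower threshold (larger volume).
    """
    if target_voxels < 1:
        raise ValueError("target_voxels must be >= 1")
    order = {"tricubic": 3, "trilinear": 1}[interpolation]
    coords = lesion.coords
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo + 1
    occ = np.zeros(tuple(span), dtype=float)
    occ[tuple((coords - lo).T)] = 1.0
    ratio = (target_voxels / lesion.volume_voxels) ** (1.0 / 3.0)
    if lesion.volume_voxels == 1:
        # degenerate single voxel: block replication instead of interpolation
        side = max(1, int(round(ratio)))
        return np.ones((side, side, side), dtype=bool)
    pad = 2  # room for interpolation overshoot at the boundary
    occ = np.pad(occ, pad)
    zoomed = ndimage.zoom(occ, ratio, order=order, mode="grid-constant", cval=0.0, grid_mode=True)
    vals = zoomed[zoomed > 0]
    if vals.size == 0:
        return np.zeros_like(zoomed, dtype=bool)
    # threshold search over observed values: count(>= t) closest to target
    sv = np.sort(vals)[::-1]
    counts = np.arange(1, sv.size + 1)
    best = np.abs(counts - target_voxels)
    # ties -> larger volume, i.e. later index / lower threshold
    i = sv.size - 1 - int(np.argmin(best[::-1]))
    return zoomed >= sv[i]


def embed_in_cube(shape: np.ndarray, cube_side: int) -> np.ndarray:
    """Centre a binary shape in an ``N^3`` cube by its centroid.

    The centroid lands on the cube centre ``floor((N - 1) / 2)`` rounded to
    the nearest voxel; raises if the shape's bounding box does not fit.
    """
    shape = np.asarray(shape, dtype=bool)
    coords = np.argwhere(shape)
    if coords.size == 0:
        return np.zeros((cube_side,) * 3, dtype=bool)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    if np.any(hi - lo + 1 > cube_side):
        raise ValueError("shape extent exceeds the cube")
    centroid = coords.mean(axis=0)
    center = (cube_side - 1) // 2
    shift = np.round(center - centroid).astype(int)
    out_coords = coords + shift
    if np.any(out_coords < 0) or np.any(out_coords >= cube_side):
        # rounding pushed the box over an edge; clamp the shift
        shift = shift - np.maximum(out_coords.max(axis=0) - (cube_side - 1), 0)
        shift = shift + np.maximum(-(coords.min(axis=0) + shift), 0)
        out_coords = coords + shift
    cube = np.zeros((cube_side,) * 3, dtype=bool)
    cube[tuple(out_coords.T)] = True
    return cube


def lesion_table(lesions: list[Lesion3D], groups: SizeGroups | None = None):
    """Summary table (one row per lesion) for CSV export."""
    import pandas as pd

    small_ids = (
        {(le.subject_id, le.lesion_id) for le in groups.group_small} if groups else set()
    )
    rows = []
    for le in lesions:
        rows.append(
            {
                "subject_id": le.subject_id,
                "lesion_id": le.lesion_id,
                "volume_voxels": le.volume_voxels,
                "volume_mm3": le.volume_mm3,
                "centroid_x": le.centroid[0],
                "centroid_y": le.centroid[1],
                "centroid_z": le.centroid[2],
                "group": (
                    ""
                    if groups is None
                    else ("small" if (le.subject_id, le.lesion_id) in small_ids else "large")
                ),
            }
        )
    return pd.DataFrame(rows)
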