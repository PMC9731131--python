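"""Potential Growth Index (PGI) over lesion penumbras.

The penumbra of a lesion is decomposed into ``l`` one-voxel-thick
morphological dilation shells.  A shell voxel counts as "growth" when its
intensity ``f`` satisfies ``m - f <= gamma * sigma``, where ``m`` and
``sigma`` are the mean and population SD of the intensities pooled over all
of the subject's lesions (at ``gamma = 2.5`` the threshold admits 99.38% of
lesion-like intensities under a Gaussian model).  Outer shells weight more:
``w_i = i / sum_j j``; the index is

    PGI = sum_i GV_i * w_i / V_total,   V_total = sum_i V_i,

a number in [0, 1] — the weighted fraction of penumbra voxels bright enough
to be at risk of converting to lesion.  Voxels belonging to any other
lesion, and voxels outside the image, never count toward the penumbra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .lesions import Lesion3D

__all__ = [
    "SubjectIntensityStats",
    "PenumbraLayers",
    "PGIResult",
    "subject_intensity_stats",
    "build_penumbra_layers",
    "count_growth_voxels",
    "compute_pgi",
    "layer_weights",
    "pgi_for_lesions",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SubjectIntensityStats:
    m: float
    sigma: float


@dataclass
class PenumbraLayers:
    """Dilation shells around one lesion: masks, sizes and growth counts."""

    l: int
    layer_masks: list[np.ndarray]
    sizes: np.ndarray  # V_i
    growth: np.ndarray | None = None  # GV_i, filled by count_growth_voxels
    gamma: float | None = None


@dataclass
class PGIResult:
    lesion_id: str
    pgi: float
    gamma: float
    l: int
    sizes: np.ndarray
    growth: np.ndarray
    weights: np.ndarray


def subject_intensity_stats(lesions: list[Lesion3D]) -> SubjectIntensityStats:
    """Mean and population SD over the pooled voxel intensities of all
    the subject's lesions."""
    pool = np.concatenate([le.intensities for le in lesions]) if lesions else np.array([])
    if pool.size == 0:
        raise ValueError("no lesion voxels to pool")
    return SubjectIntensityStats(m=float(pool.mean()), sigma=float(pool.std()))


def layer_weights(l: int) -> np.ndarray:
    """``w_i = i / sum_{j=1}^{l} j`` — strictly increasing, unit sum."""
    i = np.arange(1, l + 1, dtype=float)
    return i / i.sum()


def build_penumbra_layers(
    lesion_mask: np.ndarray,
    all_lesions_mask: np.ndarray | None = None,
    l: int = 5,
    connectivity: int = 26,
) -> PenumbraLayers:
    """``l`` one-voxel-thick dilation shells around a lesion.

    Shell ``i`` is ``dilate^i(lesion) \\ dilate^(i-1)(lesion)`` minus any
    voxel that belongs to a lesion (own or other) — those are already
    disease, not potential growth.  Image borders clip the shells.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if not lesion_mask.any():
        raise ValueError("empty lesion mask")
    if all_lesions_mask is None:
        all_lesions_mask = lesion_mask
    all_lesions_mask = np.asarray(all_lesions_mask, dtype=bool)
    struct = _STRUCTS[connectivity]
    prev = lesion_mask
    masks: list[np.ndarray] = []
    for _ in range(l):
        cur = ndimage.binary_dilation(prev, structure=struct)
        masks.append(cur & ~prev & ~all_lesions_mask)
        prev = cur
    sizes = np.array([int(m.sum()) for m in masks])
    return PenumbraLayers(l=l, layer_masks=masks, sizes=sizes)


def count_growth_voxels(
    layers: PenumbraLayers,
    volume: np.ndarray,
    stats: SubjectIntensityStats,
    gamma: float = 2.5,
) -> PenumbraLayers:
    """Count per shell the voxels with ``f >= m - gamma * sigma``."""
    volume = np.asarray(volume, dtype=float)
    thr = stats.m - gamma * stats.sigma
    layers.growth = np.array([int((volume[m] >= thr).sum()) for m in layers.layer_masks])
    layers.gamma = gamma
    return layers


def compute_pgi(layers: PenumbraLayers, lesion_id: str = "") -> PGIResult:
    """Weighted growth fraction ``sum_i GV_i w_i / sum_i V_i``."""
    if layers.growth is None:
        raise ValueError("growth counts not computed; run count_growth_voxels first")
    v_total = int(layers.sizes.sum())
    if v_total == 0:
        raise ValueError("zero-size penumbra (lesion fills the image)")
    w = layer_weights(layers.l)
    pgi = float(np.dot(layers.growth, w) / v_total)
    return PGIResult(
        lesion_id=lesion_id,
        pgi=pgi,
        gamma=layers.gamma if layers.gamma is not None else np.nan,
        l=layers.l,
        sizes=layers.sizes,
        growth=layers.growth,
        weights=w,
    )


def pgi_for_lesions(
    volume: np.ndarray,
    lesions: list[Lesion3D],
    gamma: float = 2.5,
    l: int = 5,
    connectivity: int = 26,
) -> list[PGIResult]:
    """PGI for every lesion of one subject, pooling intensity stats."""
    if not lesions:
        return []
    stats = subject_intensity_stats(lesions)
    all_mask = np.zeros(volume.shape, dtype=bool)
    for le in lesions:
        all_mask[tuple(le.coords.T)] = True
    out = []
    for le in lesions:
        layers = build_penumbra_layers(
            le.mask_in(volume.shape), all_mask, l=l, connectivity=connectivity
        )
        layers = count_growth_voxels(layers, volume, stats, gamma=gamma)
        out.append(compute_pgi(layers, lesion_id=f"{le.subject_id}:{le.lesion_id}"))
    return out
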