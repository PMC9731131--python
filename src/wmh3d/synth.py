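"""Seeded synthetic FLAIR-like phantoms with known lesion geometry.

The generator emulates what the analysis consumes: a scalar volume holding
several connected hyperintense lesions (ellipsoids, tori or sphere-union
blobs) with a bright core, smooth cosine falloff toward the boundary, an
optional bright penumbra halo of configurable thickness, and Gaussian
background noise.  Every phantom carries a ground-truth record (per-lesion
volume, centroid, and per-shell growth-voxel counts computed independently
via a chessboard distance transform) sufficient to predict the extraction
and PGI stages exactly on noise-free phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LesionPrimitive",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "make_blob_features",
    "save_nifti",
    "load_nifti",
    "nifti_roundtrip",
]


@dataclass
class LesionPrimitive:
    """One lesion: ``kind`` in {"ellipsoid", "torus", "spheres"}.

    ``radii`` means (rx, ry, rz) for an ellipsoid, (ring_radius, tube_radius)
    for a torus, and the common sphere radius for a sphere union (whose
    centres go in ``extra_centers``).  ``angles`` are ZYX Euler angles in
    radians applied about the primitive centre.
    """

    kind: str
    center: tuple[float, float, float]
    radii: tuple
    angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    extra_centers: tuple = ()


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    lesions: list[LesionPrimitive] = field(default_factory=list)
    background: float = 100.0
    core_intensity: float = 200.0
    falloff_width: float = 2.0  # voxels of cosine ramp inside the boundary
    halo_thickness: int = 0  # penumbra halo shells (0 disables)
    halo_intensity: float = 160.0
    noise_sd: float = 0.0
    gamma: float = 2.5
    pgi_layers: int = 5
    seed: int = 0
    allow_overlap: bool = False


@dataclass
class GroundTruth:
    volumes: list[int]
    centroids: list[tuple[float, float, float]]
    layer_sizes: list[np.ndarray]
    growth_counts: list[np.ndarray]
    mean_intensity: float
    sd_intensity: float
    threshold: float


def _rotation(angles) -> np.ndarray:
    a, b, c = angles
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
    return rz @ ry @ rx


def _primitive_mask(prim: LesionPrimitive, shape) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    rel = grids - np.asarray(prim.center, dtype=float)[:, None, None, None]
    rot = _rotation(prim.angles)
    local = np.einsum("ij,jxyz->ixyz", rot.T, rel)
    if prim.kind == "ellipsoid":
        rx, ry, rz = prim.radii
        q = (local[0] / rx) ** 2 + (local[1] / ry) ** 2 + (local[2] / rz) ** 2
        return q <= 1.0
    if prim.kind == "torus":
        ring, tube = prim.radii
        rho = np.sqrt(local[0] ** 2 + local[1] ** 2)
        return (rho - ring) ** 2 + local[2] ** 2 <= tube**2
    if prim.kind == "spheres":
        rad = float(prim.radii[0]) if np.ndim(prim.radii) else float(prim.radii)
        centers = [prim.center, *prim.extra_centers]
        mask = np.zeros(shape, dtype=bool)
        for c in centers:
            d2 = sum((grids[i] - c[i]) ** 2 for i in range(3))
            mask |= d2 <= rad**2
        return mask
    raise ValueError(f"unknown primitive kind {prim.kind!r}")


def make_phantom(spec: PhantomSpec):
    """Build (volume, mask, ground_truth) from a phantom specification.

    Lesion intensity is ``background + (core - background) * w(d)`` where
    ``d`` is the chessboard depth into the lesion and ``w`` ramps from 0.5
    at the boundary layer to 1 over ``falloff_width`` layers with a cosine
    profile; the halo (shells 1..halo_thickness outside the lesion) is set
    to ``halo_intensity``.  Noise is seeded Gaussian, added last.  The
    ground-truth shell geometry uses a chessboard distance transform, not
    morphological dilation, so it is an independent prediction of the
    penumbra decomposition.
    """
    shape = tuple(spec.shape)
    masks = [_primitive_mask(p, shape) for p in spec.lesions]
    all_mask = np.zeros(shape, dtype=bool)
    for i, m in enumerate(masks):
        if not spec.allow_overlap and (m & all_mask).any():
            raise ValueError(f"lesion primitive {i} overlaps a previous one")
        all_mask |= m
    volume = np.full(shape, spec.background, dtype=float)
    if all_mask.any():
        depth = ndimage.distance_transform_cdt(all_mask, metric="chessboard").astype(float)
        # cosine ramp: w = 0.5 at the boundary shell, 1.0 at full depth
        ramp = np.clip((depth - 1.0) / max(spec.falloff_width, 1e-9), 0.0, 1.0)
        w = 0.5 + 0.25 * (1.0 - np.cos(np.pi * ramp))
        volume[all_mask] = spec.background + (spec.core_intensity - spec.background) * w[all_mask]
    outside_dist = ndimage.distance_transform_cdt(~all_mask, metric="chessboard")
    if spec.halo_thickness > 0 and all_mask.any():
        halo = (outside_dist >= 1) & (outside_dist <= spec.halo_thickness)
        volume[halo] = spec.halo_intensity

    lesion_vals = volume[all_mask]
    m = float(lesion_vals.mean()) if lesion_vals.size else float("nan")
    sd = float(lesion_vals.std()) if lesion_vals.size else float("nan")
    thr = m - spec.gamma * sd

    layer_sizes, growth_counts, centroids, volumes = [], [], [], []
    for msk in masks:
        dist = ndimage.distance_transform_cdt(~msk, metric="chessboard")
        sizes, growth = [], []
        for i in range(1, spec.pgi_layers + 1):
            layer = (dist == i) & ~all_mask
            sizes.append(int(layer.sum()))
            growth.append(int((volume[layer] >= thr).sum()))
        layer_sizes.append(np.array(sizes))
        growth_counts.append(np.array(growth))
        coords = np.argwhere(msk)
        centroids.append(tuple(coords.mean(axis=0)))
        volumes.append(int(msk.sum()))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        volume = volume + rng.normal(0.0, spec.noise_sd, size=shape)

    gt = GroundTruth(
        volumes=volumes,
        centroids=centroids,
        layer_sizes=layer_sizes,
        growth_counts=growth_counts,
        mean_intensity=m,
        sd_intensity=sd,
        threshold=thr,
    )
    return volume, all_mask.astype(np.uint8), gt


def make_blob_features(
    k: int,
    n_per_cluster: int,
    separation: float,
    dim: int = 2,
    seed: int = 0,
):
    """Gaussian blobs with unit within-cluster SD and centres ``separation``
    apart (vertices of a regular polygon in the first two dimensions).
    Returns (features, labels)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    centers = np.zeros((k, dim))
    if k > 1:
        radius = separation / (2.0 * np.sin(np.pi / k))
        ang = 2 * np.pi * np.arange(k) / k
        centers[:, 0] = radius * np.cos(ang)
        centers[:, 1 % dim] = radius * np.sin(ang)
    pts = np.vstack(
        [rng.normal(0.0, 1.0, size=(n_per_cluster, dim)) + centers[i] for i in range(k)]
    )
    labels = np.repeat(np.arange(k), n_per_cluster)
    return pts, labels


# ---------------------------------------------------------------------------
# NIfTI I/O

def save_nifti(data: np.ndarray, path, spacing=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path):
    """Returns (data, spacing, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3]), img.affine


def nifti_roundtrip(data: np.ndarray, path, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Write then re-read a volume; used to guarantee lossless storage."""
    save_nifti(data, path, spacing)
    out, zooms, _ = load_nifti(path)
    return out
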