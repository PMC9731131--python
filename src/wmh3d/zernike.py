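"""3D Zernike moments, descriptors and reconstructions on the unit ball.

The basis is ``V_nlm(r, theta, phi) = R_nl(r) * Y_lm(theta, phi)`` with real
orthonormal spherical harmonics ``Y_lm`` and radial polynomials ``R_nl``
normalised so that ``R_nl(1) = 1`` and
``int_0^1 R_nl R_n'l r^2 dr = delta_nn' / (2n + 3)``.  Valid index triples
satisfy ``l <= n``, ``n - l`` even and ``|m| <= l``.  Moments of a voxel
volume are discrete inner products over the unit ball; the vector norms
``||Z_nl|| = sqrt(sum_m Z_nlm^2)`` are invariant under rotation and form the
shape descriptor.

All tables are evaluated by stable recursions (the associated-Legendre
three-step recursion over degree, and a Kintner-style three-term recursion
over radial order), which keeps orders up to 250 finite in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitBallGrid",
    "ZernikeMoments",
    "ZernikeDescriptor",
    "build_unit_ball_grid",
    "normalized_assoc_legendre",
    "real_spherical_harmonics",
    "radial_polynomials",
    "forward_transform",
    "reconstruct",
    "reconstruction_error",
    "reconstruction_error_sweep",
    "ball_quadrature",
    "basis_gram_residual",
    "compute_descriptor",
    "moment_count",
    "descriptor_dimension",
    "valid_triples",
    "valid_pairs",
]


# ---------------------------------------------------------------------------
# index bookkeeping

def moment_count(n: int) -> int:
    """Number of independent moments (m >= 0 triples) up to order ``n``."""
    if n < 0:
        raise ValueError("order must be non-negative")
    return int(sum((i + 2) ** 2 // 4 for i in range(n + 1)))


def descriptor_dimension(n: int) -> int:
    """Number of (n, l) pairs — the length of the shape descriptor."""
    if n < 0:
        raise ValueError("order must be non-negative")
    if n % 2 == 0:
        return ((n + 2) // 2) ** 2
    return (n + 3) * (n + 1) // 4


def valid_pairs(n_max: int) -> list[tuple[int, int]]:
    """All (n, l) with l <= n <= n_max and n - l even, ordered (n asc, l asc)."""
    return [(n, l) for n in range(n_max + 1) for l in range(n % 2, n + 1, 2)]


def valid_triples(n_max: int) -> list[tuple[int, int, int]]:
    """All (n, l, m) triples in lexicographic order, m from -l to l."""
    return [(n, l, m) for n, l in valid_pairs(n_max) for m in range(-l, l + 1)]


# ---------------------------------------------------------------------------
# grid

@dataclass(frozen=True)
class UnitBallGrid:
    """Spherical coordinates of a voxel cube mapped into the unit ball.

    ``r``, ``theta``, ``phi`` are flat arrays over the voxels with ``r <= 1``;
    ``index`` holds their flat positions in the ``cube_side**3`` raster.
    """

    cube_side: int
    center: tuple[float, float, float]
    scale_radius: float
    r: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    index: np.ndarray
    voxel_volume_element: float

    @property
    def n_voxels(self) -> int:
        return self.r.size


def build_unit_ball_grid(
    cube_side: int,
    scaling: str = "cube_in_ball",
    occupied_voxels: np.ndarray | None = None,
) -> UnitBallGrid:
    """Map an ``N^3`` voxel cube into the unit ball.

    Parameters
    ----------
    cube_side:
        Cube edge length ``N`` (voxels), at least 2.
    scaling:
        ``"cube_in_ball"`` scales so that the cube's corner voxel centres lie
        on the unit sphere (``scale_radius = sqrt(3) * (N - 1) / 2``); every
        voxel is then inside the ball.  ``"tight_fit"`` scales by the largest
        centre distance of ``occupied_voxels`` plus half a voxel.
    occupied_voxels:
        ``(k, 3)`` integer coordinates, required for ``tight_fit``.
    """
    if cube_side < 2:
        raise ValueError("cube_side must be >= 2")
    c = (cube_side - 1) / 2.0
    if scaling == "cube_in_ball":
        scale = np.sqrt(3.0) * c
    elif scaling == "tight_fit":
        if occupied_voxels is None or len(occupied_voxels) == 0:
            raise ValueError("tight_fit requires a non-empty occupied voxel set")
        occ = np.asarray(occupied_voxels, dtype=float)
        scale = float(np.max(np.linalg.norm(occ - c, axis=1))) + 0.5
    else:
        raise ValueError(f"unknown scaling {scaling!r}")

    ax = (np.arange(cube_side) - c) / scale
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z).ravel()
    inside = r <= 1.0 + 1e-12
    idx = np.nonzero(inside)[0]
    r = np.minimum(r[inside], 1.0)
    xv, yv, zv = x.ravel()[inside], y.ravel()[inside], z.ravel()[inside]
    ratio = np.divide(zv, r, out=np.zeros_like(zv), where=r > 0)
    theta = np.where(r > 0, np.arccos(np.clip(ratio, -1.0, 1.0)), 0.0)
    phi = np.arctan2(yv, xv)
    phi[r == 0] = 0.0
    return UnitBallGrid(
        cube_side=cube_side,
        center=(c, c, c),
        scale_radius=float(scale),
        r=r,
        theta=theta,
        phi=phi,
        index=idx,
        voxel_volume_element=float(scale) ** -3,
    )


# ---------------------------------------------------------------------------
# basis tables (reference evaluation; the transform uses streaming recursions)

def normalized_assoc_legendre(l_max: int, x: np.ndarray) -> np.ndarray:
    """Orthonormal associated Legendre functions ``P~_l^m(x)``.

    Normalised so that the real spherical harmonics built from them are
    orthonormal over the sphere: ``P~_0^0 = sqrt(1 / (4 pi))`` and
    ``int_-1^1 P~_l^m P~_l'^m dx = delta_ll' / (2 pi)`` (``1 / pi`` for
    ``m != 0`` before the sqrt(2) harmonic factor).

    Returns an array of shape ``(l_max + 1, l_max + 1, len(x))`` indexed
    ``[l, m]``; entries with ``m > l`` are zero.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("argument must lie in [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    s = np.sqrt(1.0 - x * x)
    out = np.zeros((l_max + 1, l_max + 1, x.size))
    out[0, 0] = np.sqrt(1.0 / (4.0 * np.pi))
    for l in range(1, l_max + 1):
        out[l, l] = np.sqrt((2 * l + 1) / (2.0 * l)) * s * out[l - 1, l - 1]
        for m in range(l - 1, -1, -1):
            cc = np.sqrt((2 * l + 1) / ((l + m) * (l - m)))
            c1 = cc * np.sqrt(2 * l - 1.0)
            term = c1 * x * out[l - 1, m]
            if m <= l - 2:
                c2 = cc * np.sqrt((l + m - 1) * (l - m - 1) / (2 * l - 3.0))
                term = term - c2 * out[l - 2, m]
            out[l, m] = term
    return out


def real_spherical_harmonics(l_max: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonics ``Y_l^m(theta, phi)``.

    ``Y_l^m = sqrt(2) P~_l^|m| cos(m phi)`` for ``m > 0``,
    ``sqrt(2) P~_l^|m| sin(|m| phi)`` for ``m < 0`` and ``P~_l^0`` for
    ``m = 0``.  Returns shape ``(l_max + 1, 2 l_max + 1, npts)`` indexed
    ``[l, l_max + m]``.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    plm = normalized_assoc_legendre(l_max, np.cos(theta))
    out = np.zeros((l_max + 1, 2 * l_max + 1, theta.size))
    for l in range(l_max + 1):
        out[l, l_max] = plm[l, 0]
        for m in range(1, l + 1):
            out[l, l_max + m] = np.sqrt(2.0) * plm[l, m] * np.cos(m * phi)
            out[l, l_max - m] = np.sqrt(2.0) * plm[l, m] * np.sin(m * phi)
    return out


def radial_polynomials(n_max: int, r: np.ndarray) -> np.ndarray:
    """Radial polynomials ``R_nl(r)`` for all valid (n, l), shape (n+1, n+1, npts).

    Three-term recursion over n at fixed l, seeded by ``R_nn = r^n`` and
    ``R_n,n-2 = (n + 1/2) r^n - (n - 1/2) r^(n-2)``.  The coefficients are
    those of the Jacobi recurrence for ``r^l P_k^(0, l+1/2)(2 r^2 - 1)``;
    they keep ``R_nl(1) = 1`` exact to machine precision at high order.
    Entries for invalid (n, l) are zero.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any((r < 0) | (r > 1 + 1e-12)):
        raise ValueError("radii must lie in [0, 1]")
    out = np.zeros((n_max + 1, n_max + 1, r.size))
    r2 = r * r
    for l in range(n_max + 1):
        for n in range(l, n_max + 1, 2):
            if n == l:
                out[n, l] = r**n
            elif n == l + 2:
                out[n, l] = (n + 0.5) * r**n - (n - 0.5) * r ** (n - 2)
            else:
                k0 = (n - l) * (n + l + 1) * (2 * n - 3)
                k1 = (2 * n - 1) * (2 * n + 1) * (2 * n - 3)
                k2 = (-2 * n + 1) * (4 * l * l + 4 * l + 1) / 2.0 - k1 / 2.0
                k3 = -(n - l - 2) * (n + l - 1) * (2 * n + 1)
                out[n, l] = ((k1 * r2 + k2) * out[n - 2, l] + k3 * out[n - 4, l]) / k0
    return out


# ---------------------------------------------------------------------------
# streaming basis blocks shared by the forward and inverse transforms

def _basis_blocks(grid: UnitBallGrid, n_max: int, points: np.ndarray | None = None):
    """Yield per-degree blocks ``(l, ns, Y, R)`` over the grid's voxels.

    ``Y`` has shape ``(2l + 1, nvox)`` with rows ordered m = -l .. l;
    ``R`` has shape ``(len(ns), nvox)`` for radial orders
    ``ns = l, l+2, ..., n_max``.  Values are produced by the same recursions
    as the reference tables but only two Legendre rows are kept in memory.
    """
    if points is None:
        r, theta, phi = grid.r, grid.theta, grid.phi
    else:
        r, theta, phi = points
    ct, st = np.cos(theta), np.sin(theta)
    r2 = r * r
    p_prev: np.ndarray | None = None  # rows m = 0..l-1 at degree l-1
    p_prev2: np.ndarray | None = None
    for l in range(n_max + 1):
        if l == 0:
            p = np.full((1, r.size), np.sqrt(1.0 / (4.0 * np.pi)))
        else:
            p = np.empty((l + 1, r.size))
            p[l] = np.sqrt((2 * l + 1) / (2.0 * l)) * st * p_prev[l - 1]
            m = np.arange(l)
            cc = np.sqrt((2 * l + 1) / ((l + m) * (l - m)))
            c1 = (cc * np.sqrt(2 * l - 1.0))[:, None]
            p[:l] = c1 * ct * p_prev
            if l >= 2:
                m2 = np.arange(l - 1)
                c2 = (
                    np.sqrt((2 * l + 1) / ((l + m2) * (l - m2)))
                    * np.sqrt((l + m2 - 1) * (l - m2 - 1) / (2 * l - 3.0))
                )[:, None]
                p[: l - 1] -= c2 * p_prev2
        # harmonics for this degree
        y = np.empty((2 * l + 1, r.size))
        y[l] = p[0]
        for m in range(1, l + 1):
            y[l + m] = np.sqrt(2.0) * p[m] * np.cos(m * phi)
            y[l - m] = np.sqrt(2.0) * p[m] * np.sin(m * phi)
        # radial stack for this degree
        ns = list(range(l, n_max + 1, 2))
        rad = np.empty((len(ns), r.size))
        for i, n in enumerate(ns):
            if n == l:
                rad[i] = r**n
            elif n == l + 2:
                rad[i] = (n + 0.5) * r**n - (n - 0.5) * r ** (n - 2)
            else:
                k0 = (n - l) * (n + l + 1) * (2 * n - 3)
                k1 = (2 * n - 1) * (2 * n + 1) * (2 * n - 3)
                k2 = (-2 * n + 1) * (4 * l * l + 4 * l + 1) / 2.0 - k1 / 2.0
                k3 = -(n - l - 2) * (n + l - 1) * (2 * n + 1)
                rad[i] = ((k1 * r2 + k2) * rad[i - 1] + k3 * rad[i - 2]) / k0
        yield l, ns, y, rad
        p_prev, p_prev2 = p, (p_prev if p_prev is not None else np.zeros((0, r.size)))


# ---------------------------------------------------------------------------
# moments

@dataclass
class ZernikeMoments:
    """Real 3D Zernike moments ``Z_nlm`` up to ``max_order``.

    ``values`` is a flat array over :func:`valid_triples`; ``grid`` records
    the unit-ball mapping the moments were computed on.
    """

    max_order: int
    values: np.ndarray
    grid: UnitBallGrid
    _pos: dict = field(default=None, repr=False)

    def __post_init__(self):
        self._pos = {t: i for i, t in enumerate(valid_triples(self.max_order))}

    def get(self, n: int, l: int, m: int) -> float:
        return float(self.values[self._pos[(n, l, m)]])

    @property
    def triples(self) -> list[tuple[int, int, int]]:
        return valid_triples(self.max_order)

    def to_frame(self):
        import pandas as pd

        t = np.array(self.triples)
        return pd.DataFrame({"n": t[:, 0], "l": t[:, 1], "m": t[:, 2], "value": self.values})


@dataclass
class ZernikeDescriptor:
    """Rotation-invariant norms ``||Z_nl||`` ordered (n asc, l asc)."""

    max_order: int
    values: np.ndarray

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return valid_pairs(self.max_order)

    def to_frame(self):
        import pandas as pd

        t = np.array(self.pairs)
        return pd.DataFrame({"n": t[:, 0], "l": t[:, 1], "value": self.values})


def save_moments(moments: ZernikeMoments, csv_path, meta_path=None) -> None:
    """Write moments as CSV (columns n, l, m, value) plus JSON metadata
    (order, scaling radius) alongside."""
    import json

    moments.to_frame().to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {
            "max_order": moments.max_order,
            "cube_side": moments.grid.cube_side,
            "scale_radius": moments.grid.scale_radius,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def load_moments(csv_path, grid: UnitBallGrid) -> ZernikeMoments:
    import pandas as pd

    df = pd.read_csv(csv_path)
    n_max = int(df.n.max())
    mom = ZernikeMoments(n_max, np.zeros(moment_count_full(n_max)), grid)
    for rec in df.itertuples():
        mom.values[mom._pos[(int(rec.n), int(rec.l), int(rec.m))]] = rec.value
    return mom


def forward_transform(cube: np.ndarray, grid: UnitBallGrid, n_max: int) -> ZernikeMoments:
    """Project a voxel cube onto the Zernike basis.

    ``Z_nlm = (2n + 3) * sum_vox f * V_nlm * dV`` over in-ball voxels; the
    Cartesian voxel sum realises the ball integral exactly in measure (each
    voxel contributes volume ``scale_radius**-3`` in unit-ball units).
    """
    cube = np.asarray(cube, dtype=float)
    if cube.shape != (grid.cube_side,) * 3:
        raise ValueError("cube shape does not match grid")
    f = cube.ravel()[grid.index]
    nz = np.nonzero(f)[0]
    if nz.size == 0:
        return ZernikeMoments(n_max, np.zeros(moment_count_full(n_max)), grid)
    pts = (grid.r[nz], grid.theta[nz], grid.phi[nz])
    w = f[nz] * grid.voxel_volume_element
    out = np.zeros(moment_count_full(n_max))
    pos = {t: i for i, t in enumerate(valid_triples(n_max))}
    for l, ns, y, rad in _basis_blocks(grid, n_max, points=pts):
        a = (y * w) @ rad.T  # (2l+1, len(ns))
        for j, n in enumerate(ns):
            pref = 2 * n + 3
            for mi, m in enumerate(range(-l, l + 1)):
                out[pos[(n, l, m)]] = pref * a[mi, j]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite moments; order too large for this grid")
    return ZernikeMoments(n_max, out, grid)


def moment_count_full(n: int) -> int:
    """Total number of (n, l, m) triples including negative m."""
    return len(valid_triples(n))


def compute_descriptor(moments: ZernikeMoments) -> ZernikeDescriptor:
    """Collapse moments to rotation-invariant per-(n, l) vector norms."""
    vals = []
    for n, l in valid_pairs(moments.max_order):
        v = [moments.get(n, l, m) for m in range(-l, l + 1)]
        vals.append(np.sqrt(np.sum(np.square(v))))
    return ZernikeDescriptor(moments.max_order, np.asarray(vals))


def reconstruct(moments: ZernikeMoments, grid: UnitBallGrid, M: int) -> np.ndarray:
    """Evaluate the truncated expansion ``f_M`` on the grid's cube."""
    if M > moments.max_order:
        raise ValueError("requested order exceeds available moments")
    acc = np.zeros(grid.n_voxels)
    for l, ns, y, rad in _basis_blocks(grid, M):
        z = np.array(
            [[moments.get(n, l, m) for n in ns] for m in range(-l, l + 1)]
        )  # (2l+1, len(ns))
        acc += np.einsum("mn,nv,mv->v", z, rad, y, optimize=True)
    out = np.zeros(grid.cube_side**3)
    out[grid.index] = acc
    return out.reshape((grid.cube_side,) * 3)


def reconstruction_error(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Symmetric-difference error rate between a binary shape and its
    0.5-thresholded reconstruction, normalised by the original volume."""
    original = np.asarray(original)
    if original.shape != reconstructed.shape:
        raise ValueError("shape mismatch")
    orig = original > 0.5
    n_fg = int(orig.sum())
    if n_fg == 0:
        raise ValueError("original has no foreground voxels")
    rec = np.asarray(reconstructed) >= 0.5
    return float(np.logical_xor(orig, rec).sum()) / n_fg


def ball_quadrature(side: int, subsample: int = 4):
    """Quadrature nodes covering the unit ball at ``side**3`` resolution.

    Interior cells contribute their centre with unit weight; cells within
    ~1.5 voxels of the sphere surface are split into ``subsample**3``
    subcells (only subcells inside the ball count, each with weight
    ``subsample**-3``), which removes most of the boundary-voxelisation
    error.  Returns ``(r, theta, phi, weights)`` with weights in unit-ball
    volume units.
    """
    c = (side - 1) / 2
    radius = c - 0.5
    ax = np.arange(side) - c
    x, y, w = np.meshgrid(ax, ax, ax, indexing="ij")
    d = np.sqrt(x * x + y * y + w * w)
    interior = d <= radius - 1.5
    band = (~interior) & (d <= radius + 1)
    offs = (np.arange(subsample) + 0.5) / subsample - 0.5
    ox, oy, oz = (a.ravel() for a in np.meshgrid(offs, offs, offs, indexing="ij"))
    bx, by, bz = x[band], y[band], w[band]
    sx = np.concatenate([bx + dx for dx in ox])
    sy = np.concatenate([by + dy for dy in oy])
    sz = np.concatenate([bz + dz for dz in oz])
    inside = sx * sx + sy * sy + sz * sz <= radius * radius
    px = np.concatenate([x[interior], sx[inside]])
    py = np.concatenate([y[interior], sy[inside]])
    pz = np.concatenate([w[interior], sz[inside]])
    wt = np.concatenate(
        [np.ones(int(interior.sum())), np.full(int(inside.sum()), subsample**-3.0)]
    )
    dist = np.sqrt(px * px + py * py + pz * pz)
    r = np.minimum(dist / radius, 1.0)
    ratio = np.divide(pz, dist, out=np.zeros_like(dist), where=dist > 0)
    theta = np.where(dist > 0, np.arccos(np.clip(ratio, -1.0, 1.0)), 0.0)
    phi = np.arctan2(py, px)
    return r, theta, phi, wt / radius**3


def basis_gram_residual(side: int, n_max: int = 10, subsample: int = 4, chunk: int = 150000) -> float:
    """Max deviation of the discrete basis Gram matrix from identity.

    Rows are ``sqrt(2n + 3) V_nlm`` sampled on :func:`ball_quadrature`
    nodes; exact orthonormality would give the identity.  Serves as a
    numerical QC gate for the basis recursions and the ball quadrature.
    """
    r, theta, phi, wq = ball_quadrature(side, subsample)
    grid = build_unit_ball_grid(max(side, 2))
    nrows = sum((2 * l + 1) * len(range(l, n_max + 1, 2)) for l in range(n_max + 1))
    gram = np.zeros((nrows, nrows))
    for start in range(0, r.size, chunk):
        sl = slice(start, start + chunk)
        rows, prefs = [], []
        for l, ns, y, rad in _basis_blocks(grid, n_max, points=(r[sl], theta[sl], phi[sl])):
            for j, n in enumerate(ns):
                for mi in range(2 * l + 1):
                    rows.append(y[mi] * rad[j])
                    prefs.append(np.sqrt(2 * n + 3))
        mat = np.array(rows) * np.array(prefs)[:, None]
        gram += (mat * wq[sl]) @ mat.T
        del mat, rows
    return float(np.max(np.abs(gram - np.eye(nrows))))


def reconstruction_error_sweep(
    moments: ZernikeMoments, grid: UnitBallGrid, orders: list[int], original: np.ndarray
) -> list[float]:
    """Reconstruction error at each order in ``orders`` (single basis pass).

    Contributions are bucketed by radial order so that ``f_M`` for every
    requested ``M`` comes from one traversal of the basis.
    """
    orders = sorted(orders)
    m_max = orders[-1]
    buckets = np.zeros((len(orders), grid.n_voxels))
    bin_of = np.searchsorted(orders, np.arange(m_max + 1))
    for l, ns, y, rad in _basis_blocks(grid, m_max):
        z = np.array([[moments.get(n, l, m) for n in ns] for m in range(-l, l + 1)])
        contrib = np.einsum("mn,mv->nv", z, y) * rad  # (len(ns), nvox) summed over m
        for j, n in enumerate(ns):
            buckets[bin_of[n]] += contrib[j]
    errs = []
    acc = np.zeros(grid.n_voxels)
    for b in range(len(orders)):
        acc += buckets[b]
        cube = np.zeros(grid.cube_side**3)
        cube[grid.index] = acc
        errs.append(reconstruction_error(original, cube.reshape((grid.cube_side,) * 3)))
    return errs
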