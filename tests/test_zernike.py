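"""Unit tests for the 3D Zernike basis, moments and reconstructions."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.special import eval_jacobi, sph_harm_y

from conftest import axis_rotations, rotate_cube
from wmh3d import zernike as z


# ---------------------------------------------------------------------------
# unit-ball grid

class TestUnitBallGrid:
    def test_corner_voxel_on_unit_sphere(self):
        g = z.build_unit_ball_grid(3)
        corner = np.argwhere(g.index == 0)[0][0]
        assert g.r[corner] == pytest.approx(1.0)

    def test_center_voxel_conventions(self):
        g = z.build_unit_ball_grid(3)
        mid = np.argwhere(g.index == 13)[0][0]  # (1,1,1) in a 3-cube
        assert g.r[mid] == 0.0
        assert g.theta[mid] == 0.0 and g.phi[mid] == 0.0

    def test_scale_radius_formula(self):
        g = z.build_unit_ball_grid(36)
        assert g.scale_radius == pytest.approx(np.sqrt(3) * 17.5)
        assert g.voxel_volume_element == pytest.approx(g.scale_radius**-3)

    def test_all_voxels_inside_for_cube_in_ball(self):
        g = z.build_unit_ball_grid(8)
        assert g.n_voxels == 8**3
        assert np.all(g.r <= 1.0)

    def test_tight_fit_requires_occupied(self):
        with pytest.raises(ValueError):
            z.build_unit_ball_grid(8, scaling="tight_fit")

    def test_tight_fit_scale(self):
        occ = np.array([[3, 3, 3], [5, 3, 3]])  # center of 8-cube is 3.5
        g = z.build_unit_ball_grid(8, scaling="tight_fit", occupied_voxels=occ)
        assert g.scale_radius == pytest.approx(np.sqrt(1.5**2 + 0.5**2 + 0.5**2) + 0.5)

    def test_too_small_cube_rejected(self):
        with pytest.raises(ValueError):
            z.build_unit_ball_grid(1)


# ---------------------------------------------------------------------------
# associated Legendre / spherical harmonics

class TestHarmonics:
    def test_p00_constant(self):
        p = z.normalized_assoc_legendre(0, np.array([-1.0, 0.0, 0.7]))
        assert np.allclose(p[0, 0], np.sqrt(1 / (4 * np.pi)))

    def test_p10_closed_form(self):
        # orthonormal convention: P~_1^0(x) = sqrt(3/(4 pi)) x
        p = z.normalized_assoc_legendre(1, np.array([1.0, 0.5]))
        assert p[1, 0, 0] == pytest.approx(np.sqrt(3 / (4 * np.pi)))
        assert p[1, 0, 1] == pytest.approx(np.sqrt(3 / (4 * np.pi)) * 0.5)

    def test_legendre_orthonormality_by_quadrature(self):
        lmax = 12
        x, w = np.polynomial.legendre.leggauss(64)
        p = z.normalized_assoc_legendre(lmax, x)
        for m in range(4):
            for l1 in range(m, lmax + 1):
                for l2 in range(m, lmax + 1):
                    # 2 pi int P~_l^m P~_l'^m dx = delta for every m (the
                    # sqrt(2)/cos/sin factors integrate to the same 2 pi)
                    val = 2 * np.pi * np.sum(w * p[l1, m] * p[l2, m])
                    assert val == pytest.approx(1.0 if l1 == l2 else 0.0, abs=1e-10)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            z.normalized_assoc_legendre(2, np.array([1.5]))

    def test_against_scipy_spherical_harmonics(self):
        """Real harmonics match the complex scipy ones combined into the
        real basis (up to the Condon-Shortley phase)."""
        rng = np.random.default_rng(7)
        theta = rng.uniform(0.1, np.pi - 0.1, 20)
        phi = rng.uniform(-np.pi, np.pi, 20)
        y = z.real_spherical_harmonics(6, theta, phi)
        for l in range(7):
            for m in range(0, l + 1):
                ylm = sph_harm_y(l, m, theta, phi)
                if m == 0:
                    expect = ylm.real
                    np.testing.assert_allclose(y[l, 6], expect, atol=1e-12)
                else:
                    expect_cos = np.sqrt(2) * (-1) ** m * ylm.real
                    expect_sin = np.sqrt(2) * (-1) ** m * ylm.imag
                    # our convention omits Condon-Shortley: compare |.|
                    np.testing.assert_allclose(
                        np.abs(y[l, 6 + m]), np.abs(expect_cos), atol=1e-12
                    )
                    np.testing.assert_allclose(
                        np.abs(y[l, 6 - m]), np.abs(expect_sin), atol=1e-12
                    )

    def test_y00_constant_and_sin_zero(self):
        y = z.real_spherical_harmonics(1, np.array([0.3]), np.array([0.0]))
        assert y[0, 1, 0] == pytest.approx(np.sqrt(1 / (4 * np.pi)))
        assert y[1, 0, 0] == pytest.approx(0.0)  # Y_1^{-1} at phi=0

    def test_harmonic_orthonormality_quadrature(self):
        lmax = 5
        nt, np_ = 80, 160
        theta = (np.arange(nt) + 0.5) * np.pi / nt
        phi = (np.arange(np_) + 0.5) * 2 * np.pi / np_
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        y = z.real_spherical_harmonics(lmax, tt.ravel(), pp.ravel())
        dA = np.sin(tt.ravel()) * (np.pi / nt) * (2 * np.pi / np_)
        rows = [(l, m) for l in range(lmax + 1) for m in range(-l, l + 1)]
        mat = np.array([y[l, lmax + m] for l, m in rows])
        gram = (mat * dA) @ mat.T
        np.testing.assert_allclose(gram, np.eye(len(rows)), atol=2e-3)


# ---------------------------------------------------------------------------
# radial polynomials

class TestRadial:
    def test_r00_is_one(self):
        r = np.linspace(0, 1, 11)
        tab = z.radial_polynomials(4, r)
        np.testing.assert_allclose(tab[0, 0], 1.0)

    def test_r20_printed_form(self):
        r = np.array([0.0, 0.5, 1.0])
        tab = z.radial_polynomials(2, r)
        np.testing.assert_allclose(tab[2, 0], 2.5 * r**2 - 1.5)
        assert tab[2, 0, 0] == pytest.approx(-1.5)
        assert tab[2, 0, 2] == pytest.approx(1.0)

    def test_diagonal_is_power(self):
        r = np.linspace(0, 1, 9)
        tab = z.radial_polynomials(7, r)
        for n in range(8):
            np.testing.assert_allclose(tab[n, n], r**n, atol=1e-13)

    def test_against_jacobi_closed_form(self):
        """Recursion agrees with R_nl = r^l P_k^(0, l+1/2)(2r^2-1)."""
        r = np.linspace(0, 1, 33)
        nmax = 30
        tab = z.radial_polynomials(nmax, r)
        for n, l in z.valid_pairs(nmax):
            k = (n - l) // 2
            expect = r**l * eval_jacobi(k, 0, l + 0.5, 2 * r**2 - 1)
            np.testing.assert_allclose(tab[n, l], expect, atol=1e-10)

    def test_endpoint_unity_to_order_250(self):
        tab = z.radial_polynomials(250, np.array([1.0]))
        for n, l in z.valid_pairs(250):
            assert abs(tab[n, l, 0] - 1.0) < 1e-6

    def test_radial_orthogonality_quadrature(self):
        """int_0^1 R_nl R_n'l r^2 dr = delta / (2n+3) to 1e-8 (n <= 50)."""
        nodes, weights = np.polynomial.legendre.leggauss(128)
        r = 0.5 * (nodes + 1)
        w = 0.5 * weights * r**2
        nmax = 50
        tab = z.radial_polynomials(nmax, r)
        for l in range(0, nmax + 1, 5):
            ns = list(range(l, nmax + 1, 2))
            mat = np.array([tab[n, l] for n in ns])
            gram = (mat * w) @ mat.T
            expect = np.diag([1.0 / (2 * n + 3) for n in ns])
            np.testing.assert_allclose(gram, expect, atol=1e-8)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            z.radial_polynomials(4, np.array([1.5]))


# ---------------------------------------------------------------------------
# counts and dimensions

class TestCounts:
    @pytest.mark.parametrize("n,expect", [(0, 1), (2, 7), (4, 22)])
    def test_moment_count_examples(self, n, expect):
        assert z.moment_count(n) == expect

    @pytest.mark.parametrize("n,expect", [(1, 2), (100, 2601), (250, 15876)])
    def test_descriptor_dimension_examples(self, n, expect):
        assert z.descriptor_dimension(n) == expect

    def test_against_enumeration(self):
        for n in range(0, 301, 23):
            pairs = [(a, l) for a in range(n + 1) for l in range(a % 2, a + 1, 2)]
            triples = [(a, l, m) for a, l in pairs for m in range(l + 1)]
            assert z.descriptor_dimension(n) == len(pairs)
            assert z.moment_count(n) == len(triples)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            z.moment_count(-1)
        with pytest.raises(ValueError):
            z.descriptor_dimension(-1)


# ---------------------------------------------------------------------------
# forward transform / descriptor / reconstruction

class TestTransform:
    def test_zero_field_zero_moments(self, grid16):
        mom = z.forward_transform(np.zeros((16,) * 3), grid16, 6)
        assert np.all(mom.values == 0)

    @staticmethod
    def _discrete_unit_ball(side):
        """Grid scaled to a centred ball plus the f=1 indicator of every
        in-ball voxel — the voxel realisation of 'f = 1 on the unit ball'."""
        c = (side - 1) / 2
        ax = np.arange(side) - c
        x, y, w = np.meshgrid(ax, ax, ax, indexing="ij")
        occ = np.argwhere(x**2 + y**2 + w**2 <= (c - 1) ** 2)
        g = z.build_unit_ball_grid(side, scaling="tight_fit", occupied_voxels=occ)
        ball = np.zeros((side,) * 3)
        ball.ravel()[g.index] = 1.0
        return g, ball

    def test_constant_ball_z000(self):
        """f = 1 on a voxelised unit ball: Z_000 -> sqrt(4 pi), rest -> 0."""
        g, ball = self._discrete_unit_ball(32)
        mom = z.forward_transform(ball, g, 4)
        assert mom.get(0, 0, 0) == pytest.approx(np.sqrt(4 * np.pi), rel=0.01)
        others = [abs(mom.get(n, l, m)) for n, l, m in mom.triples if (n, l, m) != (0, 0, 0)]
        assert max(others) < 0.05 * np.sqrt(4 * np.pi)

    def test_reconstruct_constant_ball_order0(self):
        g, ball = self._discrete_unit_ball(32)
        mom = z.forward_transform(ball, g, 0)
        rec = z.reconstruct(mom, g, 0)
        inner = rec.ravel()[g.index]
        assert inner.mean() == pytest.approx(1.0, abs=0.01)

    def test_shape_mismatch(self, grid16):
        with pytest.raises(ValueError):
            z.forward_transform(np.zeros((8, 8, 8)), grid16, 4)

    def test_descriptor_of_single_moment(self, grid16):
        mom = z.ZernikeMoments(4, np.zeros(z.moment_count_full(4)), grid16)
        mom.values[mom._pos[(2, 0, 0)]] = 5.0
        desc = z.compute_descriptor(mom)
        idx = desc.pairs.index((2, 0))
        assert desc.values[idx] == pytest.approx(5.0)
        assert np.sum(desc.values) == pytest.approx(5.0)

    def test_zero_moments_descriptor_and_field(self, grid16):
        mom = z.ZernikeMoments(4, np.zeros(z.moment_count_full(4)), grid16)
        assert np.all(z.compute_descriptor(mom).values == 0)
        assert np.all(z.reconstruct(mom, grid16, 4) == 0)

    def test_descriptor_invariant_under_cube_rotations(self, ellipsoid32):
        g = z.build_unit_ball_grid(32)
        base = z.compute_descriptor(z.forward_transform(ellipsoid32, g, 8)).values
        for perm, flips in axis_rotations()[:8]:
            rot = rotate_cube(ellipsoid32, perm, flips)
            d = z.compute_descriptor(z.forward_transform(rot, g, 8)).values
            np.testing.assert_allclose(d, base, atol=1e-9)

    def test_descriptor_invariant_under_arbitrary_rotation(self):
        """Smooth phantom, tricubic resampling: descriptors within 2%."""
        side = 32
        c = (side - 1) / 2
        ax = np.arange(side) - c
        x, y, w = np.meshgrid(ax, ax, ax, indexing="ij")
        cube = np.exp(-((x / 6.0) ** 2 + (y / 4.0) ** 2 + (w / 3.0) ** 2))
        rot = ndimage.rotate(cube, 33.0, axes=(0, 1), reshape=False, order=3)
        rot = ndimage.rotate(rot, 21.0, axes=(1, 2), reshape=False, order=3)
        g = z.build_unit_ball_grid(side)
        d0 = z.compute_descriptor(z.forward_transform(cube, g, 16)).values
        d1 = z.compute_descriptor(z.forward_transform(rot, g, 16)).values
        assert np.linalg.norm(d1 - d0) / np.linalg.norm(d0) < 0.02

    def test_reconstruction_error_trivials(self):
        a = np.zeros((4, 4, 4))
        a[1:3, 1:3, 1:3] = 1
        assert z.reconstruction_error(a, a.copy()) == 0.0
        b = np.zeros_like(a)
        b[0, 0, :2] = 1
        b[0, 1, :2] = 1
        b[3, 3, :2] = 1
        b[3, 2, :2] = 1
        assert z.reconstruction_error(a, b) == pytest.approx(2.0)

    def test_reconstruction_error_empty_foreground(self):
        with pytest.raises(ValueError):
            z.reconstruction_error(np.zeros((3, 3, 3)), np.zeros((3, 3, 3)))

    def test_order_exceeds_available(self, grid16):
        mom = z.ZernikeMoments(4, np.zeros(z.moment_count_full(4)), grid16)
        with pytest.raises(ValueError):
            z.reconstruct(mom, grid16, 6)

    def test_roundtrip_improves_with_order(self, ellipsoid32):
        g = z.build_unit_ball_grid(32)
        mom = z.forward_transform(ellipsoid32, g, 24)
        errs = z.reconstruction_error_sweep(mom, g, [8, 16, 24], ellipsoid32)
        assert errs[-1] <= errs[0]
        assert errs[-1] < 0.3

    def test_sweep_matches_direct_reconstruction(self, ellipsoid32):
        g = z.build_unit_ball_grid(32)
        mom = z.forward_transform(ellipsoid32, g, 12)
        errs = z.reconstruction_error_sweep(mom, g, [6, 12], ellipsoid32)
        direct6 = z.reconstruction_error(ellipsoid32, z.reconstruct(mom, g, 6))
        direct12 = z.reconstruction_error(ellipsoid32, z.reconstruct(mom, g, 12))
        assert errs == [direct6, direct12]


def test_moments_csv_roundtrip(tmp_path, grid16, ellipsoid32):
    small = ellipsoid32[8:24, 8:24, 8:24]
    mom = z.forward_transform(small, grid16, 6)
    z.save_moments(mom, tmp_path / "m.csv", tmp_path / "m.json")
    back = z.load_moments(tmp_path / "m.csv", grid16)
    np.testing.assert_allclose(back.values, mom.values)
    desc = z.compute_descriptor(mom).to_frame()
    assert list(desc.columns) == ["n", "l", "value"]
    assert len(desc) == z.descriptor_dimension(6)


def ball_grid(side):
    """Grid whose in-ball voxels cover the whole unit ball (ball-scaled)."""
    c = (side - 1) / 2
    ax = np.arange(side) - c
    x, y, w = np.meshgrid(ax, ax, ax, indexing="ij")
    occ = np.argwhere(x**2 + y**2 + w**2 <= (c - 1) ** 2)
    return z.build_unit_ball_grid(side, scaling="tight_fit", occupied_voxels=occ)


def test_basis_orthonormality_residual_shrinks():
    """Discrete basis Gram approaches identity as the grid refines.

    The quadrature must cover the whole unit ball, so the grid is scaled to
    a centred ball rather than to the cube corners."""
    residuals = []
    for side in (16, 32):
        g = ball_grid(side)
        rows, prefs = [], []
        for l, ns, y, rad in z._basis_blocks(g, 6):
            for j, n in enumerate(ns):
                for mi in range(2 * l + 1):
                    rows.append(y[mi] * rad[j])
                    prefs.append(np.sqrt(2 * n + 3))
        mat = np.array(rows) * np.array(prefs)[:, None]
        gram = (mat * g.voxel_volume_element) @ mat.T
        residuals.append(np.max(np.abs(gram - np.eye(len(rows)))))
    assert residuals[1] < residuals[0]
    assert residuals[1] < 5e-2
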