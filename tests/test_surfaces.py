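"""Layering pipeline: SDFs, Laplace potential, normals, curvature, offsets."""

import warnings

import numpy as np
import pytest

from lamglm.grid import Grid
from lamglm.surfaces import (
    compute_layering,
    equivolume_offsets,
    gradient_field,
    mean_curvature,
    signed_distance,
    solve_laplace,
)


def centred_grid(n, h):
    return Grid((n, n, n), h, -np.full(3, (n - 1) * h / 2))


class TestSignedDistance:
    def test_sphere_mask(self):
        g = centred_grid(32, 1.0)
        X, Y, Z = g.meshgrid()
        dist = np.sqrt(X**2 + Y**2 + Z**2)
        sdf = signed_distance(dist < 8.0, g)
        band = (dist > 2) & (dist < 14)
        assert np.max(np.abs(sdf - (dist - 8.0))[band]) < 1.0  # within one voxel

    def test_plane_slab_is_linear_ramp(self):
        g = centred_grid(24, 1.0)
        Z = g.meshgrid()[2]
        sdf = signed_distance(Z < 2.2, g)
        inner = np.abs(Z - 2.2) > 2
        assert np.allclose(sdf[inner], (Z - 2.7)[inner], atol=1.0)

    def test_random_blob_matches_brute_force(self, rng):
        g = Grid((20, 20, 20), 1.0, (0, 0, 0))
        X, Y, Z = g.meshgrid()
        # smooth random blob from a few seeded spheres
        mask = np.zeros(g.shape, bool)
        for _ in range(3):
            c = rng.uniform(6, 14, 3)
            r = rng.uniform(3, 5)
            mask |= (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 < r**2
        sdf = signed_distance(mask, g)
        # oracle: exhaustive distance to the interface voxels
        from scipy import ndimage

        surface = mask & ~ndimage.binary_erosion(mask)
        spts = np.argwhere(surface).astype(float)
        pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        brute = np.min(
            np.linalg.norm(pts[:, None, :] - spts[None, :, :], axis=-1), axis=1
        ).reshape(g.shape)
        assert np.max(np.abs(np.abs(sdf) - brute)) <= np.sqrt(3.0)

    def test_rejects_trivial_masks(self):
        g = centred_grid(8, 1.0)
        with pytest.raises(ValueError):
            signed_distance(np.zeros(g.shape, bool), g)


class TestLaplace:
    def test_flat_slab_linear_potential(self):
        g = Grid((6, 6, 30), 1.0, (0, 0, 0))
        Z = g.meshgrid()[2]
        wm = Z < 9.5
        ribbon = (Z > 9.5) & (Z < 20.5)
        pial = Z > 20.5
        pot = solve_laplace(wm, ribbon, pial, g)
        col = pot[3, 3, 10:21]
        assert np.allclose(col, np.arange(1, 12) / 12.0, atol=1e-6)
        assert np.all(pot[wm] == 0) and np.all(pot[pial] == 1)

    def test_annulus_log_radial(self):
        g = Grid((64, 64, 4), 0.25, (0, 0, 0))
        X, Y, _ = g.meshgrid()
        rr = np.hypot(X - 7.875, Y - 7.875)
        pot = solve_laplace(rr <= 2, (rr > 2) & (rr < 4), rr >= 4, g)
        ana = np.log(np.clip(rr, 1e-9, None) / 2.0) / np.log(2.0)
        band = (rr > 2.4) & (rr < 3.6)
        assert np.max(np.abs(pot - ana)[band]) < 0.05

    def test_disconnected_component_flagged(self):
        g = Grid((12, 12, 12), 1.0, (0, 0, 0))
        Z = g.meshgrid()[2]
        wm = Z < 2.5
        ribbon = ((Z > 2.5) & (Z < 6.5)) | (Z > 8.5)  # top slab touches nothing
        pial = (Z > 6.5) & (Z < 8.5)
        with pytest.warns(RuntimeWarning, match="one boundary set"):
            solve_laplace(wm, ribbon & ~pial, pial, g)


class TestGradientField:
    def test_slab_gives_constant_z(self):
        g = Grid((6, 6, 30), 1.0, (0, 0, 0))
        Z = g.meshgrid()[2]
        pot = np.clip((Z - 10) / 10.0, 0, 1)
        ribbon = (Z > 10) & (Z < 20)
        nf = gradient_field(pot, g, tukey_alpha=0.5, ribbon_mask=ribbon)
        assert np.allclose(nf[ribbon], [0, 0, 1], atol=1e-9)

    def test_no_taper_equals_plain_spectral_derivative(self):
        from lamglm.surfaces import _spectral_gradient

        g = Grid((16, 16, 16), 0.5, (0, 0, 0))
        X = g.meshgrid()[0]
        L = 16 * 0.5
        f = np.sin(2 * np.pi * X / L)
        grad = _spectral_gradient(f, g, tukey_alpha=0.0)
        # the spectral derivative of a resolved harmonic is exact
        expected = (2 * np.pi / L) * np.cos(2 * np.pi * X / L)
        assert np.allclose(grad[..., 0], expected, atol=1e-9)
        assert np.allclose(grad[..., 1:], 0.0, atol=1e-9)

    def test_annulus_radial_within_two_degrees(self):
        g = Grid((64, 64, 8), 0.25, (0, 0, 0))
        X, Y, _ = g.meshgrid()
        rr = np.hypot(X - 7.875, Y - 7.875)
        pot = np.log(np.clip(rr, 0.25, None) / 2.0) / np.log(2.0)
        nf = gradient_field(np.clip(pot, 0, 1), g, tukey_alpha=0.5)
        rad = np.stack(
            [(X - 7.875) / np.clip(rr, 1e-9, None),
             (Y - 7.875) / np.clip(rr, 1e-9, None),
             np.zeros_like(rr)],
            axis=-1,
        )
        band = (rr > 2.4) & (rr < 3.6)
        cosang = np.clip(np.sum(nf * rad, axis=-1), -1, 1)
        assert np.degrees(np.arccos(cosang[band])).max() < 2.0


class TestMeanCurvature:
    def test_flat_slab_zero(self):
        g = Grid((8, 8, 20), 1.0, (0, 0, 0))
        nf = np.zeros(g.shape + (3,))
        nf[..., 2] = 1.0
        assert np.allclose(mean_curvature(nf, g), 0.0, atol=1e-12)

    def test_sphere_radial_field(self):
        g = centred_grid(32, 1.0)
        X, Y, Z = g.meshgrid()
        r = np.sqrt(X**2 + Y**2 + Z**2)
        nf = np.stack([X, Y, Z], axis=-1) / np.clip(r, 1e-9, None)[..., None]
        curv = mean_curvature(nf, g)
        band = (r > 5) & (r < 12)
        assert np.max(np.abs(curv[band] * r[band] - 1.0)) < 0.05

    def test_extruded_cylinder_half_radial(self):
        g = Grid((48, 48, 8), 0.5, (0, 0, 0))
        X, Y, _ = g.meshgrid()
        rr = np.hypot(X - 11.75, Y - 11.75)
        nf = np.stack(
            [(X - 11.75) / np.clip(rr, 1e-9, None),
             (Y - 11.75) / np.clip(rr, 1e-9, None),
             np.zeros_like(rr)],
            axis=-1,
        )
        curv = mean_curvature(nf, g)
        band = (rr > 4) & (rr < 10)
        assert np.max(np.abs(curv[band] * 2 * rr[band] - 1.0)) < 0.05


class TestEquivolumeOffsets:
    def test_flat_cortex_equidistant(self):
        g = Grid((4, 4, 40), 0.25, (0, 0, 0))
        Z = g.meshgrid()[2]
        sdf_wm = Z - 3.0  # WM surface at depth-0 plane z=3
        sdf_pial = Z - 6.0  # pial at z=6, thickness 3
        nf = np.zeros(g.shape + (3,))
        nf[..., 2] = 1.0
        curv = np.zeros(g.shape)
        lb = equivolume_offsets(sdf_wm, sdf_pial, curv, nf, g, k=6)
        depths = lb.depth[:, None] + lb.offsets
        assert np.allclose(depths, np.linspace(0, 3, 7)[None, :], atol=1e-9)

    def test_annulus_matches_analytic_equal_area(self):
        g = Grid((64, 64, 4), 0.25, (0, 0, 0))
        X, Y, _ = g.meshgrid()
        rr = np.hypot(X - 7.875, Y - 7.875)
        rad = np.stack(
            [(X - 7.875) / np.clip(rr, 1e-9, None),
             (Y - 7.875) / np.clip(rr, 1e-9, None),
             np.zeros_like(rr)],
            axis=-1,
        )
        lb = equivolume_offsets(
            rr - 2.0, rr - 4.0, 1.0 / (2 * np.clip(rr, 1e-9, None)), rad, g, k=2
        )
        boundary_radius = rr[lb.support] + lb.offsets[:, 1]
        assert np.allclose(boundary_radius, np.sqrt(10.0), rtol=1e-4)

    def test_endpoints_are_surface_crossings_for_any_curvature(self, rng):
        g = Grid((4, 4, 4), 1.0, (0, 0, 0))
        sdf_wm = rng.uniform(0.2, 2.0, g.shape)
        sdf_pial = sdf_wm - 3.0
        curv = rng.uniform(-0.15, 0.15, g.shape)
        nf = np.zeros(g.shape + (3,))
        nf[..., 2] = 1.0
        lb = equivolume_offsets(
            sdf_wm, sdf_pial, curv, nf, g, k=4, support=np.ones(g.shape, bool)
        )
        assert np.allclose(lb.offsets[:, 0], -lb.depth, atol=1e-9)
        assert np.allclose(lb.offsets[:, -1], -sdf_pial[lb.support], atol=1e-9)

    def test_offsets_ascend_and_reduce_to_equidistant_at_tiny_curvature(self):
        g = Grid((2, 2, 2), 1.0, (0, 0, 0))
        sdf_wm = np.full(g.shape, 1.3)
        sdf_pial = sdf_wm - 3.0
        nf = np.zeros(g.shape + (3,))
        nf[..., 2] = 1.0
        lb = equivolume_offsets(
            sdf_wm, sdf_pial, np.full(g.shape, 1e-7), nf, g, k=6,
            support=np.ones(g.shape, bool),
        )
        assert np.all(np.diff(lb.offsets, axis=1) > 0)
        assert np.allclose(lb.depth[:, None] + lb.offsets,
                           np.linspace(0, 3, 7)[None, :], atol=1e-5)

    def test_extreme_curvature_clamped_with_warning(self):
        g = Grid((2, 2, 2), 1.0, (0, 0, 0))
        sdf_wm = np.full(g.shape, 2.0)
        sdf_pial = sdf_wm - 3.0
        nf = np.zeros(g.shape + (3,))
        nf[..., 2] = 1.0
        with pytest.warns(RuntimeWarning, match="clamped"):
            lb = equivolume_offsets(
                sdf_wm, sdf_pial, np.full(g.shape, -2.0), nf, g, k=3,
                support=np.ones(g.shape, bool),
            )
        assert np.all(np.isfinite(lb.offsets))

    def test_unequal_layer_fractions(self):
        g = Grid((2, 2, 2), 1.0, (0, 0, 0))
        sdf_wm = np.full(g.shape, 1.0)
        sdf_pial = sdf_wm - 2.0
        nf = np.zeros(g.shape + (3,))
        nf[..., 2] = 1.0
        lb = equivolume_offsets(
            sdf_wm, sdf_pial, np.zeros(g.shape), nf, g,
            layer_fractions_spec=[0.25, 0.75], support=np.ones(g.shape, bool),
        )
        depths = lb.depth[:, None] + lb.offsets
        assert np.allclose(depths, [[0.0, 0.5, 2.0]], atol=1e-9)


class TestComputeLayering:
    def test_slab_masks_give_equidistant_boundaries(self):
        g = Grid((8, 8, 16), 1.0, (0, 0, 0))
        Z = g.meshgrid()[2]
        wm_inside = Z < 4.6
        pial_inside = Z < 10.6
        boundaries, depth = compute_layering(wm_inside, pial_inside, g, k=3,
                                             upsample=2)
        assert boundaries.grid.shape == (16, 16, 32)
        ribbon = depth.ribbon_mask
        assert ribbon.any()
        # thickness ~ 6 mm everywhere in the ribbon interior
        interior = ribbon & (depth.sdf_wm > 1) & (depth.sdf_pial < -1)
        assert np.allclose(boundaries.thickness.mean(), 6.0, atol=0.5)
        # boundaries ascend everywhere
        assert np.all(np.diff(boundaries.offsets, axis=1) >= 0)
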