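"""Shape descriptors: spheres, corners, axes, and the Welzl ball."""

import itertools

import numpy as np
import pytest
import trimesh
from scipy.spatial import ConvexHull

import hippomorph as hm
from hippomorph import phantoms as ph
from hippomorph.morphometry import (CornerRegion, CornerSet, ShapeDescriptors,
                                    SphereFit, aspect_ratio,
                                    compute_volume_surface, detect_corners,
                                    max_inscribed_sphere, min_enclosing_sphere,
                                    principal_axes, roundness, sphere_fit,
                                    sphericity)
from hippomorph.reconstruction import SurfaceMesh

from conftest import ELLIPSOID_ROTATION


def _as_surface_mesh(tm: trimesh.Trimesh) -> SurfaceMesh:
    return SurfaceMesh(vertices=np.asarray(tm.vertices, float),
                       triangles=np.asarray(tm.faces, np.int64),
                       normals=np.asarray(tm.vertex_normals, float))


def brute_force_min_ball(points: np.ndarray) -> float:
    """O(n^4) reference: try every ball defined by <= 4 support points.

    The minimum enclosing ball is determined by points of the convex hull,
    so the search runs over hull vertices only (pure speed-up, same result).
    """
    from hippomorph.morphometry import _circumsphere
    pts = points[ConvexHull(points).vertices]
    best = np.inf
    for k in (2, 3, 4):
        for combo in itertools.combinations(range(len(pts)), k):
            c, r = _circumsphere(pts[list(combo)])
            if r < best and np.all(
                    np.linalg.norm(points - c, axis=1) <= r * (1 + 1e-9)):
                best = r
    return best


class TestVolumeSurface:
    def test_icosphere_closed_forms(self):
        mesh = _as_surface_mesh(trimesh.creation.icosphere(subdivisions=4,
                                                           radius=10.0))
        vol, area = compute_volume_surface(mesh)
        assert vol == pytest.approx(4.18879, rel=0.005)
        assert area == pytest.approx(12.56637, rel=0.005)

    def test_cube_exact(self):
        mesh = _as_surface_mesh(trimesh.creation.box(extents=(20, 20, 20)))
        vol, area = compute_volume_surface(mesh)
        assert vol == pytest.approx(8.0, abs=1e-9)
        assert area == pytest.approx(24.0, abs=1e-9)

    def test_capsule_phantom_mesh_matches_closed_forms(self, capsule_bundle):
        vol, area = compute_volume_surface(capsule_bundle.mesh)
        assert vol == pytest.approx(capsule_bundle.truth.volume_cm3, rel=0.02)
        assert area == pytest.approx(capsule_bundle.truth.surface_cm2, rel=0.02)

    def test_open_mesh_rejected_with_boundary_count(self):
        tm = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        open_mesh = _as_surface_mesh(
            trimesh.Trimesh(tm.vertices, tm.faces[:-1], process=False))
        with pytest.raises(ValueError, match="3 boundary edges"):
            compute_volume_surface(open_mesh)


class TestInscribedSphere:
    def test_sphere_radius(self, sphere_bundle):
        r, center = max_inscribed_sphere(sphere_bundle.field,
                                         sphere_bundle.mesh)
        assert r == pytest.approx(9.2, abs=0.25)
        assert np.linalg.norm(center - 12.0) < 1.0

    def test_ellipsoid_radius_is_smallest_semi_axis(self, ellipsoid_bundle):
        r, _ = max_inscribed_sphere(ellipsoid_bundle.field,
                                    ellipsoid_bundle.mesh)
        assert r == pytest.approx(10.0, abs=0.3)

    def test_capsule_radius_is_tube_radius(self, capsule_bundle):
        r, _ = max_inscribed_sphere(capsule_bundle.field, capsule_bundle.mesh)
        assert r == pytest.approx(5.0, abs=0.25)



class TestMinEnclosingSphere:
    def test_two_points(self):
        r, c = min_enclosing_sphere(np.array([[0, 0, 0], [10, 0, 0.0]]))
        assert r == pytest.approx(5.0, abs=1e-9)
        assert c == pytest.approx([5, 0, 0], abs=1e-9)

    def test_cube_corners(self):
        corners = np.array(list(itertools.product([0, 20.0], repeat=3)))
        r, c = min_enclosing_sphere(corners)
        assert r == pytest.approx(10 * np.sqrt(3), abs=1e-9)
        assert c == pytest.approx([10, 10, 10], abs=1e-9)

    @pytest.mark.parametrize("n,seed", [(30, 0), (80, 1), (250, 2)])
    def test_matches_brute_force_on_seeded_points(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 5, (n, 3))
        r, c = min_enclosing_sphere(pts)
        assert r == pytest.approx(brute_force_min_ball(pts), abs=1e-6)
        # enclosing property within relative tolerance
        assert np.linalg.norm(pts - c, axis=1).max() <= r * (1 + 1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 2, (100, 3))
        r1, c1 = min_enclosing_sphere(pts)
        r2, c2 = min_enclosing_sphere(pts)
        assert r1 == r2 and np.array_equal(c1, c2)


class TestSphericity:
    def test_arithmetic(self):
        fit = SphereFit(r_in_max=0.4, center_in=np.zeros(3),
                        r_cir_min=1.0, center_cir=np.zeros(3))
        assert sphericity(fit) == pytest.approx(0.4, abs=1e-12)

    def test_sphere_close_to_one(self, sphere_bundle):
        assert sphericity(sphere_fit(sphere_bundle.field,
                                     sphere_bundle.mesh)) == pytest.approx(
            1.0, abs=0.05)

    def test_ellipsoid_c_over_a(self, ellipsoid_bundle):
        assert sphericity(sphere_fit(ellipsoid_bundle.field,
                                     ellipsoid_bundle.mesh)) == pytest.approx(
            0.5, abs=0.03)

    def test_inverted_radii_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            SphereFit(r_in_max=2.0, center_in=np.zeros(3),
                      r_cir_min=1.0, center_cir=np.zeros(3))


class TestCorners:
    def test_sphere_single_region_with_sphere_radius(self, sphere_bundle):
        fit = sphere_fit(sphere_bundle.field, sphere_bundle.mesh)
        corners = detect_corners(sphere_bundle.mesh, fit.r_in_max)
        assert corners.n == 1
        assert corners.radii_mm[0] == pytest.approx(9.2, rel=0.05)

    def test_capsule_two_cap_regions(self, capsule_bundle):
        fit = sphere_fit(capsule_bundle.field, capsule_bundle.mesh)
        corners = detect_corners(capsule_bundle.mesh, fit.r_in_max)
        assert corners.n == 2
        assert corners.radii_mm == pytest.approx([5.0, 5.0], rel=0.10)

    def test_ellipsoid_sharpest_radius_at_tips(self, ellipsoid_bundle):
        """The sharpest corner curvature radius is c^2/a at the long-axis
        tips (5 mm for the 20/15/10 ellipsoid)."""
        fit = sphere_fit(ellipsoid_bundle.field, ellipsoid_bundle.mesh)
        corners = detect_corners(ellipsoid_bundle.mesh, fit.r_in_max)
        sharpest = min(r.min_radius_mm for r in corners.regions)
        assert sharpest == pytest.approx(5.0, rel=0.15)
        # the sharpest vertices sit near the +/-a tips
        region = min(corners.regions, key=lambda r: r.min_radius_mm)
        verts = ellipsoid_bundle.mesh.vertices
        centered = verts - verts.mean(axis=0)
        along_a = np.abs(centered @ ELLIPSOID_ROTATION[:, 0])
        tip_extent = along_a[region.vertex_indices].max()
        assert tip_extent > 0.85 * 20.0

    def test_corner_radii_bounded_by_inscribed_radius(self, capsule_bundle):
        fit = sphere_fit(capsule_bundle.field, capsule_bundle.mesh)
        corners = detect_corners(capsule_bundle.mesh, fit.r_in_max)
        assert np.all(corners.radii_mm <= fit.r_in_max * 1.1)


class TestRoundness:
    def test_arithmetic(self):
        corners = CornerSet(regions=(
            CornerRegion(np.array([0]), 0.2, 0.2),
            CornerRegion(np.array([1]), 0.4, 0.4)))
        fit = SphereFit(r_in_max=0.3, center_in=np.zeros(3),
                        r_cir_min=0.6, center_cir=np.zeros(3))
        assert roundness(corners, fit) == pytest.approx(0.5, abs=1e-12)
        assert roundness(corners, fit,
                         denominator="inscribed") == pytest.approx(1.0)

    def test_sphere_roundness_is_one(self, sphere_bundle):
        assert sphere_bundle.desc.roundness == pytest.approx(1.0, abs=0.05)

    def test_capsule_roundness_r_over_circumradius(self, capsule_bundle):
        # two cap regions with r_i ~ 5, r_cir = r + L/2 = 15
        assert capsule_bundle.desc.roundness == pytest.approx(1 / 3, abs=0.05)

    def test_empty_corner_set_rejected(self):
        fit = SphereFit(r_in_max=1.0, center_in=np.zeros(3),
                        r_cir_min=2.0, center_cir=np.zeros(3))
        with pytest.raises(ValueError, match="empty"):
            roundness(CornerSet(regions=()), fit)


class TestPrincipalAxes:
    def test_rotated_ellipsoid_extents_and_directions(self, ellipsoid_bundle):
        axes = principal_axes(ellipsoid_bundle.field)
        assert axes.extents_mm == pytest.approx([40, 30, 20], rel=0.02)
        for direction, generator in zip(axes.directions, ELLIPSOID_ROTATION.T):
            angle = np.degrees(np.arccos(min(1.0, abs(direction @ generator))))
            assert angle < 3.0

    def test_sphere_extents_equal(self, sphere_bundle):
        axes = principal_axes(sphere_bundle.field)
        assert axes.extents_mm.max() / axes.extents_mm.min() < 1.03

    def test_axis_aligned_box_extents(self):
        s = 0.5
        mask = np.zeros((96, 56, 36), dtype=bool)
        mask[4:84, 4:44, 4:24] = True  # 40 x 20 x 10 mm box
        from hippomorph.imaging_io import BinaryMask
        field = hm.reinitialize_sdf(BinaryMask(values=mask, spacing=(s, s, s)))
        axes = principal_axes(field)
        assert axes.extents_mm == pytest.approx([40, 20, 10], abs=s)
        assert aspect_ratio(axes) == pytest.approx(0.25, abs=0.02)

    def test_too_few_interior_voxels_rejected(self):
        vals = np.ones((8, 8, 8))
        vals[4, 4, 4] = -0.5
        field = hm.LevelSetField(values=vals, spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="interior voxels"):
            principal_axes(field)


class TestAspectRatio:
    def test_sphere(self, sphere_bundle):
        assert sphere_bundle.desc.aspect_ratio == pytest.approx(1.0, abs=0.03)

    def test_ellipsoid_c_over_a(self, ellipsoid_bundle):
        assert ellipsoid_bundle.desc.aspect_ratio == pytest.approx(0.5,
                                                                   abs=0.02)


class TestDescribe:
    def test_sphere_descriptor_set(self, sphere_bundle):
        d = sphere_bundle.desc
        assert d.volume_cm3 == pytest.approx(3.26, abs=0.1)
        assert d.diameter_cm == pytest.approx(1.84, abs=0.06)
        assert d.sphericity == pytest.approx(1.0, abs=0.05)
        assert d.roundness == pytest.approx(1.0, abs=0.05)
        assert d.aspect_ratio == pytest.approx(1.0, abs=0.05)
        assert d.vs_ratio_cm == pytest.approx(0.92 / 3, rel=0.03)

    def test_ellipsoid_sphericity_equals_aspect_ratio(self, ellipsoid_bundle):
        d = ellipsoid_bundle.desc
        assert d.sphericity == pytest.approx(0.5, abs=0.04)
        assert d.aspect_ratio == pytest.approx(0.5, abs=0.04)

    def test_sphericity_never_exceeds_one(self, sphere_bundle, capsule_bundle,
                                          ellipsoid_bundle):
        for b in (sphere_bundle, capsule_bundle, ellipsoid_bundle):
            assert b.desc.sphericity <= 1.0

    def test_mesh_volume_agrees_with_voxel_count(self, sphere_bundle,
                                                 capsule_bundle):
        for b in (sphere_bundle, capsule_bundle):
            assert b.desc.volume_cm3 == pytest.approx(b.mask.volume_cm3(),
                                                      rel=0.02)

    def test_zero_iteration_and_evolved_descriptors_agree(self, sphere_bundle):
        evolved = hm.evolve_level_set(sphere_bundle.mask, sphere_bundle.grid,
                                      hm.EvolutionParams(iterations=200))
        d0, d1 = sphere_bundle.desc, hm.describe(evolved)
        for attr in ("volume_cm3", "diameter_cm", "sphericity",
                     "aspect_ratio", "vs_ratio_cm"):
            assert getattr(d1, attr) == pytest.approx(getattr(d0, attr),
                                                      rel=0.03)

    def test_scaling_laws(self):
        """Scaling by s multiplies V by s^3, A by s^2, D and V/S by s, and
        leaves the dimensionless descriptors unchanged (within 2 %)."""
        descs = {}
        for s in (0.5, 1.0, 2.0):
            spec = ph.PhantomSpec(family="capsule", radius=5.0 * s,
                                  length=20.0 * s, spacing_mm=0.5 * s)
            _, mask, _ = ph.make_phantom(spec, (76,) * 3, noise_sigma=0)
            descs[s] = hm.describe(hm.reinitialize_sdf(mask))
        for s in (0.5, 2.0):
            rel = descs[s]
            base = descs[1.0]
            assert rel.volume_cm3 / base.volume_cm3 == pytest.approx(s ** 3,
                                                                     rel=0.02)
            assert rel.surface_cm2 / base.surface_cm2 == pytest.approx(s ** 2,
                                                                       rel=0.02)
            assert rel.diameter_cm / base.diameter_cm == pytest.approx(s,
                                                                       rel=0.02)
            assert rel.vs_ratio_cm / base.vs_ratio_cm == pytest.approx(s,
                                                                       rel=0.02)
            for attr in ("sphericity", "roundness", "aspect_ratio"):
                assert getattr(rel, attr) == pytest.approx(
                    getattr(base, attr), rel=0.02)

    def test_descriptor_invariants_enforced(self):
        with pytest.raises(ValueError, match="sphericity"):
            ShapeDescriptors(volume_cm3=1, surface_cm2=5, diameter_cm=2,
                             sphericity=1.2, roundness=0.5, aspect_ratio=0.5,
                             vs_ratio_cm=0.2, sv_ratio_per_cm=5.0)
        with pytest.raises(ValueError, match="reciprocal"):
            ShapeDescriptors(volume_cm3=1, surface_cm2=5, diameter_cm=2,
                             sphericity=0.5, roundness=0.5, aspect_ratio=0.5,
                             vs_ratio_cm=0.2, sv_ratio_per_cm=4.0)
        with pytest.raises(ValueError, match="ball diameter"):
            ShapeDescriptors(volume_cm3=8.0, surface_cm2=5, diameter_cm=1.0,
                             sphericity=0.5, roundness=0.5, aspect_ratio=0.5,
                             vs_ratio_cm=1.6, sv_ratio_per_cm=0.625)
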