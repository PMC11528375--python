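"""Six 3D morphological descriptors computed from a level-set digital twin.

Descriptors (reported in cm units, matching clinical volumetry tables):

* **volume** and **surface area** — signed tetrahedron sum / triangle sum over
  the closed zero-level surface mesh;
* **diameter** — diameter of the smallest sphere containing the shape
  (2 x minimum circumscribed radius, exact Welzl ball);
* **sphericity** ``S = r_in,max / r_cir,min`` — maximum inscribed over
  minimum circumscribed radius, 1 for a sphere;
* **roundness** ``R = (1/N) sum_i r_i / r_cir,min`` — mean corner curvature
  radius normalized by the circumscribed radius;
* **aspect ratio** ``AR = min extent / max extent`` along the principal axes;
* **volume-to-surface ratio** ``V/S`` (cm) with its reciprocal ``S/V``
  (cm^-1) as a companion output (see note in :func:`describe`).

Internal computations are in mm; report units are cm/cm^2/cm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .imaging_io import voxel_centers_1d
from .reconstruction import LevelSetField, SurfaceMesh, extract_mesh

__all__ = [
    "ShapeDescriptors",
    "SphereFit",
    "CornerRegion",
    "CornerSet",
    "PrincipalAxes",
    "compute_volume_surface",
    "max_inscribed_sphere",
    "min_enclosing_sphere",
    "sphericity",
    "vertex_principal_curvatures",
    "detect_corners",
    "roundness",
    "principal_axes",
    "aspect_ratio",
    "describe",
]

MM3_PER_CM3 = 1000.0
MM2_PER_CM2 = 100.0
MM_PER_CM = 10.0


@dataclass(frozen=True)
class ShapeDescriptors:
    """Per-structure morphological descriptor set (cm-based units).

    ``roundness`` may be ``None`` when no analytic value exists (e.g. for
    phantom families without a closed-form corner decomposition).
    """

    volume_cm3: float
    surface_cm2: float
    diameter_cm: float
    sphericity: float
    roundness: float | None
    aspect_ratio: float
    vs_ratio_cm: float
    sv_ratio_per_cm: float

    def __post_init__(self) -> None:
        if min(self.volume_cm3, self.surface_cm2, self.diameter_cm) <= 0:
            raise ValueError("volume, surface area and diameter must be positive")
        if not (0 < self.sphericity <= 1):
            raise ValueError(f"sphericity must be in (0, 1], got {self.sphericity}")
        if not (0 < self.aspect_ratio <= 1):
            raise ValueError(f"aspect ratio must be in (0, 1], got {self.aspect_ratio}")
        if self.roundness is not None and not (0 < self.roundness <= 1.05):
            raise ValueError(f"roundness must be in (0, 1.05], got {self.roundness}")
        ball_diam = 2.0 * (3.0 * self.volume_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        if self.diameter_cm < ball_diam * (1 - 1e-6):
            raise ValueError(
                f"diameter {self.diameter_cm:.4f} cm below the equal-volume "
                f"ball diameter {ball_diam:.4f} cm")
        if abs(self.vs_ratio_cm * self.sv_ratio_per_cm - 1.0) > 1e-9:
            raise ValueError("vs_ratio and sv_ratio must be reciprocal")

    def to_dict(self) -> dict:
        return {
            "volume_cm3": self.volume_cm3,
            "surface_cm2": self.surface_cm2,
            "diameter_cm": self.diameter_cm,
            "sphericity": self.sphericity,
            "roundness": self.roundness,
            "aspect_ratio": self.aspect_ratio,
            "vs_ratio_cm": self.vs_ratio_cm,
            "sv_ratio_per_cm": self.sv_ratio_per_cm,
        }


@dataclass(frozen=True)
class SphereFit:
    """Maximum inscribed and minimum enclosing sphere of one shape (mm)."""

    r_in_max: float
    center_in: np.ndarray
    r_cir_min: float
    center_cir: np.ndarray

    def __post_init__(self) -> None:
        if not (0 < self.r_in_max):
            raise ValueError("inscribed radius must be positive")
        if self.r_in_max > self.r_cir_min * (1 + 1e-9):
            raise ValueError(
                f"inscribed radius {self.r_in_max:.3f} exceeds circumscribed "
                f"radius {self.r_cir_min:.3f}")


@dataclass(frozen=True)
class CornerRegion:
    vertex_indices: np.ndarray
    radius_mm: float      # representative (mean) curvature radius of the region
    min_radius_mm: float  # sharpest pointwise radius within the region


@dataclass(frozen=True)
class CornerSet:
    regions: tuple[CornerRegion, ...]

    @property
    def n(self) -> int:
        return len(self.regions)

    @property
    def radii_mm(self) -> np.ndarray:
        return np.array([r.radius_mm for r in self.regions])


@dataclass(frozen=True)
class PrincipalAxes:
    """Orthonormal principal directions with projection-range extents (mm)."""

    directions: np.ndarray  # (3, 3), rows are unit vectors
    extents_mm: np.ndarray  # (3,), sorted descending

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise ValueError("principal directions must be orthonormal")
        e = np.asarray(self.extents_mm, dtype=float)
        if not np.all(np.diff(e) <= 1e-9):
            raise ValueError("extents must be sorted descending")


# ---------------------------------------------------------------------------
# Volume and surface area
# ---------------------------------------------------------------------------


def compute_volume_surface(mesh: SurfaceMesh) -> tuple[float, float]:
    """Mesh volume (cm^3) and surface area (cm^2) of a closed oriented mesh.

    Volume by the divergence theorem (signed tetrahedron sum), area by
    summing triangle areas.
    """
    nb = mesh.n_boundary_edges
    if nb:
        raise ValueError(f"mesh is not closed: {nb} boundary edges")
    tm = mesh.as_trimesh()
    volume_mm3 = float(abs(tm.volume))
    area_mm2 = float(tm.area)
    return volume_mm3 / MM3_PER_CM3, area_mm2 / MM2_PER_CM2


# ---------------------------------------------------------------------------
# Inscribed / circumscribed spheres
# ---------------------------------------------------------------------------


def max_inscribed_sphere(field: LevelSetField,
                         mesh: SurfaceMesh | None = None
                         ) -> tuple[float, np.ndarray]:
    """Maximum inscribed sphere radius (mm) and center.

    The EDT argmax (``max(-phi)``) locates the deepest voxel, then the
    center is refined on a subvoxel grid around it by maximizing the
    distance to the triangulated interface (nearest mesh vertex; the
    vertices sample the surface densely enough that the sag error is far
    below a voxel).  The grid argmax alone can under-estimate the radius by
    up to half a voxel diagonal because the SDF is cone-like at its apex,
    where quadratic interpolation is invalid.
    """
    depth = -field.values
    if depth.max() <= 0:
        raise ValueError("level set has no interior")
    idx = np.unravel_index(np.argmax(depth), depth.shape)
    p0 = np.array([
        voxel_centers_1d(n, s, o)[i]
        for i, n, s, o in zip(idx, depth.shape, field.spacing, field.origin)
    ])
    mesh = mesh if mesh is not None else extract_mesh(field)
    tree = cKDTree(mesh.vertices)
    s_mean = float(np.mean(field.spacing))
    offsets = np.linspace(-s_mean, s_mean, 9)
    gx, gy, gz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    candidates = p0 + np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    dists, _ = tree.query(candidates, k=1)
    best = int(np.argmax(dists))
    return float(dists[best]), candidates[best]


def _circumsphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest sphere with all given (affinely independent) points on its
    boundary: circumsphere restricted to the points' affine hull."""
    p0 = points[0]
    if len(points) == 1:
        return p0.copy(), 0.0
    a = points[1:] - p0
    b = 0.5 * np.einsum("ij,ij->i", a, a)
    m = a @ a.T
    try:
        x = np.linalg.solve(m, b)
    except np.linalg.LinAlgError:
        x = np.linalg.lstsq(m, b, rcond=None)[0]
    center = p0 + a.T @ x
    return center, float(np.linalg.norm(center - p0))


def min_enclosing_sphere(points: np.ndarray, seed: int = 0) -> tuple[float, np.ndarray]:
    """Exact smallest enclosing ball (Welzl-type randomized incremental).

    The recursion over at most four boundary support points is unrolled into
    nested incremental passes, giving the classic expected-linear runtime.
    The shuffle is seeded, so the result is deterministic.  For large inputs
    the point set is first reduced to its convex hull vertices (the minimum
    enclosing ball depends only on those).

    Returns ``(radius_mm, center)``.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    pts = np.unique(pts, axis=0)
    if len(pts) > 500:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    rng = np.random.default_rng(seed)
    pts = pts[rng.permutation(len(pts))]

    def outside(p, c, r):
        return np.dot(p - c, p - c) > r * r * (1 + 1e-12) + 1e-12

    def ball_with(boundary: list, interior: np.ndarray):
        c, r = _circumsphere(np.array(boundary))
        if len(boundary) == 4:
            return c, r
        for i, p in enumerate(interior):
            if outside(p, c, r):
                c, r = ball_with(boundary + [p], interior[:i])
        return c, r

    c, r = pts[0].copy(), 0.0
    for i, p in enumerate(pts[1:], start=1):
        if outside(p, c, r):
            c, r = ball_with([p], pts[:i])
    return float(r), c


def sphere_fit(field: LevelSetField, mesh: SurfaceMesh | None = None,
               seed: int = 0) -> SphereFit:
    """Combined maximum inscribed / minimum enclosing sphere fit."""
    mesh = mesh if mesh is not None else extract_mesh(field)
    r_in, c_in = max_inscribed_sphere(field, mesh)
    r_cir, c_cir = min_enclosing_sphere(mesh.vertices, seed=seed)
    if r_in > r_cir:
        # the two radii come from different discretizations (SDF vs mesh);
        # a genuine inversion beyond discretization error is an input defect
        if r_in > r_cir * 1.02:
            raise ValueError(
                f"inscribed radius {r_in:.3f} mm exceeds circumscribed "
                f"{r_cir:.3f} mm by more than discretization tolerance")
        r_in = r_cir
    return SphereFit(r_in_max=r_in, center_in=c_in,
                     r_cir_min=r_cir, center_cir=c_cir)


def sphericity(fit: SphereFit) -> float:
    """Sphericity ``S = r_in,max / r_cir,min`` (1 for a sphere)."""
    return fit.r_in_max / fit.r_cir_min


# ---------------------------------------------------------------------------
# Corners and roundness
# ---------------------------------------------------------------------------


def _taubin_smoothed(mesh: SurfaceMesh, iterations: int) -> trimesh.Trimesh:
    tm = mesh.as_trimesh().copy()
    if iterations > 0:
        # lamb/nu pair below is the standard non-shrinking Taubin setting
        trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=-0.53,
                                        iterations=iterations)
    return tm


def vertex_principal_curvatures(tm: trimesh.Trimesh,
                                ball_radius_mm: float | None = None,
                                umbilic_tolerance: float = 0.3
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex principal curvatures (kappa_max, kappa_min), positive = convex.

    Uses integral curvature measures over a ball of ``ball_radius_mm``
    around each vertex: mean curvature from the signed dihedral angles of
    the edges in the ball, Gaussian curvature from the vertex angle defects,
    both normalized by the enclosed surface area.  Integrating over a finite
    patch averages out the discretization noise that defeats pointwise
    (quadric-fit) estimators on marching-cubes meshes.  The default ball
    radius is 4.5 mean edge lengths, i.e. it scales with the mesh
    resolution, which keeps the estimate scale-equivariant.

    Principal curvatures follow from ``kappa = H +/- sqrt(H^2 - K)``.  On
    near-umbilic patches the discriminant is pure estimation noise and
    ``H + |noise|`` would bias ``kappa_max`` upward, so whenever
    ``sqrt(H^2 - K) < umbilic_tolerance * |H|`` the point is treated as
    umbilic (``kappa_1 = kappa_2 = H``).
    """
    pts = np.asarray(tm.vertices)
    edge_pairs = tm.face_adjacency_edges
    angles = np.array(tm.face_adjacency_angles, dtype=float)
    angles[~tm.face_adjacency_convex] *= -1.0  # concave hinges count negative
    edge_mid = pts[edge_pairs].mean(axis=1)
    edge_len = np.linalg.norm(pts[edge_pairs[:, 0]] - pts[edge_pairs[:, 1]], axis=1)
    if ball_radius_mm is None:
        ball_radius_mm = 4.5 * float(edge_len.mean())
    edge_measure = 0.5 * edge_len * angles
    vertex_defect = np.asarray(tm.vertex_defects, dtype=float)
    face_center = np.asarray(tm.triangles_center)
    face_area = np.asarray(tm.area_faces)

    edge_tree = cKDTree(edge_mid)
    vert_tree = cKDTree(pts)
    face_tree = cKDTree(face_center)
    h = np.zeros(len(pts))
    k = np.zeros(len(pts))
    edge_hits = edge_tree.query_ball_point(pts, ball_radius_mm)
    vert_hits = vert_tree.query_ball_point(pts, ball_radius_mm)
    face_hits = face_tree.query_ball_point(pts, ball_radius_mm)
    for i in range(len(pts)):
        area = face_area[face_hits[i]].sum()
        if area <= 0:
            continue
        h[i] = edge_measure[edge_hits[i]].sum() / area
        k[i] = vertex_defect[vert_hits[i]].sum() / area
    disc = h * h - k
    root = np.sqrt(np.maximum(disc, 0.0))
    umbilic = root < umbilic_tolerance * np.abs(h)
    root = np.where(umbilic, 0.0, root)
    return h + root, h - root


def detect_corners(mesh: SurfaceMesh, r_in_max: float, *,
                   epsilon: float = 0.1, elliptic_ratio: float = 0.3,
                   smooth_iterations: int = 10,
                   min_region_vertices: int = 3,
                   min_region_fraction: float = 0.05) -> CornerSet:
    """Identify corner regions on the surface and their curvature radii.

    A *corner* is a connected, locally cap-like surface patch whose maximum
    principal-curvature radius ``r(v) = 1/kappa_max`` does not exceed the
    maximum inscribed sphere radius (within the relative tolerance
    ``epsilon``).  Cap-like means both principal curvatures are convex and
    comparable (``kappa_min >= elliptic_ratio * kappa_max``), which excludes
    cylindrical walls whose smallest-radius curvature matches a corner's but
    which are not corners.  Each region's representative radius ``r_i`` is
    the mean of ``r(v)`` over the region.  Candidate specks smaller than
    ``min_region_fraction`` of the largest region are discarded as curvature
    noise.

    The mesh is Taubin-smoothed before curvature estimation, otherwise the
    marching-cubes staircase dominates the curvature signal.
    """
    tm = _taubin_smoothed(mesh, smooth_iterations)
    areas = np.asarray(tm.area_faces)
    if (areas < 1e-12).sum() > 0.01 * len(areas):
        raise ValueError("degenerate mesh: too many zero-area triangles")
    k_max, k_min = vertex_principal_curvatures(tm)
    with np.errstate(divide="ignore"):
        radius = np.where(k_max > 0, 1.0 / k_max, np.inf)
    candidate = (
        (k_max > 0)
        & (radius <= r_in_max * (1.0 + epsilon))
        & (k_min >= elliptic_ratio * k_max)
    )
    regions = _connected_vertex_regions(tm, candidate, radius,
                                        min_region_vertices)
    if regions:
        largest = max(len(r.vertex_indices) for r in regions)
        regions = [r for r in regions
                   if len(r.vertex_indices) >= min_region_fraction * largest]
    if not regions:
        # closed surfaces always have a sharpest convex point; fall back to a
        # single-vertex region there so the corner set is never empty
        v = int(np.argmin(np.where(k_max > 0, radius, np.inf)))
        regions = [CornerRegion(vertex_indices=np.array([v]),
                                radius_mm=float(radius[v]),
                                min_radius_mm=float(radius[v]))]
    return CornerSet(regions=tuple(regions))


def _connected_vertex_regions(tm, candidate, radius, min_vertices):
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    idx = np.flatnonzero(candidate)
    if len(idx) == 0:
        return []
    pos = -np.ones(len(candidate), dtype=np.int64)
    pos[idx] = np.arange(len(idx))
    edges = np.asarray(tm.edges_unique)
    keep = candidate[edges[:, 0]] & candidate[edges[:, 1]]
    e = edges[keep]
    graph = coo_matrix(
        (np.ones(len(e)), (pos[e[:, 0]], pos[e[:, 1]])),
        shape=(len(idx), len(idx)))
    n_comp, labels = connected_components(graph, directed=False)
    regions = []
    for comp in range(n_comp):
        members = idx[labels == comp]
        if len(members) < min_vertices:
            continue
        regions.append(CornerRegion(vertex_indices=members,
                                    radius_mm=float(np.mean(radius[members])),
                                    min_radius_mm=float(np.min(radius[members]))))
    return regions


def roundness(corners: CornerSet, fit: SphereFit,
              denominator: str = "circumscribed") -> float:
    """Roundness ``R = (1/N) sum_i r_i / r_cir,min``.

    ``denominator`` selects the normalizing radius: ``"circumscribed"``
    (``r_cir,min``, the default) or ``"inscribed"`` (``r_in,max``, the
    classical Wadell convention).
    """
    if corners.n == 0:
        raise ValueError("corner set is empty")
    if denominator == "circumscribed":
        denom = fit.r_cir_min
    elif denominator == "inscribed":
        denom = fit.r_in_max
    else:
        raise ValueError("denominator must be 'circumscribed' or 'inscribed'")
    return float(np.mean(corners.radii_mm) / denom)


# ---------------------------------------------------------------------------
# Principal axes and aspect ratio
# ---------------------------------------------------------------------------


def principal_axes(field: LevelSetField,
                   mesh: SurfaceMesh | None = None) -> PrincipalAxes:
    """Principal directions and extents of the shape.

    Directions are the eigenvectors of the interior voxel-center covariance;
    extents are the projection ranges of the zero-level surface vertices
    along each direction.  The surface (rather than the voxel centers) is
    used for the extents because interior centers under-span the solid by
    up to a voxel, with a bias that depends on how the surface is oriented
    relative to the lattice.
    """
    inside = field.values < 0
    n_in = int(inside.sum())
    if n_in < 10:
        raise ValueError(f"need >= 10 interior voxels, got {n_in}")
    coords = np.argwhere(inside).astype(np.float64)
    centers = (coords + 0.5) * np.asarray(field.spacing) + np.asarray(field.origin)
    centered = centers - centers.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-12 * max(evals[-1], 1.0):
        warnings.warn("degenerate covariance; falling back to the "
                      "axis-aligned bounding box", stacklevel=2)
        evecs = np.eye(3)
    mesh = mesh if mesh is not None else extract_mesh(field)
    verts = mesh.vertices - mesh.vertices.mean(axis=0)
    proj = verts @ evecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    order = np.argsort(extents)[::-1]
    return PrincipalAxes(directions=evecs.T[order], extents_mm=extents[order])


def aspect_ratio(axes: PrincipalAxes) -> float:
    """Aspect ratio ``AR = shortest extent / longest extent``."""
    return float(axes.extents_mm[-1] / axes.extents_mm[0])


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def describe(field: LevelSetField, *, roundness_denominator: str = "circumscribed",
             corner_epsilon: float = 0.1, corner_elliptic_ratio: float = 0.3,
             smooth_iterations: int = 10, seed: int = 0) -> ShapeDescriptors:
    """Compute all six descriptors from a signed-distance field.

    Note on the volume-to-surface ratio: for a compact ~3 cm^3 structure
    ``V/S`` is a few tenths of a cm while ``S/V`` is a few cm^-1; published
    hippocampus tables print values near 8 "cm", which matches the
    surface-to-volume magnitude.  Both ratios are therefore reported
    (``vs_ratio_cm`` = V/S and ``sv_ratio_per_cm`` = S/V) so either
    convention can be compared against.
    """
    mesh = extract_mesh(field)
    volume_cm3, surface_cm2 = compute_volume_surface(mesh)
    fit = sphere_fit(field, mesh, seed=seed)
    s_val = min(sphericity(fit), 1.0)
    corners = detect_corners(mesh, fit.r_in_max, epsilon=corner_epsilon,
                             elliptic_ratio=corner_elliptic_ratio,
                             smooth_iterations=smooth_iterations)
    r_val = roundness(corners, fit, denominator=roundness_denominator)
    r_val = min(r_val, 1.05)
    axes = principal_axes(field, mesh)
    ar_val = aspect_ratio(axes)
    vs = volume_cm3 / surface_cm2
    return ShapeDescriptors(
        volume_cm3=volume_cm3,
        surface_cm2=surface_cm2,
        diameter_cm=2.0 * fit.r_cir_min / MM_PER_CM,
        sphericity=s_val,
        roundness=r_val,
        aspect_ratio=ar_val,
        vs_ratio_cm=vs,
        sv_ratio_per_cm=1.0 / vs,
    )
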