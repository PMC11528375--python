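"""Level-set reconstruction of a segmented structure from MRI + mask.

Implements the imaging pipeline that turns a manually traced binary mask and
its MRI into a signed-distance "digital twin":

1. watershed labeling of the binarized traces (splits touching blobs),
2. non-local-means denoising of the intensity image,
3. distance-regularized level-set evolution against an edge-stopping map
   ``g = 1 / (1 + |grad(G_sigma * I)|^2)``,
4. signed-distance reinitialization and marching-cubes surface extraction.

The whole module is deterministic for fixed inputs.

Level-set convention: ``phi`` is in mm, negative inside the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure, morphology, restoration, segmentation

from .imaging_io import BinaryMask, VoxelGrid

__all__ = [
    "LevelSetField",
    "EvolutionParams",
    "label_components",
    "nlm_denoise",
    "estimate_noise_sigma",
    "evolve_level_set",
    "reinitialize_sdf",
    "extract_mesh",
    "SurfaceMesh",
]


@dataclass(frozen=True)
class LevelSetField:
    """Signed-distance representation of one structure (negative inside)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = "init-from-mask"  # or "evolved"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if values.ndim != 3:
            raise ValueError("phi must be a 3D array")
        if not ((values < 0).any() and (values > 0).any()):
            raise ValueError("phi must contain both phases (inside and outside)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def interior_mask(self) -> BinaryMask:
        """Zero-sublevel set as a binary mask."""
        return BinaryMask(values=self.values < 0, spacing=self.spacing,
                          origin=self.origin)

    def gradient_norm(self, scheme: str = "upwind") -> np.ndarray:
        """|grad phi| per voxel.

        ``"upwind"`` (default) uses the Godunov scheme from eikonal solvers:
        one-sided differences selected by the sign of ``phi``, which is exact
        to O(h) on a signed distance field and does not smear the interface
        kink the way central differences do.  ``"central"`` uses
        ``np.gradient``.
        """
        if scheme == "central":
            grads = np.gradient(self.values, *self.spacing)
            return np.sqrt(sum(g * g for g in grads))
        if scheme == "smoothed":
            sm = ndimage.gaussian_filter(self.values, 0.6)
            grads = np.gradient(sm, *self.spacing)
            return np.sqrt(sum(g * g for g in grads))
        if scheme != "upwind":
            raise ValueError("scheme must be 'upwind', 'central' or 'smoothed'")
        phi = self.values
        g2 = np.zeros_like(phi)
        pos = phi > 0
        for ax, s in enumerate(self.spacing):
            dm = (phi - np.roll(phi, 1, axis=ax)) / s
            dp = (np.roll(phi, -1, axis=ax) - phi) / s
            # one-sided values at the array border are invalid; duplicate
            # the interior-facing difference there
            sl_lo = [slice(None)] * 3; sl_lo[ax] = 0
            sl_hi = [slice(None)] * 3; sl_hi[ax] = -1
            dm[tuple(sl_lo)] = dp[tuple(sl_lo)]
            dp[tuple(sl_hi)] = dm[tuple(sl_hi)]
            up = np.where(pos,
                          np.maximum(np.maximum(dm, 0.0) ** 2,
                                     np.minimum(dp, 0.0) ** 2),
                          np.maximum(np.minimum(dm, 0.0) ** 2,
                                     np.maximum(dp, 0.0) ** 2))
            g2 += up
        return np.sqrt(g2)

    def sdf_band_fraction(self, band_mm: float = 3.0,
                          bounds: tuple[float, float] = (0.8, 1.2)) -> float:
        """Fraction of near-interface voxels with a distance-like gradient.

        Checks ``|grad phi|`` (on the lightly smoothed field, which
        regularizes the O(h) kinks exact voxel EDTs carry at the interface)
        against ``bounds`` over the band ``|phi| <= band_mm``.  A proper
        signed distance field scores ~1; a scaled or binary field does not.
        """
        gn = self.gradient_norm("smoothed")
        band = np.abs(self.values) <= band_mm
        if not band.any():
            raise ValueError("no voxels inside the requested band")
        inside = (gn[band] >= bounds[0]) & (gn[band] <= bounds[1])
        return float(inside.mean())


@dataclass(frozen=True)
class EvolutionParams:
    """Parameters of the distance-regularized level-set evolution.

    The time step must satisfy the stability bound
    ``time_step * regularization_weight < 0.25`` (forward-Euler bound for the
    distance-regularization diffusion term, voxel units).
    """

    sigma_mm: float = 0.5           # Gaussian scale of the edge map (mm)
    gradient_scale: float | None = None  # edge-map K; None = auto (see edge_indicator)
    regularization_weight: float = 0.2   # mu: distance-regularization term
    length_weight: float = 5.0      # lambda: edge-weighted curvature term
    area_weight: float = -1.5       # alpha: balloon term (<0 expands)
    # strong two-level edges make the advective edge term the binding CFL
    # constraint, not the diffusion bound; 0.1 keeps |update| well below a
    # voxel per step at lambda = 5
    time_step: float = 0.1
    iterations: int = 250
    narrow_band_mm: float = 5.0
    delta_epsilon: float = 1.5      # width of the smoothed Dirac (voxels)

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iteration count must be >= 0")
        if self.time_step * self.regularization_weight >= 0.25:
            raise ValueError(
                "stability bound violated: time_step * regularization_weight "
                f"= {self.time_step * self.regularization_weight:.3f} >= 0.25")
        if self.sigma_mm <= 0 or self.narrow_band_mm <= 0:
            raise ValueError("sigma_mm and narrow_band_mm must be positive")


# ---------------------------------------------------------------------------
# Watershed labeling
# ---------------------------------------------------------------------------


def label_components(mask: BinaryMask, h_maxima_voxels: float = 1.0):
    """Watershed-label a binary mask, splitting touching blobs.

    The watershed runs on the negated internal Euclidean distance transform,
    seeded at distance maxima after h-maxima suppression (``h`` in voxels)
    to avoid over-segmentation.

    Returns
    -------
    labels : ndarray of int
        0 outside the mask, positive component labels inside.
    n_components : int
    candidate_label : int
        Label of the largest component (the structure candidate).
    """
    if mask.n_true == 0:
        raise ValueError("cannot label an empty mask")
    dist = ndimage.distance_transform_edt(mask.values, sampling=mask.spacing)
    h = h_maxima_voxels * min(mask.spacing)
    peaks = morphology.h_maxima(dist, h)
    markers, _ = ndimage.label(peaks)
    labels = segmentation.watershed(-dist, markers=markers, mask=mask.values)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    candidate = int(ids[np.argmax(counts)])
    return labels, int(len(ids)), candidate


# ---------------------------------------------------------------------------
# Non-local means denoising
# ---------------------------------------------------------------------------


def estimate_noise_sigma(image: np.ndarray) -> float:
    """Robust Gaussian-noise estimate: MAD of the discrete Laplacian.

    For i.i.d. noise the 6-connected 3D Laplacian response has variance
    ``42 * sigma^2`` (kernel weights ``(-6, 1 x 6)``), so
    ``sigma = 1.4826 * MAD(lap) / sqrt(42)``.  Structure edges contribute only
    to the tails, which the median absolute deviation ignores.
    """
    lap = ndimage.laplace(np.asarray(image, dtype=np.float64))
    mad = np.median(np.abs(lap - np.median(lap)))
    return float(1.4826 * mad / np.sqrt(42.0))


def nlm_denoise(image: VoxelGrid, patch_radius: int = 1, search_radius: int = 3,
                strength: float | None = None) -> VoxelGrid:
    """Non-local-means denoising with patch-mean weighting.

    ``strength`` is the NLM ``h`` parameter (same units as the intensities);
    when omitted it defaults to ``0.8 * sigma_hat`` with ``sigma_hat`` from
    :func:`estimate_noise_sigma`.  A constant image is a fixed point.
    """
    if patch_radius < 1 or search_radius < 1:
        raise ValueError("patch and search radii must be >= 1 voxel")
    sigma_hat = estimate_noise_sigma(image.values)
    if strength is None:
        strength = 0.8 * sigma_hat
    if strength == 0.0:  # noiseless image: nothing to average away
        return image.with_values(image.values.copy())
    den = restoration.denoise_nl_means(
        image.values.astype(np.float64),
        patch_size=2 * patch_radius + 1,
        patch_distance=search_radius,
        h=strength,
        sigma=sigma_hat,
        fast_mode=True,
        preserve_range=True,
    )
    return image.with_values(den)


# ---------------------------------------------------------------------------
# Signed distance reinitialization
# ---------------------------------------------------------------------------


def reinitialize_sdf(source: BinaryMask | LevelSetField) -> LevelSetField:
    """Signed Euclidean distance to the interface, negative inside.

    Uses the exact Euclidean distance transform on both phases with a
    half-voxel interface offset: a voxel center adjacent to the interface is
    half a voxel away from it, not a full voxel.  ``phi < 0`` exactly on
    mask-true voxels, and reinitialization is idempotent.
    """
    if isinstance(source, LevelSetField):
        inside = source.values < 0
        spacing, origin = source.spacing, source.origin
        provenance = source.provenance
    else:
        inside = np.asarray(source.values, dtype=bool)
        spacing, origin = source.spacing, source.origin
        provenance = "init-from-mask"
    if not inside.any() or inside.all():
        raise ValueError("both phases must be present to reinitialize")
    d_in = ndimage.distance_transform_edt(inside, sampling=spacing)
    d_out = ndimage.distance_transform_edt(~inside, sampling=spacing)
    half = 0.5 * float(np.mean(spacing))
    phi = np.where(inside, -(d_in - half), d_out - half)
    return LevelSetField(values=phi, spacing=spacing, origin=origin,
                         provenance=provenance)


# ---------------------------------------------------------------------------
# Distance-regularized level-set evolution
# ---------------------------------------------------------------------------


def _delta(phi: np.ndarray, eps: float) -> np.ndarray:
    """Smoothed Dirac delta with compact support ``|phi| <= eps``."""
    d = np.zeros_like(phi)
    band = np.abs(phi) <= eps
    d[band] = (1.0 / (2.0 * eps)) * (1.0 + np.cos(np.pi * phi[band] / eps))
    return d


def _div(fx: np.ndarray, fy: np.ndarray, fz: np.ndarray) -> np.ndarray:
    return np.gradient(fx, axis=0) + np.gradient(fy, axis=1) + np.gradient(fz, axis=2)


def _dist_reg_p2(phi: np.ndarray) -> np.ndarray:
    """Double-well distance-regularization term div(d_p(|grad phi|) grad phi).

    The double-well potential drives ``|grad phi|`` toward 1 near the
    interface and toward 0 far away, keeping the field well conditioned
    without explicit re-distancing during the evolution.
    """
    gx, gy, gz = np.gradient(phi)
    s = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
    a = (s >= 0) & (s <= 1)
    b = s > 1
    ps = a * np.sin(2 * np.pi * s) / (2 * np.pi) + b * (s - 1)
    dps = np.where(ps != 0, ps, 1.0) / np.where(s != 0, s, 1.0)
    return _div((dps - 1.0) * gx, (dps - 1.0) * gy, (dps - 1.0) * gz) + ndimage.laplace(phi)


def edge_indicator(image: VoxelGrid, sigma_mm: float,
                   gradient_scale: float | None = None) -> np.ndarray:
    """Edge-stopping map ``g = 1 / (1 + (|grad(G_sigma * I)| / K)^2)``.

    The gradient is taken per voxel on the Gaussian-smoothed image; ``g``
    approaches 0 at strong intensity edges and 1 in flat regions.  ``K``
    (``gradient_scale``) makes the map insensitive to the arbitrary
    intensity units of the image; by default it is a tenth of the
    99.5th-percentile gradient magnitude, so the strongest edges map to
    ``g ~ 0.01`` while the stopping valley stays only as wide as the edge
    itself.  Without the scaling, high-contrast images produce a near-zero
    ``g`` plateau several voxels wide that stalls the front well before the
    edge.
    """
    sigma_vox = [sigma_mm / s for s in image.spacing]
    smoothed = ndimage.gaussian_filter(image.values.astype(np.float64), sigma_vox)
    gx, gy, gz = np.gradient(smoothed)
    gm = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
    if gradient_scale is None:
        gradient_scale = 0.1 * float(np.percentile(gm, 99.5))
        if gradient_scale <= 0:
            gradient_scale = 1.0
    return 1.0 / (1.0 + (gm / gradient_scale) ** 2)


def evolve_level_set(init: BinaryMask, image: VoxelGrid,
                     params: EvolutionParams | None = None) -> LevelSetField:
    """Distance-regularized level-set evolution of ``init`` against ``image``.

    The initial front is the signed distance of the mask; the evolution
    combines a distance-regularization term (weight
    ``regularization_weight``), an edge-weighted curvature/length term
    (``length_weight``) and a balloon/area term (``area_weight``, negative
    values expand the front).  Updates are restricted to the narrow band
    ``|phi| <= narrow_band_mm`` around the initial interface.

    With ``iterations == 0`` the reinitialized signed distance of ``init`` is
    returned unchanged.  After a nonzero evolution the zero-sublevel set is
    re-quantized to the voxel lattice and reinitialized so the output is an
    exact signed distance field.
    """
    params = params or EvolutionParams()
    if init.n_true == 0:
        raise ValueError("initial mask is empty")
    if init.shape != image.shape:
        raise ValueError(
            f"mask shape {init.shape} does not match image shape {image.shape}")
    sdf0 = reinitialize_sdf(init)
    if params.iterations == 0:
        return sdf0

    h = float(np.mean(init.spacing))  # evolve in voxel units
    phi = sdf0.values / h
    band = np.abs(sdf0.values) <= params.narrow_band_mm
    g = edge_indicator(image, params.sigma_mm, params.gradient_scale)
    ggx, ggy, ggz = np.gradient(g)
    mu, lam, alpha = (params.regularization_weight, params.length_weight,
                      params.area_weight)
    dt, eps = params.time_step, params.delta_epsilon
    tiny = 1e-10
    for _ in range(params.iterations):
        gx, gy, gz = np.gradient(phi)
        mag = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2) + tiny
        nx, ny, nz = gx / mag, gy / mag, gz / mag
        curvature = _div(nx, ny, nz)
        dirac = _delta(phi, eps)
        edge_term = dirac * (ggx * nx + ggy * ny + ggz * nz) + dirac * g * curvature
        area_term = dirac * g
        update = dt * (mu * _dist_reg_p2(phi) + lam * edge_term + alpha * area_term)
        phi = phi + np.where(band, update, 0.0)
    inside = phi < 0
    if not inside.any() or inside.all():
        raise RuntimeError(
            "level-set evolution collapsed to a single phase; the front left "
            "the image (check time_step * regularization_weight < 0.25 and "
            "the sign/magnitude of area_weight)")
    mask = BinaryMask(values=inside, spacing=init.spacing, origin=init.origin,
                      side=init.side, rater=init.rater)
    out = reinitialize_sdf(mask)
    return replace(out, provenance="evolved")


# ---------------------------------------------------------------------------
# Surface extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceMesh:
    """Closed triangulated zero-level surface in physical (mm) coordinates."""

    vertices: np.ndarray   # (n, 3) mm
    triangles: np.ndarray  # (m, 3) vertex indices
    normals: np.ndarray    # (n, 3) per-vertex outward normals

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.triangles,
                               process=False)

    @property
    def n_boundary_edges(self) -> int:
        tm = self.as_trimesh()
        edges = tm.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int((counts != 2).sum())

    @property
    def is_closed(self) -> bool:
        return self.n_boundary_edges == 0

    @property
    def euler_characteristic(self) -> int:
        tm = self.as_trimesh()
        return int(tm.euler_number)


def extract_mesh(field: LevelSetField,
                 presmooth_sigma_vox: float = 0.6,
                 volume_calibrate: bool = True) -> SurfaceMesh:
    """Marching-cubes surface of the zero level set, in mm coordinates.

    Vertices are linearly interpolated along grid edges, offset by half a
    voxel so they live in the same physical frame as voxel centers, and the
    triangle orientation is fixed so the enclosed signed volume is positive.

    ``presmooth_sigma_vox`` Gaussian-smooths ``phi`` (in voxels) before
    contouring: exact-EDT fields are cone-like with lattice quantization
    that otherwise inflates the triangulated area by several percent; on
    already-smooth fields the effect is negligible.  Because smoothing a
    distance field contracts convex interfaces slightly (a mean-curvature
    flow step), ``volume_calibrate`` bisects the extracted iso-level so the
    mesh volume matches the voxel-count volume of the zero-sublevel set,
    which is the unbiased volume estimate the grid provides.  Set
    ``presmooth_sigma_vox=0`` to contour the raw field.
    """
    phi = field.values
    if not ((phi < 0).any() and (phi > 0).any()):
        raise ValueError("level set has no zero crossing to mesh")
    phi_s = phi
    if presmooth_sigma_vox > 0:
        phi_s = ndimage.gaussian_filter(phi, presmooth_sigma_vox)
        if not ((phi_s < 0).any() and (phi_s > 0).any()):
            phi_s = phi  # structure thinner than the smoothing scale

    def _mesh_at(level: float) -> trimesh.Trimesh:
        verts, faces, _, _ = measure.marching_cubes(phi_s, level=level,
                                                    spacing=field.spacing)
        # voxel (i,j,k) center sits at origin + (i+0.5)*spacing
        verts = verts + np.asarray(field.origin) + 0.5 * np.asarray(field.spacing)
        tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        if tm.volume < 0:
            tm.invert()
        return tm

    tm = _mesh_at(0.0)
    if volume_calibrate and presmooth_sigma_vox > 0:
        target = float((phi < 0).sum()) * float(np.prod(field.spacing))
        step = float(min(field.spacing))
        lo, hi = -step, step
        f_lo = abs(_mesh_at(lo).volume) - target if (phi_s < lo).any() else -target
        f_hi = abs(_mesh_at(hi).volume) - target
        if f_lo < 0 < f_hi:
            for _ in range(20):
                mid = 0.5 * (lo + hi)
                tm_mid = _mesh_at(mid)
                err = abs(tm_mid.volume) - target
                if abs(err) <= 1e-3 * target:
                    tm = tm_mid
                    break
                if err < 0:
                    lo = mid
                else:
                    hi = mid
            else:
                tm = tm_mid
    return SurfaceMesh(vertices=np.asarray(tm.vertices, dtype=np.float64),
                       triangles=np.asarray(tm.faces, dtype=np.int64),
                       normals=np.asarray(tm.vertex_normals, dtype=np.float64))


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a surface mesh (format from the file suffix, e.g. .ply/.stl)."""
    mesh.as_trimesh().export(str(path))
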