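"""Synthetic phantoms and simulated cohorts with known ground truth.

Two generators make the whole pipeline testable without patient MRIs:

* :func:`make_phantom` voxelizes analytic solids (sphere, ellipsoid,
  capsule, bent tube) into a two-level intensity image plus a binary mask,
  carrying closed-form descriptor values where they exist;
* :func:`simulate_cohort` draws per-patient/per-hemisphere/per-rater
  descriptor tables with the statistical structure of a manual-volumetry
  study: an inverted-U (quadratic) volume-age law, sex and hemisphere
  offsets, and a linear second-rater calibration.

The bent tube mimics the hippocampus' seahorse-like curved elongated shape;
it carries no analytic descriptor truth and is intended for pipeline smoke
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.spatial import cKDTree
from scipy.special import ellipeinc, ellipkinc

from .imaging_io import BinaryMask, VoxelGrid, voxel_centers_1d
from .morphometry import ShapeDescriptors

__all__ = [
    "PhantomSpec",
    "CohortSimParams",
    "make_phantom",
    "simulate_cohort",
    "ellipsoid_surface_area",
    "COHORT_COLUMNS",
]

FAMILIES = ("sphere", "ellipsoid", "capsule", "bent_tube")


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic solid to voxelize.

    Lengths in mm.  ``rotation`` (3x3, proper orthogonal) and
    ``translation_mm`` (relative to the grid center) give the rigid pose.

    Family parameters: sphere -> ``radius``; ellipsoid -> ``semi_axes``
    (a >= b >= c); capsule -> ``radius`` (cap) + ``length`` (cylinder);
    bent_tube -> ``control_points`` (centerline, local mm) + ``radius``.
    """

    family: str
    radius: float | None = None
    semi_axes: tuple[float, float, float] | None = None
    length: float | None = None
    control_points: np.ndarray | None = None
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing_mm: float = 0.5
    analytic_truth: ShapeDescriptors | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown phantom family {self.family!r}")
        rot = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", rot)
        if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthogonal matrix")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.family == "sphere":
            if self.radius is None or self.radius <= 0:
                raise ValueError("sphere needs a positive radius")
        elif self.family == "ellipsoid":
            if self.semi_axes is None or len(self.semi_axes) != 3:
                raise ValueError("ellipsoid needs three semi-axes")
            a, b, c = self.semi_axes
            if not (a >= b >= c > 0):
                raise ValueError("semi-axes must satisfy a >= b >= c > 0")
        elif self.family == "capsule":
            if self.radius is None or self.radius <= 0 or self.length is None \
                    or self.length <= 0:
                raise ValueError("capsule needs positive cap radius and length")
        elif self.family == "bent_tube":
            if self.radius is None or self.radius <= 0:
                raise ValueError("bent tube needs a positive tube radius")
            cp = np.asarray(self.control_points, dtype=float)
            object.__setattr__(self, "control_points", cp)
            if cp.ndim != 2 or cp.shape[1] != 3 or len(cp) < 3:
                raise ValueError("bent tube needs >= 3 centerline control points")


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Exact surface area of an ellipsoid with semi-axes a >= b >= c (mm^2),
    via incomplete elliptic integrals (spheroid closed forms when two axes
    coincide)."""
    if np.isclose(a, b) and np.isclose(b, c):
        return 4.0 * np.pi * a * a
    if np.isclose(a, b):  # oblate (a = b > c)
        e = np.sqrt(1 - (c / a) ** 2)
        return 2 * np.pi * a * a * (1 + (1 - e * e) / e * np.arctanh(e))
    if np.isclose(b, c):  # prolate (a > b = c)
        e = np.sqrt(1 - (b / a) ** 2)
        return 2 * np.pi * b * b * (1 + a / (b * e) * np.arcsin(e))
    phi = np.arccos(c / a)
    m = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    sin_phi = np.sin(phi)
    return float(2 * np.pi * c * c + (2 * np.pi * a * b / sin_phi)
                 * (ellipeinc(phi, m) * sin_phi ** 2
                    + ellipkinc(phi, m) * np.cos(phi) ** 2))


def _analytic_truth(spec: PhantomSpec) -> ShapeDescriptors | None:
    """Closed-form descriptor values; None for the bent tube."""
    if spec.family == "sphere":
        r = spec.radius
        vol = 4.0 / 3.0 * np.pi * r ** 3
        sur = 4.0 * np.pi * r ** 2
        r_in = r_cir = r
        round_ = 1.0
        ar = 1.0
    elif spec.family == "ellipsoid":
        a, b, c = spec.semi_axes
        vol = 4.0 / 3.0 * np.pi * a * b * c
        sur = ellipsoid_surface_area(a, b, c)
        r_in, r_cir = c, a
        round_ = None  # no closed-form corner decomposition
        ar = c / a
    elif spec.family == "capsule":
        r, length = spec.radius, spec.length
        vol = np.pi * r * r * length + 4.0 / 3.0 * np.pi * r ** 3
        sur = 2.0 * np.pi * r * length + 4.0 * np.pi * r ** 2
        r_in = r
        r_cir = r + length / 2.0
        round_ = r / r_cir  # two hemispherical caps of radius r
        ar = 2.0 * r / (length + 2.0 * r)
    else:
        return None
    vs = (vol / 1000.0) / (sur / 100.0)
    return ShapeDescriptors(
        volume_cm3=vol / 1000.0,
        surface_cm2=sur / 100.0,
        diameter_cm=2.0 * r_cir / 10.0,
        sphericity=r_in / r_cir,
        roundness=round_,
        aspect_ratio=ar,
        vs_ratio_cm=vs,
        sv_ratio_per_cm=1.0 / vs,
    )


def _world_half_extents(spec: PhantomSpec) -> np.ndarray:
    """Half-extent of the solid along each world axis (mm, about its center)."""
    rot = spec.rotation
    if spec.family == "sphere":
        return np.full(3, spec.radius)
    if spec.family == "ellipsoid":
        # support of a rotated ellipsoid along axis i is ||row_i(R diag(axes))||
        scaled = rot @ np.diag(spec.semi_axes)
        return np.linalg.norm(scaled, axis=1)
    if spec.family == "capsule":
        axis = rot[:, 0]
        return np.abs(axis) * spec.length / 2.0 + spec.radius
    cp_world = spec.control_points @ rot.T
    return np.abs(cp_world).max(axis=0) + spec.radius


def _inside_solid(spec: PhantomSpec, pts_local: np.ndarray) -> np.ndarray:
    """Inside test in the solid's local frame (points (n, 3) mm)."""
    if spec.family == "sphere":
        return np.einsum("ij,ij->i", pts_local, pts_local) <= spec.radius ** 2
    if spec.family == "ellipsoid":
        scaled = pts_local / np.asarray(spec.semi_axes)
        return np.einsum("ij,ij->i", scaled, scaled) <= 1.0
    if spec.family == "capsule":
        half = spec.length / 2.0
        x = np.clip(pts_local[:, 0], -half, half)
        d2 = (pts_local[:, 0] - x) ** 2 + pts_local[:, 1] ** 2 + pts_local[:, 2] ** 2
        return d2 <= spec.radius ** 2
    # bent tube: distance to a densely sampled spline through the control pts
    cp = spec.control_points
    tck, _ = interpolate.splprep(cp.T, s=0, k=min(3, len(cp) - 1))
    u = np.linspace(0, 1, 512)
    centerline = np.column_stack(interpolate.splev(u, tck))
    tree = cKDTree(centerline)
    d, _ = tree.query(pts_local, k=1)
    return d <= spec.radius


def make_phantom(spec: PhantomSpec, grid_shape: tuple[int, int, int],
                 *, inside_intensity: float = 100.0,
                 outside_intensity: float = 20.0,
                 noise_sigma: float = 5.0,
                 seed: int = 0) -> tuple[VoxelGrid, BinaryMask, PhantomSpec]:
    """Voxelize an analytic solid into an intensity image and binary mask.

    A mask voxel is true iff its *center* lies inside the solid (no partial
    volume).  The image is two-level (inside high, outside low) with optional
    additive Gaussian noise.  The returned spec carries the analytic
    descriptor truth for sphere/ellipsoid/capsule.

    Raises when the posed solid does not fit the grid with a 2-voxel margin,
    naming the overflowing axis.
    """
    s = spec.spacing_mm
    shape = tuple(int(n) for n in grid_shape)
    extent = np.asarray(shape) * s
    center = extent / 2.0 + np.asarray(spec.translation_mm)
    half = _world_half_extents(spec)
    margin = 2.0 * s
    for ax in range(3):
        if center[ax] - half[ax] < margin or center[ax] + half[ax] > extent[ax] - margin:
            raise ValueError(
                f"phantom exceeds grid along axis {ax}: needs "
                f"[{center[ax] - half[ax]:.1f}, {center[ax] + half[ax]:.1f}] mm "
                f"within [{margin:.1f}, {extent[ax] - margin:.1f}] mm")
    axes_centers = [voxel_centers_1d(n, s) for n in shape]
    xx, yy, zz = np.meshgrid(*axes_centers, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]) - center
    pts_local = pts @ spec.rotation  # R^T . (p - c)
    inside = _inside_solid(spec, pts_local).reshape(shape)
    values = np.where(inside, inside_intensity, outside_intensity).astype(np.float64)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=shape)
    grid = VoxelGrid(values=values, spacing=(s, s, s))
    mask = BinaryMask(values=inside, spacing=(s, s, s))
    return grid, mask, replace(spec, analytic_truth=_analytic_truth(spec))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["patient_id", "age", "sex", "hemisphere", "rater",
                  "volume_cm3", "aspect_ratio", "diameter_cm", "roundness",
                  "sphericity", "vs_ratio"]

_DESCRIPTOR_MEANS = {"aspect_ratio": 0.28, "diameter_cm": 4.03,
                     "roundness": 0.75, "sphericity": 0.12, "vs_ratio": 7.93}
_DESCRIPTOR_SDS = {"aspect_ratio": 0.04, "diameter_cm": 0.25,
                   "roundness": 0.05, "sphericity": 0.03, "vs_ratio": 1.0}
# second-rater mean shifts per descriptor (rater 2 minus rater 1)
_RATER2_OFFSETS = {"aspect_ratio": 0.02, "diameter_cm": -0.13,
                   "roundness": -0.04, "sphericity": 0.02, "vs_ratio": 0.67}
# descriptor response to volume (units per cm^3); smaller volumes go with
# smaller diameter and V/S and higher roundness, mirroring the reported
# shrinkage pattern
_VOLUME_SLOPES = {"aspect_ratio": 0.0, "diameter_cm": 0.2, "roundness": -0.05,
                  "sphericity": 0.0, "vs_ratio": 0.5}


@dataclass(frozen=True)
class CohortSimParams:
    """Generative parameters of a simulated manual-volumetry cohort.

    The rater-1 volume law is a quadratic (inverted U) in age passing through
    the peak ``(peak_age, peak_volume)`` and the late-life anchor
    ``(end_age, end_volume)``, plus additive sex and hemisphere offsets and
    Gaussian residual noise; volumes are floored at ``volume_floor``.  The
    offsets are *centered* (``sex_offset * (male - male_fraction)``,
    ``hemisphere_offset * (right - 1/2)``) so the quadratic is the
    population mean curve of the pooled scatter, not a baseline-subgroup
    curve; group-mean differences still equal the configured offsets.
    Rater 2 applies a linear calibration ``slope * v1 + intercept`` plus
    calibration noise whose spread is derived from a target regression R^2
    (see :meth:`rater2_noise_sd_value`).
    """

    n_patients: int = 63
    age_range: tuple[float, float] = (18.0, 95.0)
    peak_age: float = 55.0
    peak_volume: float = 3.7        # cm^3
    end_age: float = 90.0
    end_volume: float = 1.7         # cm^3
    sex_offset: float = 0.125       # male - female, cm^3
    hemisphere_offset: float = 0.325  # right - left, cm^3
    male_fraction: float = 26.0 / 63.0
    volume_sd: float = 0.5          # residual spread of rater-1 volume, cm^3
    volume_floor: float = 0.5       # cm^3
    rater2_slope: float = 0.981
    rater2_intercept: float = 0.156  # cm^3
    rater2_r2: float = 0.93         # target R^2 of the rater calibration
    rater2_noise_sd: float | None = None  # override; derived from R^2 if None
    descriptor_means: dict = field(default_factory=lambda: dict(_DESCRIPTOR_MEANS))
    descriptor_sds: dict = field(default_factory=lambda: dict(_DESCRIPTOR_SDS))
    rater2_offsets: dict = field(default_factory=lambda: dict(_RATER2_OFFSETS))
    volume_slopes: dict = field(default_factory=lambda: dict(_VOLUME_SLOPES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        lo, hi = self.age_range
        if not (lo < hi):
            raise ValueError("age range must be increasing")
        if not (lo <= self.peak_age <= hi):
            raise ValueError("peak age must lie within the age range")
        if self.volume_sd < 0 or (self.rater2_noise_sd is not None
                                  and self.rater2_noise_sd < 0):
            raise ValueError("spreads must be >= 0")
        if not (0 < self.rater2_r2 <= 1):
            raise ValueError("target R^2 must be in (0, 1]")
        if not (0 <= self.male_fraction <= 1):
            raise ValueError("male fraction must be in [0, 1]")

    @property
    def quad_coefficient(self) -> float:
        """Curvature k of v(age) = peak_volume + k (age - peak_age)^2."""
        return (self.end_volume - self.peak_volume) / (self.end_age - self.peak_age) ** 2

    def volume_age_law(self, age: np.ndarray) -> np.ndarray:
        return self.peak_volume + self.quad_coefficient * (np.asarray(age) - self.peak_age) ** 2

    def rater1_volume_sd(self) -> float:
        """Analytic marginal SD of rater-1 volumes under uniform ages.

        Sums the variance of the quadratic age term (from the uniform
        central moments), the Bernoulli sex and hemisphere offset terms, and
        the residual spread.  Used to construct the rater-2 calibration
        noise; volume-floor truncation is ignored (it is rare at the
        defaults).
        """
        lo, hi = self.age_range
        c = self.peak_age

        def moment(n: int) -> float:
            return ((hi - c) ** (n + 1) - (lo - c) ** (n + 1)) / ((n + 1) * (hi - lo))

        var_quad = self.quad_coefficient ** 2 * (moment(4) - moment(2) ** 2)
        p = self.male_fraction
        var = (var_quad + p * (1 - p) * self.sex_offset ** 2
               + 0.25 * self.hemisphere_offset ** 2 + self.volume_sd ** 2)
        return float(np.sqrt(var))

    def rater2_noise_sd_value(self) -> float:
        """Calibration-noise spread hitting the target regression R^2.

        For y = slope*x + noise, R^2 = slope^2 Var(x) / (slope^2 Var(x) +
        sd^2), so sd = |slope| * SD(x) * sqrt(1/R^2 - 1) with SD(x) the
        analytic rater-1 spread.
        """
        if self.rater2_noise_sd is not None:
            return float(self.rater2_noise_sd)
        return float(abs(self.rater2_slope) * self.rater1_volume_sd()
                     * np.sqrt(1.0 / self.rater2_r2 - 1.0))


def simulate_cohort(params: CohortSimParams | None = None) -> pd.DataFrame:
    """Simulate a per-patient/hemisphere/rater descriptor table.

    Returns a tidy DataFrame with one row per patient x hemisphere x rater
    (``n_patients * 2 * 2`` rows) and columns :data:`COHORT_COLUMNS`.
    Reproducible given ``params.seed``.
    """
    params = params or CohortSimParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    lo, hi = params.age_range
    ages = rng.uniform(lo, hi, size=n)
    sexes = np.where(rng.random(n) < params.male_fraction, "M", "F")

    rows = []
    noise_sd2 = params.rater2_noise_sd_value()
    for i in range(n):
        male = 1.0 if sexes[i] == "M" else 0.0
        base = (float(params.volume_age_law(ages[i]))
                + params.sex_offset * (male - params.male_fraction))
        for hemi in ("L", "R"):
            right = 1.0 if hemi == "R" else 0.0
            v1 = base + params.hemisphere_offset * (right - 0.5)
            v1 += rng.normal(0.0, params.volume_sd) if params.volume_sd > 0 else 0.0
            v1 = max(v1, params.volume_floor)
            v2 = params.rater2_slope * v1 + params.rater2_intercept
            if noise_sd2 > 0:
                v2 += rng.normal(0.0, noise_sd2)
            v2 = max(v2, params.volume_floor)
            desc1, desc2 = {}, {}
            for name, mean in params.descriptor_means.items():
                sd = params.descriptor_sds[name]
                slope = params.volume_slopes.get(name, 0.0)
                d1 = mean + slope * (v1 - _expected_volume(params))
                d1 += rng.normal(0.0, sd) if sd > 0 else 0.0
                d2 = d1 + params.rater2_offsets.get(name, 0.0)
                d2 += rng.normal(0.0, 0.25 * sd) if sd > 0 else 0.0
                desc1[name], desc2[name] = d1, d2
            for rater, vol, desc in ((1, v1, desc1), (2, v2, desc2)):
                rows.append({
                    "patient_id": f"P{i:04d}", "age": float(ages[i]),
                    "sex": str(sexes[i]), "hemisphere": hemi, "rater": rater,
                    "volume_cm3": float(vol),
                    **{k: float(_clip_descriptor(k, v)) for k, v in desc.items()},
                })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _expected_volume(params: CohortSimParams) -> float:
    """Mean rater-1 volume implied by the generative law (centering point
    for the descriptor-volume couplings)."""
    lo, hi = params.age_range
    c = params.peak_age
    m2 = ((hi - c) ** 3 - (lo - c) ** 3) / (3 * (hi - lo))
    # sex and hemisphere offsets are centered, so they drop out of the mean
    return params.peak_volume + params.quad_coefficient * m2


def _clip_descriptor(name: str, value: float) -> float:
    if name in ("aspect_ratio", "sphericity"):
        return float(np.clip(value, 0.01, 1.0))
    if name == "roundness":
        return float(np.clip(value, 0.01, 1.05))
    return float(max(value, 0.01))
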