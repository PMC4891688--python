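"""Synthetic porated-vesicle scenes with ground truth.

A scene is a spherical vesicle of radius R bearing one circular pore whose
rim is the circle at polar angle ``pore_half_angle`` about the pore axis
(pore diameter d = 2·R·sin(half_angle)).  Gold particles are placed on the
rim (with radial jitter) and/or uniformly over the remaining membrane,
the scene is projected orthographically along the viewing axis (+z, as in
transmission imaging — no occlusion), and rendered to a calibrated 8-bit
image in which gold is the darkest feature.

Conventions: right-handed axes, viewing axis +z, image y increases
downward.  All stochastic draws derive from one seed in a documented
order: rim placement uses sub-stream (seed, 1), background placement
(seed, 2), particle diameters share the placement stream, rendering noise
(seed, 3).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .detect import ProjectionImage
from .errors import ParameterError, ValidationError
from .geometry import Polyline

__all__ = [
    "VesicleModel",
    "Particle3D",
    "PlacementParams",
    "Orientation",
    "Scene",
    "ParticleTruth",
    "GroundTruth",
    "make_scene",
    "place_rim_particles",
    "place_background_particles",
    "project_scene",
    "render_image",
    "image_offset",
]

logger = logging.getLogger(__name__)

GOLD_INTENSITY = 40
MEMBRANE_INTENSITY_RANGE = (80, 150)
LUMEN_INTENSITY = 200
EXTERIOR_INTENSITY = 220
DEFAULT_MARGIN = 15.0  # nm of clear space around the vesicle in renders
RIM_POLYLINE_VERTICES = 720
_PLACEMENT_CAP = 1e6


@dataclass(frozen=True)
class VesicleModel:
    """Spherical vesicle with a single circular pore."""

    radius: float  # nm
    membrane_thickness: float = 5.0  # nm
    pore_half_angle: float = 0.4  # rad, polar angle of the rim circle

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError("radius: must be positive")
        if not 0 < self.membrane_thickness < self.radius:
            raise ValidationError(
                "membrane_thickness: must satisfy 0 < thickness < radius"
            )
        if not 0 < self.pore_half_angle < np.pi / 2:
            raise ValidationError("pore_half_angle: must lie in (0, π/2)")

    @property
    def rim_radius(self) -> float:
        """Radius of the rim circle, R·sin(half_angle)."""
        return self.radius * math.sin(self.pore_half_angle)

    @property
    def pore_diameter(self) -> float:
        return 2.0 * self.rim_radius

    @property
    def rim_circumference(self) -> float:
        return math.pi * self.pore_diameter

    @property
    def rim_height(self) -> float:
        """z of the rim plane in the vesicle frame (pore axis = +z)."""
        return self.radius * math.cos(self.pore_half_angle)


@dataclass(frozen=True)
class Orientation:
    """Viewing geometry: tilt is the angle between pore axis and the
    viewing axis; azimuth rotates the tilted axis about the viewing axis."""

    tilt: float = 0.0
    azimuth: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt <= np.pi / 2:
            raise ValidationError("tilt: must lie in [0, π/2]")

    @property
    def is_edge_on(self) -> bool:
        return self.tilt == np.pi / 2

    def rotation_matrix(self) -> np.ndarray:
        """Vesicle frame -> lab frame (pore axis maps to the tilted axis)."""
        ct, st = math.cos(self.tilt), math.sin(self.tilt)
        ca, sa = math.cos(self.azimuth), math.sin(self.azimuth)
        ry = np.array([[ct, 0, st], [0, 1, 0], [-st, 0, ct]])
        rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        return rz @ ry


@dataclass(frozen=True)
class Particle3D:
    position: np.ndarray  # (3,) nm, vesicle frame, on the membrane sphere
    diameter: float  # nm
    particle_class: str  # "rim" | "background"

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValidationError("diameter: must be positive")
        if self.particle_class not in ("rim", "background"):
            raise ValidationError(f"particle_class: unknown {self.particle_class!r}")


@dataclass(frozen=True)
class PlacementParams:
    """Parameters of stochastic particle placement.

    ``linear_density`` (λ) is particles per nm of rim; ``labeling_efficiency``
    (p) thins the rim count; ``count_mode`` selects Poisson counts (default)
    or the deterministic fixed count round(λ·p·circumference).
    """

    linear_density: float = 1.0 / 6.0
    labeling_efficiency: float = 1.0
    rim_jitter_sd: float = 0.3
    background_area_density: float = 0.0
    seed: int = 0
    count_mode: str = "poisson"  # "poisson" | "fixed"
    rim_exclusion_nm: float = 5.0  # background keep-out band around the rim
    diameter_mean: float = 1.3
    diameter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.linear_density < 0:
            raise ValidationError("linear_density: must be non-negative")
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise ValidationError("labeling_efficiency: must lie in [0, 1]")
        if self.rim_jitter_sd < 0:
            raise ValidationError("rim_jitter_sd: must be non-negative")
        if self.background_area_density < 0:
            raise ValidationError("background_area_density: must be non-negative")
        if self.count_mode not in ("poisson", "fixed"):
            raise ValidationError(f"count_mode: unknown {self.count_mode!r}")
        if self.rim_exclusion_nm < 0:
            raise ValidationError("rim_exclusion_nm: must be non-negative")
        if self.diameter_mean <= 0 or self.diameter_sd < 0:
            raise ValidationError("diameter_mean/diameter_sd: invalid")


@dataclass(frozen=True)
class Scene:
    vesicle: VesicleModel
    orientation: Orientation
    particles: tuple = ()

    @property
    def rim_particles(self):
        return tuple(p for p in self.particles if p.particle_class == "rim")

    @property
    def background_particles(self):
        return tuple(p for p in self.particles if p.particle_class == "background")


@dataclass(frozen=True)
class ParticleTruth:
    position_2d: np.ndarray  # projected center, lab nm (vesicle-centered)
    particle_class: str
    distance_to_rim: float  # true 3D distance to the rim circle, nm
    diameter: float


@dataclass(frozen=True)
class GroundTruth:
    true_circumference: float
    projected_rim: Polyline
    particles_2d: tuple
    tilt: float


def make_scene(vesicle: VesicleModel, orientation: Orientation) -> Scene:
    """Create an empty scene; the rim circle is defined analytically by the
    vesicle model, so nothing further is computed here."""
    if orientation.is_edge_on:
        logger.info("scene viewed exactly edge-on (tilt = π/2)")
    return Scene(vesicle=vesicle, orientation=orientation)


def _draw_diameters(rng: np.random.Generator, n: int, params: PlacementParams):
    if params.diameter_sd == 0:
        return np.full(n, params.diameter_mean)
    d = rng.normal(params.diameter_mean, params.diameter_sd, size=n)
    return np.clip(d, 0.1 * params.diameter_mean, None)


def place_rim_particles(scene: Scene, params: PlacementParams) -> Scene:
    """Decorate the rim with particles at linear density λ, thinned by the
    labeling efficiency.

    The count is Poisson(λ·p·C) (or round(λ·p·C) in fixed mode); azimuths
    are uniform on the rim circle and each particle is displaced along the
    sphere surface, perpendicular to the rim, by a Gaussian jitter
    truncated at ±3 sd.
    """
    v = scene.vesicle
    circ = v.rim_circumference
    if params.linear_density * circ >= _PLACEMENT_CAP:
        raise ParameterError(
            "linear_density: λ·circumference exceeds the sanity cap of 1e6"
        )
    rng = np.random.default_rng([params.seed, 1])
    mean = params.linear_density * params.labeling_efficiency * circ
    if params.count_mode == "fixed":
        n = int(round(mean))
    else:
        n = int(rng.poisson(mean))
    if n == 0:
        return scene
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    if params.rim_jitter_sd > 0:
        s = rng.normal(0.0, params.rim_jitter_sd, size=n)
        s = np.clip(s, -3.0 * params.rim_jitter_sd, 3.0 * params.rim_jitter_sd)
    else:
        s = np.zeros(n)
    theta = v.pore_half_angle + s / v.radius  # arc jitter perpendicular to rim
    diam = _draw_diameters(rng, n, params)
    pos = np.column_stack(
        [
            v.radius * np.sin(theta) * np.cos(phi),
            v.radius * np.sin(theta) * np.sin(phi),
            v.radius * np.cos(theta),
        ]
    )
    new = tuple(
        Particle3D(position=pos[i], diameter=float(diam[i]), particle_class="rim")
        for i in range(n)
    )
    return replace(scene, particles=scene.particles + new)


def eligible_background_area(vesicle: VesicleModel, rim_exclusion_nm: float) -> float:
    """Membrane area available to background particles: the sphere minus the
    pore cap and a geodesic keep-out band beyond the rim."""
    theta_min = vesicle.pore_half_angle + rim_exclusion_nm / vesicle.radius
    if theta_min >= np.pi:
        return 0.0
    return 2.0 * np.pi * vesicle.radius ** 2 * (1.0 + math.cos(theta_min))


def place_background_particles(scene: Scene, params: PlacementParams) -> Scene:
    """Scatter nonspecific particles uniformly over the membrane outside the
    pore cap and outside the rim keep-out band."""
    v = scene.vesicle
    area = eligible_background_area(v, params.rim_exclusion_nm)
    rng = np.random.default_rng([params.seed, 2])
    n = int(rng.poisson(params.background_area_density * area))
    if n == 0:
        return scene
    theta_min = v.pore_half_angle + params.rim_exclusion_nm / v.radius
    # uniform on the spherical zone theta in [theta_min, pi]
    cos_theta = rng.uniform(-1.0, math.cos(theta_min), size=n)
    theta = np.arccos(cos_theta)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    diam = _draw_diameters(rng, n, params)
    pos = np.column_stack(
        [
            v.radius * np.sin(theta) * np.cos(phi),
            v.radius * np.sin(theta) * np.sin(phi),
            v.radius * cos_theta,
        ]
    )
    new = tuple(
        Particle3D(position=pos[i], diameter=float(diam[i]),
                   particle_class="background")
        for i in range(n)
    )
    return replace(scene, particles=scene.particles + new)


def _distance_to_rim_3d(position: np.ndarray, vesicle: VesicleModel) -> float:
    """Exact distance from a 3D point (vesicle frame) to the rim circle."""
    x, y, z = position
    rho = math.hypot(x, y)
    return math.hypot(rho - vesicle.rim_radius, z - vesicle.rim_height)


def rim_circle_points(vesicle: VesicleModel, n: int = RIM_POLYLINE_VERTICES,
                      radial_offset: float = 0.0) -> np.ndarray:
    """Vertices of a circle concentric with the rim, in the rim plane
    (vesicle frame), at rim_radius + radial_offset."""
    r = vesicle.rim_radius + radial_offset
    if r <= 0:
        raise ValidationError("radial_offset: circle radius must stay positive")
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [r * np.cos(phi), r * np.sin(phi), np.full(n, vesicle.rim_height)]
    )


def project_scene(scene: Scene, n_rim_vertices: int = RIM_POLYLINE_VERTICES) -> GroundTruth:
    """Orthographic projection along +z with exact ground truth.

    The rim circle projects to an ellipse with semiaxes r and r·cos(tilt)
    (polygonized at ``n_rim_vertices``); particle centers project exactly
    and each carries its true 3D distance to the rim circle.
    """
    v = scene.vesicle
    M = scene.orientation.rotation_matrix()
    rim3d = rim_circle_points(v, n_rim_vertices)
    rim2d = (rim3d @ M.T)[:, :2]
    truths = []
    for p in scene.particles:
        lab = M @ p.position
        truths.append(
            ParticleTruth(
                position_2d=lab[:2],
                particle_class=p.particle_class,
                distance_to_rim=_distance_to_rim_3d(p.position, v),
                diameter=p.diameter,
            )
        )
    return GroundTruth(
        true_circumference=v.rim_circumference,
        projected_rim=Polyline(rim2d, closed=True),
        particles_2d=tuple(truths),
        tilt=scene.orientation.tilt,
    )


def image_offset(vesicle: VesicleModel, margin: float = DEFAULT_MARGIN) -> float:
    """Shift from lab coordinates (vesicle-centered) to image coordinates
    (origin at the top-left pixel corner): add this to both x and y."""
    return vesicle.radius + margin


def render_image(
    scene: Scene,
    pixel_size: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin: float = DEFAULT_MARGIN,
) -> ProjectionImage:
    """Render the scene to a calibrated 8-bit image.

    Gold particles are hard disks at intensity 40 (center of the default
    detection band); the membrane shell maps its projected path length into
    [80, 150]; lumen and exterior are >= 180, so in noise-free renders the
    30-50 band selects gold pixels and nothing else.  Optional Gaussian
    noise (off by default) is clipped to [0, 255].
    """
    if not pixel_size > 0:
        raise ValidationError("pixel_size: must be positive")
    v = scene.vesicle
    half = image_offset(v, margin)
    n_px = int(math.ceil(2.0 * half / pixel_size))
    c = (np.arange(n_px) + 0.5) * pixel_size - half
    X, Y = np.meshgrid(c, c)  # X: column coordinate, Y: row coordinate (down)
    rho = np.hypot(X, Y)

    img = np.full((n_px, n_px), float(EXTERIOR_INTENSITY))
    inner_r = v.radius - v.membrane_thickness
    img[rho < inner_r] = LUMEN_INTENSITY

    ring = (rho >= inner_r) & (rho <= v.radius)
    if np.any(ring):
        M = scene.orientation.rotation_matrix()
        zmax = math.sqrt(max(v.radius ** 2 - inner_r ** 2, 0.0))
        xr, yr = X[ring], Y[ring]
        z1 = np.sqrt(np.maximum(v.radius ** 2 - xr ** 2 - yr ** 2, 0.0))
        cos_cap = math.cos(v.pore_half_angle)
        # membrane is absent where the shell crossing falls in the pore cap;
        # the near and far crossings each carry half the path length
        weight = np.zeros_like(z1)
        for sign in (1.0, -1.0):
            z_v = M[0, 2] * xr + M[1, 2] * yr + M[2, 2] * sign * z1
            weight += 0.5 * (z_v < cos_cap * v.radius)
        path = 2.0 * z1 * weight
        lo, hi = MEMBRANE_INTENSITY_RANGE
        frac = np.clip(path / (2.0 * zmax), 0.0, 1.0) if zmax > 0 else path * 0.0
        vals = np.where(
            path > 0.0,
            np.rint(hi - (hi - lo) * frac),
            float(LUMEN_INTENSITY),
        )
        img[ring] = vals

    # gold disks, drawn last (darkest feature wins)
    M = scene.orientation.rotation_matrix()
    for p in scene.particles:
        lab = M @ p.position
        r_disk = p.diameter / 2.0
        if math.pi * r_disk ** 2 < pixel_size ** 2:
            logger.warning(
                "particle of diameter %.3g nm covers < 1 pixel at %.3g nm/px",
                p.diameter, pixel_size,
            )
        cx, cy = lab[0], lab[1]
        c0 = max(int((cx + half - r_disk) / pixel_size) - 1, 0)
        c1 = min(int((cx + half + r_disk) / pixel_size) + 2, n_px)
        r0 = max(int((cy + half - r_disk) / pixel_size) - 1, 0)
        r1 = min(int((cy + half + r_disk) / pixel_size) + 2, n_px)
        if c0 >= c1 or r0 >= r1:
            continue
        sub_x = X[r0:r1, c0:c1]
        sub_y = Y[r0:r1, c0:c1]
        disk = (sub_x - cx) ** 2 + (sub_y - cy) ** 2 <= r_disk ** 2
        img[r0:r1, c0:c1][disk] = GOLD_INTENSITY

    if noise_sd > 0:
        rng = np.random.default_rng([seed, 3])
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ProjectionImage(intensities=img, pixel_size=pixel_size)
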