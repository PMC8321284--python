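"""Synthetic compressed-breast slab phantoms and noisy projection simulation.

The generator emulates the structure of a swirled two-tissue breast imaging
slab: a heterogeneous background where adipose-like and gland-like material
mix in a roughly 50/50 ratio, low-contrast acrylic-like spheres standing in
for masses (millimetre scale), and clusters of small high-attenuation specks
standing in for microcalcifications (hundreds of micrometres, i.e. around
one or two voxels across, rendered with partial-volume weighting so they do
not vanish from the grid).

Projections follow the Lambert-Beer log model: expected photon counts are
``P0 * exp(-line integral)``; optional Poisson noise is drawn per detector
cell from a seeded generator and counts are clipped to >= 1 before the log.
The simulator also returns the exact noise norm ``||b - Mx||``, directly
usable as the data-fit ball radius of the constrained solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Geometry
from .projector import ProjectionStack, Volume, forward_project

__all__ = [
    "BackgroundSpec",
    "MassSpec",
    "MCClusterSpec",
    "PhantomSpec",
    "SimulationSpec",
    "generate_phantom",
    "simulate_projections",
    "default_phantom_spec",
]


@dataclass(frozen=True)
class BackgroundSpec:
    """Two-tissue heterogeneous background parameters (attenuations in 1/mm)."""

    mu_adipose: float = 0.05
    mu_gland: float = 0.08
    mix_fraction: float = 0.5   # gland volume fraction
    texture_scale_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.mix_fraction < 1:
            raise ValueError("mix_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class MassSpec:
    """A low-contrast sphere; center in mm (world frame), diameter in mm."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    mu: float = 0.09

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")


@dataclass(frozen=True)
class MCClusterSpec:
    """A cluster of small high-contrast spheres on one slice.

    Speck positions are drawn (seeded) uniformly in a disc of radius
    ``spread_mm`` around the cluster center, all at the center's Z.
    """

    center_mm: tuple[float, float, float]
    n_specks: int = 6
    speck_diameter_um: float = 230.0
    spread_mm: float = 1.0
    mu: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.speck_diameter_um <= 0:
            raise ValueError("speck_diameter_um must be > 0")
        if self.n_specks < 1:
            raise ValueError("n_specks must be >= 1")


@dataclass(frozen=True)
class PhantomSpec:
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    masses: tuple[MassSpec, ...] = ()
    mc_clusters: tuple[MCClusterSpec, ...] = ()


@dataclass(frozen=True)
class SimulationSpec:
    """Photon budget and noise switches for projection simulation."""

    photon_count_p0: float = 1e5
    poisson: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.photon_count_p0 <= 0:
            raise ValueError("photon_count_p0 must be > 0")


def _sphere_fraction(g: Geometry, center, radius_mm, subsamples=4):
    """Sphere-voxel overlap fractions on the voxel grid (partial volume).

    Returns ``(slices, frac)`` where ``frac`` holds, for each voxel in the
    bounding box ``slices``, the fraction of its volume inside the sphere,
    estimated on a per-voxel sub-grid.  The sub-grid is refined per axis so
    the sub-cell size stays below about a quarter of the sphere radius;
    without that, specks much smaller than the (strongly anisotropic) voxel
    would fall between sampling points and vanish.
    """
    d = np.array(g.voxel_size_mm)
    org = np.array(g.volume_origin_mm)
    c = np.asarray(center, dtype=np.float64)
    lo_idx = np.floor((c - radius_mm - org) / d).astype(int)
    hi_idx = np.ceil((c + radius_mm - org) / d).astype(int)
    if np.any(lo_idx < 0) or np.any(hi_idx > np.array(g.grid_shape)):
        raise ValueError(
            f"object at {tuple(c)} mm (radius {radius_mm} mm) extends outside the grid"
        )
    shape = tuple(hi_idx - lo_idx)
    n_sub = [
        int(min(32, max(subsamples, np.ceil(4.0 * d[a] / radius_mm)))) for a in range(3)
    ]
    # sub-sample offsets at sub-cell centers, per axis
    offs = [(np.arange(n_sub[a]) + 0.5) / n_sub[a] * d[a] for a in range(3)]
    centers = [
        org[a] + (lo_idx[a] + np.arange(shape[a])[:, None]) * d[a] + offs[a][None, :]
        for a in range(3)
    ]
    dx2 = (centers[0] - c[0]) ** 2  # (nx, sx)
    dy2 = (centers[1] - c[1]) ** 2
    dz2 = (centers[2] - c[2]) ** 2
    inside = (
        dx2[:, None, None, :, None, None]
        + dy2[None, :, None, None, :, None]
        + dz2[None, None, :, None, None, :]
    ) <= radius_mm**2
    frac = inside.reshape(shape + (int(np.prod(n_sub)),)).mean(axis=-1)
    sl = tuple(slice(lo_idx[a], hi_idx[a]) for a in range(3))
    return sl, frac


def generate_phantom(spec: PhantomSpec, g: Geometry) -> Volume:
    """Build the phantom volume: textured background plus embedded objects.

    The background thresholds a smoothed seeded Gaussian random field at the
    quantile matching ``mix_fraction``, giving a binary adipose/gland
    texture whose gland fraction matches the requested mix to within the
    grid's granularity.  Masses and microcalcification specks then overwrite
    the background via convex partial-volume blending.  Deterministic given
    the seeds.
    """
    bg = spec.background
    rng = np.random.default_rng(bg.seed)
    field_ = rng.standard_normal(g.grid_shape)
    sigma_vox = [bg.texture_scale_mm / v for v in g.voxel_size_mm]
    field_ = gaussian_filter(field_, sigma=sigma_vox, mode="wrap")
    thr = np.quantile(field_, 1.0 - bg.mix_fraction)
    values = np.where(field_ >= thr, bg.mu_gland, bg.mu_adipose).astype(np.float64)

    for mass in spec.masses:
        sl, frac = _sphere_fraction(g, mass.center_mm, mass.diameter_mm / 2.0)
        values[sl] = values[sl] * (1.0 - frac) + mass.mu * frac

    for cluster in spec.mc_clusters:
        crng = np.random.default_rng(cluster.seed)
        r = cluster.spread_mm * np.sqrt(crng.uniform(0, 1, cluster.n_specks))
        ang = crng.uniform(0, 2 * np.pi, cluster.n_specks)
        cx, cy, cz = cluster.center_mm
        radius = cluster.speck_diameter_um / 2000.0  # um diameter -> mm radius
        for ri, ai in zip(r, ang):
            center = (cx + ri * np.cos(ai), cy + ri * np.sin(ai), cz)
            sl, frac = _sphere_fraction(g, center, radius, subsamples=6)
            values[sl] = values[sl] * (1.0 - frac) + cluster.mu * frac

    return Volume(values, g)


def simulate_projections(
    x: Volume, g: Geometry | None = None, sim: SimulationSpec | None = None
) -> tuple[ProjectionStack, float]:
    """Simulate log-attenuation projections, optionally with Poisson noise.

    Returns ``(projections, noise_norm)`` where ``noise_norm`` is the
    Euclidean norm of the difference between the noisy log data and the
    exact line integrals (zero in the noiseless branch).
    """
    if np.any(x.values < 0):
        raise ValueError("attenuation volume must be nonnegative")
    g = g if g is not None else x.geometry
    sim = sim or SimulationSpec()
    line_integrals = forward_project(x, g).values
    if not sim.poisson:
        return ProjectionStack(line_integrals.copy(), g), 0.0
    rng = np.random.default_rng(sim.seed)
    expected = sim.photon_count_p0 * np.exp(-line_integrals)
    counts = np.maximum(rng.poisson(expected).astype(np.float64), 1.0)
    b = -np.log(counts / sim.photon_count_p0)
    noise_norm = float(np.linalg.norm(b - line_integrals))
    return ProjectionStack(b, g), noise_norm


def default_phantom_spec(g: Geometry, seed: int = 0) -> PhantomSpec:
    """A slab mirroring the analyzed objects of a breast accreditation slab.

    Contains the 4.7 mm and 3.1 mm masses and the 230 / 165 / 130 um speck
    clusters, all on the central slice, placed in the XY plane relative to
    the volume center.  Requires a grid of at least ~11 x 11 mm in-plane.
    """
    nx, ny, nz = g.grid_shape
    dx, dy, dz = g.voxel_size_mm
    ox, oy, oz = g.volume_origin_mm
    cx = ox + nx * dx / 2.0
    cy = oy + ny * dy / 2.0
    cz = oz + nz * dz / 2.0
    return PhantomSpec(
        background=BackgroundSpec(seed=seed),
        masses=(
            MassSpec(center_mm=(cx - 2.6, cy - 2.6, cz), diameter_mm=4.7),
            MassSpec(center_mm=(cx + 2.8, cy + 2.8, cz), diameter_mm=3.1),
        ),
        mc_clusters=(
            MCClusterSpec(center_mm=(cx, cy + 3.5, cz), speck_diameter_um=230.0, seed=seed + 1),
            MCClusterSpec(center_mm=(cx + 3.5, cy - 2.0, cz), speck_diameter_um=165.0, seed=seed + 2),
            MCClusterSpec(center_mm=(cx - 3.5, cy + 0.5, cz), speck_diameter_um=130.0, seed=seed + 3),
        ),
    )
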