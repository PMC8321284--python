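"""Acquisition geometry for a digital breast tomosynthesis (DBT) scan.

The world frame is fixed as follows: the flat, stationary detector lies in
the plane ``z = 0`` with its center at the origin; ``X`` runs along detector
columns, ``Y`` along detector rows, and ``Z`` points up towards the X-ray
source.  The reconstructed volume is a slab of voxels sitting on (or above)
the detector, sliced parallel to it along ``Z``.  The source travels along a
circular arc in the ``XZ`` plane, centered on the detector center, symmetric
about the vertical; for an odd number of views the central source position is
vertically above the detector center.

All lengths are millimetres, all angles degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = ["Geometry", "default_geometry", "source_positions"]


@dataclass(frozen=True)
class Geometry:
    """Scanner description: source arc, detector grid and voxel grid.

    Parameters
    ----------
    n_angles
        Number of projection views ``N_theta`` (equally spaced angles).
    angular_range_deg
        Total angular span of the source arc; views are spaced by
        ``angular_range_deg / (n_angles - 1)`` and symmetric about 0 deg.
    source_to_detector_mm
        Arc radius, i.e. the source height above the detector center at the
        central (vertical) position.
    detector_rows, detector_cols
        Detector grid size; rows run along ``Y``, columns along ``X``.
    detector_pitch_mm
        Square detector pixel pitch.
    grid_shape
        Voxel counts ``(Nx, Ny, Nz)``.
    voxel_size_mm
        Voxel edge lengths ``(dx, dy, dz)``.
    volume_origin_mm
        World position of the corner of voxel ``(0, 0, 0)``; voxel
        ``(i, j, k)`` occupies the half-open box
        ``[origin + (i, j, k) * d, origin + (i + 1, j + 1, k + 1) * d)``.
    """

    n_angles: int
    angular_range_deg: float
    source_to_detector_mm: float
    detector_rows: int
    detector_cols: int
    detector_pitch_mm: float
    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    volume_origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "volume_origin_mm", tuple(float(v) for v in self.volume_origin_mm))
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.n_angles > 1 and self.angular_range_deg <= 0:
            raise ValueError("angular_range_deg must be > 0 for more than one view")
        for name in ("source_to_detector_mm", "detector_pitch_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.detector_rows < 1 or self.detector_cols < 1:
            raise ValueError("detector grid must have at least one pixel")
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be three counts >= 1")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be > 0")
        if self.volume_origin_mm[2] < 0:
            raise ValueError("volume must sit above the detector plane (z >= 0)")
        top = self.volume_origin_mm[2] + self.grid_shape[2] * self.voxel_size_mm[2]
        if top >= self.source_to_detector_mm:
            raise ValueError("source arc must lie above the volume")

    # ---- derived sizes -------------------------------------------------
    @property
    def n_detector_pixels(self) -> int:
        """Pixels per projection image, ``Np``."""
        return self.detector_rows * self.detector_cols

    @property
    def n_voxels(self) -> int:
        """Voxel count ``Nv = Nx * Ny * Nz``."""
        return int(np.prod(self.grid_shape))

    @property
    def n_data(self) -> int:
        """Total measurement count ``Nd = Np * N_theta``."""
        return self.n_detector_pixels * self.n_angles

    @property
    def angles_deg(self) -> np.ndarray:
        """View angles, equally spaced and symmetric about the vertical."""
        if self.n_angles == 1:
            return np.zeros(1)
        half = self.angular_range_deg / 2.0
        return np.linspace(-half, half, self.n_angles)

    # detector pixel edge coordinates (cell c spans [x_edges[c], x_edges[c+1]])
    @property
    def detector_x_edges(self) -> np.ndarray:
        w = self.detector_cols * self.detector_pitch_mm
        return -w / 2.0 + self.detector_pitch_mm * np.arange(self.detector_cols + 1)

    @property
    def detector_y_edges(self) -> np.ndarray:
        h = self.detector_rows * self.detector_pitch_mm
        return -h / 2.0 + self.detector_pitch_mm * np.arange(self.detector_rows + 1)

    def voxel_edges(self, axis: int) -> np.ndarray:
        """World coordinates of voxel boundaries along ``axis`` (0=x,1=y,2=z)."""
        n = self.grid_shape[axis]
        return self.volume_origin_mm[axis] + self.voxel_size_mm[axis] * np.arange(n + 1)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["volume_origin_mm"] = list(self.volume_origin_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry":
        return cls(
            n_angles=int(d["n_angles"]),
            angular_range_deg=float(d["angular_range_deg"]),
            source_to_detector_mm=float(d["source_to_detector_mm"]),
            detector_rows=int(d["detector_rows"]),
            detector_cols=int(d["detector_cols"]),
            detector_pitch_mm=float(d["detector_pitch_mm"]),
            grid_shape=tuple(d["grid_shape"]),
            voxel_size_mm=tuple(d["voxel_size_mm"]),
            volume_origin_mm=tuple(d["volume_origin_mm"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Geometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _centered_origin(grid_shape, voxel_size) -> tuple[float, float, float]:
    nx, ny, _ = grid_shape
    dx, dy, _ = voxel_size
    return (-nx * dx / 2.0, -ny * dy / 2.0, 0.0)


def default_geometry(preset: str) -> Geometry:
    """Return a named geometry preset.

    ``"giotto-class"`` describes a nominal clinical DBT unit: 11 views over a
    30 degree arc, source 700 mm above a stationary flat detector with
    0.085 mm pixel pitch, reconstructing 0.090 x 0.090 x 1.0 mm voxels.  The
    published figures are approximate ("about 70 cm", "approximately 30
    degrees"), so every field stays configurable.

    ``"small-test"`` is a desk-scale geometry small enough that the full
    system matrix can be materialized as a dense array for oracle tests.
    """
    if preset == "giotto-class":
        grid = (2333, 1267, 50)  # 21.0 cm x 11.4 cm x 50 slices
        voxel = (0.090, 0.090, 1.0)
        return Geometry(
            n_angles=11,
            angular_range_deg=30.0,
            source_to_detector_mm=700.0,
            detector_rows=2824,   # 24 cm sensitive area
            detector_cols=3529,   # 30 cm sensitive area
            detector_pitch_mm=0.085,
            grid_shape=grid,
            voxel_size_mm=voxel,
            volume_origin_mm=_centered_origin(grid, voxel),
        )
    if preset == "small-test":
        grid = (24, 24, 4)
        voxel = (0.090, 0.090, 1.0)
        return Geometry(
            n_angles=11,
            angular_range_deg=30.0,
            source_to_detector_mm=700.0,
            detector_rows=32,
            detector_cols=48,
            detector_pitch_mm=0.085,
            grid_shape=grid,
            voxel_size_mm=voxel,
            volume_origin_mm=_centered_origin(grid, voxel),
        )
    raise ValueError(f"unknown geometry preset: {preset!r}")


def source_positions(g: Geometry) -> np.ndarray:
    """Source points along the arc, ordered by angle, shape ``(n_angles, 3)``.

    The arc of radius ``source_to_detector_mm`` lies in the XZ plane and is
    centered on the detector center, so the central view (odd ``n_angles``)
    is vertically above the detector center.
    """
    phi = np.deg2rad(g.angles_deg)
    r = g.source_to_detector_mm
    return np.column_stack([r * np.sin(phi), np.zeros_like(phi), r * np.cos(phi)])
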