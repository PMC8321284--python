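"""Distance-driven cone-beam projector for a flat stationary detector.

The system matrix ``M`` maps a voxelized attenuation map ``x`` to the stack
of log-attenuation line integrals ``b`` recorded by the detector (the
Lambert-Beer log transform of the measured intensities).  ``M`` is modeled
with the distance-driven construction: for each view and each detector-
parallel voxel slice, the axis-aligned footprint of every voxel is
perspectively projected from the source point straight onto the detector
plane (the detector is parallel to the compression plane, so no intermediate
projection plane is needed), and the weight coupling detector cell ``i`` to
voxel ``j`` is the separable overlap of the two footprints, normalized by
the cell area and scaled by the slice thickness times the ray obliquity
``1 / cos(psi)``.  A vertical ray through a single voxel therefore
accumulates exactly ``mu * dz``: projections are length-weighted line
integrals.

The forward operator and the backprojector are matrix-free but share the
same footprint weights, so backprojection is the exact adjoint ``M^T``.  For
desk-scale geometries :func:`build_dense_matrix` materializes ``M``
explicitly as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import Geometry, source_positions

__all__ = [
    "Volume",
    "ProjectionStack",
    "forward_project",
    "back_project",
    "build_dense_matrix",
    "DENSE_MATRIX_GUARD",
]

# refuse to materialize system matrices beyond this many entries
DENSE_MATRIX_GUARD = 10**8


@dataclass
class Volume:
    """3D attenuation map (1/mm), shape ``(Nx, Ny, Nz)``, tied to a geometry."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.grid_shape:
            raise ValueError(
                f"volume shape {self.values.shape} does not match "
                f"geometry grid {self.geometry.grid_shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @classmethod
    def zeros(cls, g: Geometry) -> "Volume":
        return cls(np.zeros(g.grid_shape), g)


@dataclass
class ProjectionStack:
    """Stack of log-attenuation projection images, shape ``(N_theta, rows, cols)``."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_angles, self.geometry.detector_rows, self.geometry.detector_cols)
        if self.values.shape != expected:
            raise ValueError(
                f"projection shape {self.values.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projection values must be finite")

    @classmethod
    def zeros(cls, g: Geometry) -> "ProjectionStack":
        return cls(np.zeros((g.n_angles, g.detector_rows, g.detector_cols)), g)


def _interval_overlap(cell_edges: np.ndarray, foot_edges: np.ndarray) -> np.ndarray:
    """Pairwise overlap lengths between two sets of contiguous sorted intervals.

    Returns an array ``O[c, j]`` = length of the intersection of detector
    cell ``c`` with projected voxel footprint ``j``.
    """
    lo = np.maximum(cell_edges[:-1, None], foot_edges[None, :-1])
    hi = np.minimum(cell_edges[1:, None], foot_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


class DistanceDrivenProjector:
    """Precomputed per-(view, slice) footprint overlap factors for a geometry.

    The separable distance-driven weight for view ``t``, slice ``k``,
    detector pixel ``(r, c)`` and voxel ``(ix, iy, k)`` is::

        W = obliq[t][r, c] * A_v[t][k][r, iy] * A_u[t][k][c, ix] * dz / pitch^2

    where ``A_u`` / ``A_v`` are the 1D overlaps along detector columns (X)
    and rows (Y) between the cell and the voxel footprint projected from the
    source through the slice mid-plane, and ``obliq = 1 / cos(psi)`` is the
    obliquity of the ray through the pixel center.
    """

    def __init__(self, g: Geometry):
        self.geometry = g
        nx, ny, nz = g.grid_shape
        dz = g.voxel_size_mm[2]
        self.scale = dz / g.detector_pitch_mm**2
        cell_u = g.detector_x_edges
        cell_v = g.detector_y_edges
        ucent = 0.5 * (cell_u[:-1] + cell_u[1:])
        vcent = 0.5 * (cell_v[:-1] + cell_v[1:])
        xe = g.voxel_edges(0)
        ye = g.voxel_edges(1)
        ze = g.voxel_edges(2)
        z_mid = 0.5 * (ze[:-1] + ze[1:])  # slice mid-planes

        self.obliq: list[np.ndarray] = []
        self.a_u: list[list[np.ndarray]] = []  # [view][slice] -> (cols, Nx)
        self.a_v: list[list[np.ndarray]] = []  # [view][slice] -> (rows, Ny)
        for s in source_positions(g):
            sx, sy, sz = s
            dist = np.sqrt((ucent[None, :] - sx) ** 2 + (vcent[:, None] - sy) ** 2 + sz**2)
            self.obliq.append(dist / sz)
            au_k, av_k = [], []
            for zc in z_mid:
                t = sz / (sz - zc)  # magnification of the slice onto the detector
                au_k.append(_interval_overlap(cell_u, sx + t * (xe - sx)))
                av_k.append(_interval_overlap(cell_v, sy + t * (ye - sy)))
            self.a_u.append(au_k)
            self.a_v.append(av_k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        g = self.geometry
        out = np.zeros((g.n_angles, g.detector_rows, g.detector_cols))
        for t in range(g.n_angles):
            acc = np.zeros((g.detector_rows, g.detector_cols))
            for k in range(g.grid_shape[2]):
                # (rows, Ny) @ (Ny, Nx) @ (Nx, cols) -> (rows, cols)
                acc += self.a_v[t][k] @ x[:, :, k].T @ self.a_u[t][k].T
            out[t] = self.obliq[t] * acc * self.scale
        return out

    def adjoint(self, b: np.ndarray) -> np.ndarray:
        g = self.geometry
        x = np.zeros(g.grid_shape)
        for t in range(g.n_angles):
            p = self.obliq[t] * b[t] * self.scale
            for k in range(g.grid_shape[2]):
                x[:, :, k] += (self.a_v[t][k].T @ p @ self.a_u[t][k]).T
        return x


@lru_cache(maxsize=8)
def get_projector(g: Geometry) -> DistanceDrivenProjector:
    """Cached projector factory (Geometry is frozen, hence hashable)."""
    return DistanceDrivenProjector(g)


def _check_geometry(obj, g: Geometry | None) -> Geometry:
    if g is None:
        return obj.geometry
    if g != obj.geometry:
        raise ValueError("geometry does not match the container's geometry")
    return g


def forward_project(x: Volume, g: Geometry | None = None) -> ProjectionStack:
    """Apply ``M``: project a volume into the stack of line integrals."""
    g = _check_geometry(x, g)
    return ProjectionStack(get_projector(g).forward(x.values), g)


def back_project(b: ProjectionStack, g: Geometry | None = None) -> Volume:
    """Apply ``M^T``: smear projections back into the volume.

    Uses exactly the same footprint weights as :func:`forward_project`, so
    this is the true adjoint rather than an independent discretization.
    """
    g = _check_geometry(b, g)
    return Volume(get_projector(g).adjoint(b.values), g)


def build_dense_matrix(g: Geometry, guard: int = DENSE_MATRIX_GUARD) -> np.ndarray:
    """Materialize ``M`` as a dense ``(Nd, Nv)`` array (test oracle).

    Row ``i = t * Np + r * cols + c`` corresponds to view ``t`` and detector
    pixel ``(r, c)``; column ``j`` corresponds to ``Volume.values.ravel()``
    order (C order over ``(ix, iy, k)``).  Entries reproduce the matrix-free
    operators up to summation-order rounding.
    """
    nd, nv = g.n_data, g.n_voxels
    if nd * nv > guard:
        raise ValueError(
            f"system matrix with {nd}x{nv} = {nd * nv} entries exceeds the "
            f"materialization guard ({guard})"
        )
    proj = get_projector(g)
    nx, ny, nz = g.grid_shape
    np_pix = g.n_detector_pixels
    m = np.zeros((nd, nv))
    for t in range(g.n_angles):
        rows = slice(t * np_pix, (t + 1) * np_pix)
        for k in range(nz):
            # W[r, c, ix, iy] for slice k
            w = np.einsum(
                "rj,ci,rc->rcij", proj.a_v[t][k], proj.a_u[t][k], proj.obliq[t]
            ) * proj.scale
            cols = np.arange(nx * ny) * nz + k  # ravel index of (ix, iy, k)
            m[rows.start : rows.stop, cols] = w.reshape(np_pix, nx * ny)
    return m
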