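"""Total-variation regularization on voxel grids.

The discrete gradient uses forward differences with periodic boundary
conditions along each axis, taken on voxel indices (voxel anisotropy is not
divided out; it enters the model only through the projector, which fixes the
scale of the regularization weight ``lambda``).  TV is the sum over voxels
of the Euclidean norm of the three-component gradient; ``TV_beta`` replaces
that norm with ``sqrt(||grad||^2 + beta^2)`` so the functional is
differentiable everywhere.

``apply_diffusion_operator`` applies the symmetric weighted Laplacian
``L(x)`` (the lagged-diffusivity linearization) whose per-edge diffusivity
``1 / sqrt(||grad x_j||^2 + beta^2)`` is frozen at a given state, so that
``L(x) x`` equals the exact ``TV_beta`` gradient at ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projector import Volume

__all__ = [
    "GradientField",
    "gradient_field",
    "tv",
    "tv_beta",
    "tv_beta_gradient",
    "apply_diffusion_operator",
]


@dataclass
class GradientField:
    """Forward-difference gradient components, each shaped like the volume."""

    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray

    def norm_squared(self) -> np.ndarray:
        return self.dx**2 + self.dy**2 + self.dz**2


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, Volume) else np.asarray(x, dtype=np.float64)


def _like(x, values: np.ndarray):
    return Volume(values, x.geometry) if isinstance(x, Volume) else values


def _forward_diff(v: np.ndarray, axis: int) -> np.ndarray:
    return np.roll(v, -1, axis=axis) - v


def _forward_diff_adjoint(q: np.ndarray, axis: int) -> np.ndarray:
    # adjoint of the periodic forward difference: <Dv, q> = <v, D^T q>
    return np.roll(q, 1, axis=axis) - q


def gradient_field(x) -> GradientField:
    """Forward differences along each axis with periodic wrap-around."""
    v = _values(x)
    return GradientField(*(_forward_diff(v, a) for a in range(3)))


def tv(x) -> float:
    """Total variation: sum over voxels of the gradient's Euclidean norm."""
    return float(np.sum(np.sqrt(gradient_field(x).norm_squared())))


def tv_beta(x, beta: float) -> float:
    """Smoothed total variation, ``sum_j sqrt(||grad x_j||^2 + beta^2)``."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return float(np.sum(np.sqrt(gradient_field(x).norm_squared() + beta**2)))


def tv_beta_gradient(x, beta: float):
    """Exact gradient of :func:`tv_beta` with respect to every voxel.

    Computed as the negative weighted divergence ``D^T (D x / phi)`` with
    ``phi_j = sqrt(||grad x_j||^2 + beta^2)``, using the periodic adjoint of
    the same forward-difference operator as :func:`gradient_field`.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0 (TV is not differentiable at beta = 0)")
    v = _values(x)
    grads = [_forward_diff(v, a) for a in range(3)]
    phi = np.sqrt(sum(d**2 for d in grads) + beta**2)
    out = np.zeros_like(v)
    for a, d in enumerate(grads):
        out += _forward_diff_adjoint(d / phi, a)
    return _like(x, out)


def apply_diffusion_operator(x_state, v, beta: float):
    """Apply the lagged-diffusivity operator ``L(x_state)`` to ``v``.

    ``L`` is the symmetric positive-semidefinite weighted Laplacian with
    per-voxel edge weight ``1 / phi_j`` frozen at ``x_state``; by
    construction ``L(x) x == tv_beta_gradient(x, beta)``.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    xs = _values(x_state)
    vv = _values(v)
    if xs.shape != vv.shape:
        raise ValueError("x_state and v must have the same shape")
    phi = np.sqrt(gradient_field(xs).norm_squared() + beta**2)
    out = np.zeros_like(vv)
    for a in range(3):
        out += _forward_diff_adjoint(_forward_diff(vv, a) / phi, a)
    return _like(v, out)
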