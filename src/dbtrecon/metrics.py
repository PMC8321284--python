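"""Image-quality metrics for reconstructed DBT volumes.

The figures of merit target the two object classes radiologists look for:

* masses (larger, low contrast) are scored with a contrast-to-noise ratio
  built from region means and standard deviations;
* microcalcifications (sub-millimetre, high contrast) are scored with a
  peak-based CNR, a Gaussian-fit full width at half maximum of the in-plane
  profile (whose product with the pixel pitch approximates the physical
  speck width), and the artifact spread function (ASF) that quantifies how
  much of the object leaks into out-of-focus slices along Z.

Regions of interest are circles in a transverse slice: the set of voxels
whose in-plane center distance to the ROI center is at most ``diameter / 2``
(Euclidean, voxel units).  Standard deviations are population (1/N) ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .projector import Volume

__all__ = [
    "ROISpec",
    "MetricsReport",
    "FitError",
    "circular_roi_values",
    "cnr_mass",
    "cnr_microcalc",
    "plane_profile",
    "fwhm_from_profile",
    "asf_curve",
    "GAUSSIAN_FWHM_FACTOR",
]

#: FWHM of a unit-standard-deviation Gaussian: 2 sqrt(2 ln 2)
GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class FitError(RuntimeError):
    """Profile fit failed (flat or otherwise unmeasurable profile)."""


@dataclass(frozen=True)
class ROISpec:
    """A circular region on one transverse slice.

    ``kind`` is one of ``"mass"``, ``"microcalc"``, ``"background"``;
    ``center`` is the in-plane voxel index pair ``(ix, iy)``;
    ``slice_index`` the Z index of the in-focus plane.
    """

    kind: str
    center: tuple[int, int]
    diameter_vox: float
    slice_index: int

    def __post_init__(self):
        if self.kind not in ("mass", "microcalc", "background"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.diameter_vox < 1:
            raise ValueError("diameter_vox must be >= 1")


@dataclass
class MetricsReport:
    """Collected metric values for one analyzed object."""

    cnr: float | None = None
    fwhm: float | None = None
    width_um: float | None = None
    asf: np.ndarray | None = None
    profile: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cnr": self.cnr,
            "fwhm": self.fwhm,
            "width_um": self.width_um,
            "asf": None if self.asf is None else [float(v) for v in self.asf],
            "profile": None if self.profile is None else [float(v) for v in self.profile],
            **self.extras,
        }


def _vals(vol) -> np.ndarray:
    return vol.values if isinstance(vol, Volume) else np.asarray(vol, dtype=np.float64)


def _circle_mask(shape_xy, center, diameter) -> np.ndarray:
    ix, iy = center
    gx, gy = np.meshgrid(np.arange(shape_xy[0]), np.arange(shape_xy[1]), indexing="ij")
    return (gx - ix) ** 2 + (gy - iy) ** 2 <= (diameter / 2.0) ** 2


def circular_roi_values(vol, roi: ROISpec, slice_index: int | None = None) -> np.ndarray:
    """Voxel values inside a circular ROI on one slice."""
    v = _vals(vol)
    z = roi.slice_index if slice_index is None else slice_index
    if not 0 <= z < v.shape[2]:
        raise ValueError("ROI slice outside the volume")
    mask = _circle_mask(v.shape[:2], roi.center, roi.diameter_vox)
    r = roi.diameter_vox / 2.0
    if (
        roi.center[0] - r < -0.5
        or roi.center[1] - r < -0.5
        or roi.center[0] + r > v.shape[0] - 0.5
        or roi.center[1] + r > v.shape[1] - 0.5
    ):
        raise ValueError("ROI extends outside the volume")
    return v[:, :, z][mask]


def cnr_mass(vol, roi_ms: ROISpec, roi_bg: ROISpec, denominator: str = "difference") -> float:
    """Contrast-to-noise ratio of a mass.

    Default form: ``(mean(MS) - mean(BG)) / (std(MS) - std(BG))`` with
    population standard deviations.  The difference in the denominator can
    vanish; that case raises.  ``denominator="background"`` switches to the
    common ``std(BG)``-only variant without changing the default.
    """
    ms = circular_roi_values(vol, roi_ms)
    bg = circular_roi_values(vol, roi_bg)
    num = float(np.mean(ms) - np.mean(bg))
    if denominator == "difference":
        den = float(np.std(ms) - np.std(bg))
        if den == 0.0:
            raise ZeroDivisionError("std(MS) == std(BG): CNR undefined")
    elif denominator == "background":
        den = float(np.std(bg))
        if den == 0.0:
            raise ZeroDivisionError("std(BG) == 0: CNR undefined")
    else:
        raise ValueError("denominator must be 'difference' or 'background'")
    return num / den


def cnr_microcalc(vol, roi_mc: ROISpec, roi_bg: ROISpec) -> float:
    """Peak-based CNR of a microcalcification: ``(max(MC) - mean(BG)) / std(BG)``."""
    mc = circular_roi_values(vol, roi_mc)
    bg = circular_roi_values(vol, roi_bg)
    sd = float(np.std(bg))
    if sd == 0.0:
        raise ZeroDivisionError("std(BG) == 0: CNR undefined")
    return float((np.max(mc) - np.mean(bg)) / sd)


def plane_profile(vol, slice_index: int, x_index: int, y_range=None) -> np.ndarray:
    """Intensity trace along the Y axis through ``x_index`` on one slice."""
    v = _vals(vol)
    if not 0 <= slice_index < v.shape[2]:
        raise ValueError("slice_index out of bounds")
    if not 0 <= x_index < v.shape[0]:
        raise ValueError("x_index out of bounds")
    line = v[x_index, :, slice_index]
    if y_range is not None:
        y0, y1 = y_range
        if y0 < 0 or y1 > v.shape[1] or y0 >= y1:
            raise ValueError("y_range out of bounds")
        line = line[y0:y1]
    return line.copy()


def _gaussian(y, a, h, c, d):
    return a + h * np.exp(-((y - c) ** 2) / (2.0 * d**2))


def fwhm_from_profile(profile, delta_y_mm: float) -> tuple[float, int]:
    """Gaussian-fit full width at half maximum of a plane profile.

    Fits ``a + h exp(-(y - c)^2 / (2 d^2))`` by nonlinear least squares with
    moment-based initialization and returns ``(fwhm_samples, width_um)``
    where ``fwhm = 2 sqrt(2 ln 2) d`` and the physical width is
    ``fwhm * delta_y`` rounded to the nearest micrometre.  A flat or
    unfittable profile raises :class:`FitError`, mirroring objects that are
    not discernible from the background.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.size < 5:
        raise FitError("profile too short to fit")
    a0 = float(np.min(p))
    h0 = float(np.max(p) - a0)
    if h0 <= 0 or not np.isfinite(h0):
        raise FitError("flat profile: no discernible peak")
    y = np.arange(p.size, dtype=np.float64)
    c0 = float(np.argmax(p))
    # initialize the width from the half-maximum crossing count, which is
    # robust to baseline noise (a central second moment is not)
    n_half = int(np.sum(p > a0 + 0.5 * h0))
    d0 = max(n_half / GAUSSIAN_FWHM_FACTOR, 0.5)
    try:
        popt, _ = curve_fit(_gaussian, y, p, p0=(a0, h0, c0, d0), maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Gaussian fit failed: {exc}") from exc
    a, h, c, d = popt
    d = abs(float(d))
    if not np.isfinite(d) or d == 0.0 or h <= 0 or d > p.size:
        raise FitError("degenerate Gaussian fit")
    fwhm = GAUSSIAN_FWHM_FACTOR * d
    width_um = int(round(fwhm * delta_y_mm * 1000.0))
    return float(fwhm), width_um


def asf_curve(vol, mc_center, bg_center, z_focus: int, diameter_vox: float = 3.0) -> np.ndarray:
    """Artifact spread function along Z for a small object.

    ``ASF(z) = |mu_MC(z) - mu_BG(z)| / |mu_MC(z_focus) - mu_BG(z_focus)|``
    with means over circular regions (default three-pixel diameter) at the
    object and background in-plane positions, one value per slice.  By
    construction ``ASF(z_focus) = 1``.
    """
    v = _vals(vol)
    nz = v.shape[2]
    if not 0 <= z_focus < nz:
        raise ValueError("z_focus out of bounds")
    mc_mask = _circle_mask(v.shape[:2], mc_center, diameter_vox)
    bg_mask = _circle_mask(v.shape[:2], bg_center, diameter_vox)
    diffs = np.array(
        [abs(float(np.mean(v[:, :, z][mc_mask]) - np.mean(v[:, :, z][bg_mask]))) for z in range(nz)]
    )
    den = diffs[z_focus]
    if den == 0.0:
        raise ZeroDivisionError("object absent at the in-focus slice: ASF undefined")
    return diffs / den
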