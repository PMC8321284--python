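"""Volume/projection I/O, configuration parsing and run manifests.

Volumes and projection stacks travel as multi-page 32-bit float TIFF files
(one page per slice or per view) with a JSON sidecar carrying the geometry;
solver and pipeline configurations are YAML documents mirroring the
dataclass field names.  Every pipeline run writes a manifest (command,
config snapshot, seeds, paths, package version, timestamp) sufficient to
re-run it bit-identically on the same platform.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import Geometry
from .phantom import (
    BackgroundSpec,
    MassSpec,
    MCClusterSpec,
    PhantomSpec,
    SimulationSpec,
)
from .solvers import SolverConfig, SolverTrace

__all__ = [
    "ConfigError",
    "RunManifest",
    "sidecar_path",
    "save_volume",
    "load_volume",
    "save_projections",
    "load_projections",
    "save_trace",
    "geometry_from_config",
    "phantom_spec_from_dict",
    "solver_config_from_dict",
    "load_yaml",
]


class ConfigError(ValueError):
    """Configuration schema violation; the message names the offending field."""


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".geometry.json")


def _write_stack(path, pages: np.ndarray, g: Geometry) -> None:
    tifffile.imwrite(path, pages.astype(np.float32))
    g.to_json(sidecar_path(path))


def _read_stack(path, geometry: Geometry | None):
    pages = np.asarray(tifffile.imread(path), dtype=np.float32)
    if geometry is None:
        side = sidecar_path(path)
        if not side.exists():
            raise ConfigError(f"geometry: sidecar {side} not found and no geometry given")
        geometry = Geometry.from_json(side)
    return pages, geometry


def save_volume(vol, path) -> None:
    """Write a volume as a multi-page float32 TIFF (one page per Z slice)."""
    from .projector import Volume

    assert isinstance(vol, Volume)
    _write_stack(path, np.moveaxis(vol.values, 2, 0), vol.geometry)


def load_volume(path, geometry: Geometry | None = None):
    from .projector import Volume

    pages, geometry = _read_stack(path, geometry)
    if pages.ndim == 2:
        pages = pages[None]
    return Volume(np.moveaxis(pages.astype(np.float64), 0, 2), geometry)


def save_projections(proj, path) -> None:
    """Write a projection stack as a multi-page float32 TIFF (one page per view)."""
    from .projector import ProjectionStack

    assert isinstance(proj, ProjectionStack)
    _write_stack(path, proj.values, proj.geometry)


def load_projections(path, geometry: Geometry | None = None):
    from .projector import ProjectionStack

    pages, geometry = _read_stack(path, geometry)
    if pages.ndim == 2:
        pages = pages[None]
    return ProjectionStack(pages.astype(np.float64), geometry)


def save_trace(trace: SolverTrace, path) -> None:
    trace.to_dataframe().to_csv(path, index=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top-level YAML document must be a mapping")
    return doc


def geometry_from_config(node, base_dir: Path | None = None) -> Geometry:
    """Resolve a geometry config node: preset name, file reference or inline."""
    from .geometry import default_geometry

    if node is None:
        raise ConfigError("geometry: field is required")
    if isinstance(node, str):
        return default_geometry(node)
    if not isinstance(node, dict):
        raise ConfigError("geometry: must be a preset name, {preset}, {file} or inline fields")
    if "preset" in node:
        return default_geometry(node["preset"])
    if "file" in node:
        p = Path(node["file"])
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        return Geometry.from_json(p)
    try:
        return Geometry.from_dict(node)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"geometry: {exc}") from exc


def phantom_spec_from_dict(node: dict) -> PhantomSpec:
    if not isinstance(node, dict):
        raise ConfigError("phantom: must be a mapping")
    try:
        bg = BackgroundSpec(**node.get("background", {}))
        masses = tuple(
            MassSpec(center_mm=tuple(m["center_mm"]), diameter_mm=m["diameter_mm"],
                     mu=m.get("mu", 0.09))
            for m in node.get("masses", [])
        )
        clusters = tuple(
            MCClusterSpec(
                center_mm=tuple(c["center_mm"]),
                n_specks=c.get("n_specks", 6),
                speck_diameter_um=c.get("speck_diameter_um", 230.0),
                spread_mm=c.get("spread_mm", 1.0),
                mu=c.get("mu", 0.4),
                seed=c.get("seed", 0),
            )
            for c in node.get("mc_clusters", [])
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"phantom: {exc}") from exc
    return PhantomSpec(background=bg, masses=masses, mc_clusters=clusters)


def simulation_spec_from_dict(node: dict, seed: int | None = None) -> SimulationSpec:
    node = dict(node or {})
    if seed is not None:
        node.setdefault("seed", seed)
    try:
        return SimulationSpec(
            photon_count_p0=float(node.get("p0", node.get("photon_count_p0", 1e5))),
            poisson=bool(node.get("poisson", True)),
            seed=int(node.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulation: {exc}") from exc


def solver_config_from_dict(node: dict | None) -> SolverConfig:
    node = dict(node or {})
    if "lambda" in node:
        node["lambda_"] = node.pop("lambda")
    known = {f.name for f in dataclasses.fields(SolverConfig)}
    unknown = set(node) - known
    if unknown:
        raise ConfigError(f"solver_config: unknown fields {sorted(unknown)}")
    try:
        return SolverConfig(**node)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"solver_config: {exc}") from exc


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written next to every command's outputs."""

    command: str
    config: dict
    seeds: dict
    inputs: dict
    outputs: dict
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
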