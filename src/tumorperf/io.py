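"""File interfaces: VTK snapshots, CSV tables, YAML configs, run manifests.

Snapshots are written as legacy-ASCII VTK structured points (cell data on
the uniform grid), which every VTK-compatible viewer reads; tabular outputs
are plain CSV.  The writer is deliberately minimal -- structured uniform
grids need nothing more.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry as geo
from .constitutive import InletWaveform, PhaseSpec
from .pipeline import ExperimentConfig, ProbeSeries

__all__ = [
    "write_vtk",
    "load_phases",
    "save_phases",
    "write_circles_csv",
    "write_probe_csv",
    "read_probe_csv",
    "write_residual_log",
    "load_config",
    "save_config",
    "RunManifest",
]


def write_vtk(path, mask: geo.GridMask, cell_data: dict, title: str = "tumorperf"):
    """Write cell-centered fields on the uniform grid as legacy ASCII VTK."""
    path = Path(path)
    h = mask.cell_size
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {mask.nx + 1} {mask.ny + 1} 1",
        f"ORIGIN {mask.origin[0]} {mask.origin[1]} 0.0",
        f"SPACING {h} {h} {h}",
        f"CELL_DATA {mask.nx * mask.ny}",
    ]
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if arr.shape != (mask.nx, mask.ny):
            raise ValueError(f"field {name!r} shape {arr.shape} does not "
                             f"match grid ({mask.nx}, {mask.ny})")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell ordering: x fastest, then y
        lines.extend(" ".join(f"{v:.9g}" for v in arr[:, j])
                     for j in range(mask.ny))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_circles_csv(path, circles) -> Path:
    path = Path(path)
    pd.DataFrame(circles, columns=["cx_um", "cy_um", "r_um"]).to_csv(
        path, index=False, float_format="%.6f")
    return path


def write_probe_csv(path, probe: ProbeSeries) -> Path:
    path = Path(path)
    probe.to_frame().to_csv(path, index=False)
    return path


def read_probe_csv(path) -> ProbeSeries:
    return ProbeSeries.from_frame(pd.read_csv(path))


def write_residual_log(path, residual_log) -> Path:
    path = Path(path)
    pd.DataFrame(residual_log).to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# YAML configuration
# --------------------------------------------------------------------------

def save_config(path, cfg: ExperimentConfig) -> Path:
    d = dataclasses.asdict(cfg)
    if cfg.waveform is not None:
        d["waveform"] = dataclasses.asdict(cfg.waveform)
    path = Path(path)
    path.write_text(yaml.safe_dump(_plain(d), sort_keys=False))
    return path


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path) -> ExperimentConfig:
    """Load a master experiment config from YAML (missing keys -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "vessel" in kwargs and kwargs["vessel"] is not None:
        v = dict(kwargs["vessel"])
        if "fiber_obstacles" in v:
            v["fiber_obstacles"] = tuple(tuple(c) for c in v["fiber_obstacles"])
        kwargs["vessel"] = geo.VesselGeometryConfig(**v)
    if kwargs.get("waveform") is not None:
        w = dict(kwargs["waveform"])
        w["cos_coeffs"] = tuple(w.get("cos_coeffs", ()))
        w["sin_coeffs"] = tuple(w.get("sin_coeffs", ()))
        kwargs["waveform"] = InletWaveform(**w)
    for key in ("fiber_circles", "snapshot_times", "models"):
        if kwargs.get(key) is not None:
            kwargs[key] = tuple(
                tuple(x) if isinstance(x, (list, tuple)) else x
                for x in kwargs[key])
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(kwargs) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**kwargs)


def save_phases(path, phases) -> Path:
    """Write a phase property table (list of PhaseSpec) as YAML."""
    path = Path(path)
    path.write_text(yaml.safe_dump(
        [dataclasses.asdict(p) for p in phases], sort_keys=False))
    return path


def load_phases(path) -> list:
    """Read a phase property table (YAML list of PhaseSpec fields)."""
    raw = yaml.safe_load(Path(path).read_text()) or []
    return [PhaseSpec(**entry) for entry in raw]


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------

class RunManifest:
    """Records what a run produced: config hash, seed, stages, files."""

    def __init__(self, out_dir, provenance: dict):
        self.out_dir = Path(out_dir)
        self.data = {
            "provenance": provenance,
            "stages": [],
        }
        self._t0 = time.time()

    def add_stage(self, name: str, files, wall_clock_s: float | None = None):
        files = [str(Path(f).relative_to(self.out_dir)) for f in files]
        self.data["stages"].append({
            "name": name,
            "files": files,
            "wall_clock_s": (round(wall_clock_s, 3)
                             if wall_clock_s is not None else None),
        })

    def write(self) -> Path:
        self.data["total_wall_clock_s"] = round(time.time() - self._t0, 3)
        # invariant: every listed output exists at run end
        missing = [f for st in self.data["stages"] for f in st["files"]
                   if not (self.out_dir / f).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing files: {missing}")
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2))
        return path
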