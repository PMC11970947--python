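"""Packaged reference fixtures and deterministic fixture generation.

Three small plain-text fixtures ship with the package:

* ``reference_ratios.csv`` -- the reference (R+G):B leakiness ratios per model
  and flow time, consumed by the table-reproduction mode of the analysis
  stage;
* ``waveform_default.csv`` -- the default 5-harmonic pulsatile inlet
  coefficients (period 0.735 s);
* ``fiber_layout_default.csv`` -- the default biomimetic fiber layout for
  the 6 x 6 um tumor domain at packing fraction 0.27.

``make_fixtures`` regenerates these (plus analytic test fields) into a
directory, byte-identically for a fixed seed.
"""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .constitutive import InletWaveform

__all__ = [
    "load_reference_ratios",
    "load_default_waveform_coeffs",
    "load_default_fiber_layout",
    "load_waveform_csv",
    "make_fixtures",
    "analytic_half_field",
]

_DATA = resources.files("tumorperf") / "data"


def load_reference_ratios() -> pd.DataFrame:
    """Reference leakiness ratios (columns model, time, ratio)."""
    with resources.as_file(_DATA / "reference_ratios.csv") as p:
        return pd.read_csv(p)


def load_default_fiber_layout() -> list:
    """Packaged default fiber circle list [(cx, cy, r), ...] in um."""
    with resources.as_file(_DATA / "fiber_layout_default.csv") as p:
        df = pd.read_csv(p)
    return [tuple(row) for row in df[["cx_um", "cy_um", "r_um"]].to_numpy()]


def load_waveform_csv(path, period: float = 0.735,
                      mean_velocity: float = 3e-4) -> InletWaveform:
    """Build an InletWaveform from a (harmonic, cos_coeff, sin_coeff) CSV."""
    df = pd.read_csv(path).sort_values("harmonic")
    return InletWaveform(period, mean_velocity,
                         tuple(df["cos_coeff"]), tuple(df["sin_coeff"]))


def load_default_waveform_coeffs() -> pd.DataFrame:
    with resources.as_file(_DATA / "waveform_default.csv") as p:
        return pd.read_csv(p)


def analytic_half_field(n: int = 32):
    """Synthetic plasma-fraction field: 1 on the left half, 0 on the right.

    Returns (field, mask) on an obstacle-free square tumor grid; by
    construction the red and blue class areas are each exactly half of the
    fluid area (there is no green band).  Used to exercise the
    classification stage independently of the solver.
    """
    cfg = geometry.TumorGeometryConfig(
        tumor_width=4.0, tumor_height=4.0, fenestra_diameter=0.5,
        fiber_circles=())
    geo = geometry.build_tumor_geometry(cfg)
    mask = geometry.rasterize(geo, 4.0 / n)
    X = np.broadcast_to(mask.xc[:, None], (mask.nx, mask.ny))
    field = np.where(X < 2.0, 1.0, 0.0)
    return field, mask


def make_fixtures(kind: str, seed: int = 0, out_dir="fixtures") -> list:
    """Write deterministic fixture files; returns the created paths.

    kind in {'analytic_fields', 'reference_ratios', 'waveform', 'fiber_layout'}.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created = []
    if kind == "reference_ratios":
        p = out / "reference_ratios.csv"
        load_reference_ratios().to_csv(p, index=False)
        created.append(p)
    elif kind == "waveform":
        p = out / "waveform_default.csv"
        load_default_waveform_coeffs().to_csv(p, index=False)
        created.append(p)
    elif kind == "fiber_layout":
        circles = geometry.place_fibers(
            6.0, 6.0, 0.27, rng_seed=seed, r_min=0.4, r_max=0.7,
            min_gap=0.22, exclusions=((3.0, 6.0, 0.9),))
        p = out / f"fiber_layout_seed{seed}.csv"
        pd.DataFrame(circles, columns=["cx_um", "cy_um", "r_um"]).to_csv(
            p, index=False, float_format="%.6f")
        created.append(p)
    elif kind == "analytic_fields":
        field, mask = analytic_half_field()
        p = out / "half_field.csv"
        np.savetxt(p, field, delimiter=",", fmt="%.1f")
        created.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return created
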