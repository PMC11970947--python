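"""Percolation quantification: color-zone areas, power-law exponents, slopes.

The plasma volume-fraction maps of the tumor stage are summarised the way a
rainbow-colormap rendering reads: cells dominated by air are *blue*, partially
wetted cells *green*, plasma-dominated cells *red*.  The leakiness measure is
the area ratio (R+G):B.  Across fenestra diameters the ratios obey a
power-law idealization

    A_{R+G}(D_i) / A_{R+G}(D_k) = (D_i / D_k)^x_n

whose exponent ``x_n = ln(area ratio) / ln(diameter ratio)`` is tabulated per
flow time; the time evolution of the exponent ratio x/y is summarised by
finite-difference slopes, and the decay of those slopes is read against the
Fick-law relation R = D A dP / d.

Reported table values are rounded half-up to 2 decimal places; raw values are
retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .geometry import CellClass, GridMask

__all__ = [
    "ColorClassification",
    "PowerLawResult",
    "FickInputs",
    "classify_field",
    "area_ratio",
    "power_exponent",
    "exponent_table",
    "slope_between",
    "fick_rate",
    "penetration_distance",
    "round2",
    "MODEL_DIAMETERS",
]

#: Fenestra diameter (um) per model label.
MODEL_DIAMETERS = {1: 0.1, 2: 0.3, 3: 0.5}


def round2(x: float) -> float:
    """Round half-up to 2 decimal places (table-reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ColorClassification:
    """Per-class areas of a plasma volume-fraction field (um^2).

    blue: Psi_plasma < theta1 (air dominated); green: theta1 <= Psi < theta2;
    red: Psi >= theta2.  Areas count fluid cells of the tumor region only
    (fiber solids never; the fenestra channel excluded by default).
    """

    theta1: float
    theta2: float
    cell_size: float
    area_red: float
    area_green: float
    area_blue: float

    @property
    def area_red_green(self) -> float:
        return self.area_red + self.area_green

    @property
    def total_area(self) -> float:
        return self.area_red + self.area_green + self.area_blue


def classify_field(
    plasma_fraction: np.ndarray,
    mask: GridMask,
    theta1: float = 1.0 / 3.0,
    theta2: float = 2.0 / 3.0,
    include_fenestra: bool = False,
) -> ColorClassification:
    """Classify a plasma-fraction field into red/green/blue zone areas.

    Cells are classified by thresholding the cell value; class areas are
    cell counts times the cell area, so they conserve the fluid area exactly
    for any threshold pair.
    """
    if not (0 <= theta1 < theta2 <= 1):
        raise ValueError("thresholds must satisfy 0 <= theta1 < theta2 <= 1")
    cls = mask.cell_class
    sel = cls == CellClass.FLUID
    if include_fenestra:
        sel |= cls == CellClass.FENESTRA_INTERFACE
    vals = np.asarray(plasma_fraction)[sel]
    if not np.all(np.isfinite(vals)):
        raise ValueError("plasma-fraction field contains non-finite values")
    a = mask.cell_size ** 2
    red = int(np.count_nonzero(vals >= theta2))
    green = int(np.count_nonzero((vals >= theta1) & (vals < theta2)))
    blue = int(np.count_nonzero(vals < theta1))
    return ColorClassification(theta1, theta2, mask.cell_size,
                               red * a, green * a, blue * a)


def area_ratio(classification: ColorClassification) -> float:
    """(R+G):B leakiness ratio; +inf when no blue area remains.

    An infinite ratio flags that plasma has passed its percolation limit and
    fully displaced the air phase.
    """
    if classification.area_blue <= 0:
        return math.inf
    return classification.area_red_green / classification.area_blue


def power_exponent(area_i: float, area_k: float, d_i: float, d_k: float) -> float:
    """Power-law exponent ``x_n = ln(area_i/area_k) / ln(d_i/d_k)``.

    ``area_i``/``area_k`` may be the raw percolated areas or the (R+G):B
    ratios -- the exponent only depends on their ratio, and dividing both
    areas by a common blue area cancels.
    """
    if d_i <= 0 or d_k <= 0 or d_i == d_k:
        raise ValueError("diameters must be positive and distinct")
    if area_i <= 0 or area_k <= 0:
        raise ValueError(
            f"percolated areas must be positive (got {area_i}, {area_k})"
        )
    return math.log(area_i / area_k) / math.log(d_i / d_k)


@dataclass
class PowerLawResult:
    """Exponent table across flow times (x: 0.3/0.1 pair, y: 0.5/0.1 pair).

    ``table`` columns: time, x, y, x_over_y at full precision; ``rounded``
    carries the 2-d.p. reporting values; ``slopes`` the finite-difference
    slopes of the *reported* (rounded) x/y against time, matching how the
    printed table is read.
    """

    table: pd.DataFrame
    rounded: pd.DataFrame
    slopes: pd.DataFrame


def exponent_table(ratios: pd.DataFrame) -> PowerLawResult:
    """Fit the exponent table from per-model leakiness ratios.

    Parameters
    ----------
    ratios : DataFrame with columns ``model`` (1, 2, 3), ``time`` (s) and
        ``ratio`` ((R+G):B), one row per model and time.
    """
    need = {"model", "time", "ratio"}
    if not need.issubset(ratios.columns):
        raise ValueError(f"ratios table needs columns {sorted(need)}")
    piv = ratios.pivot(index="time", columns="model", values="ratio").sort_index()
    for m in (1, 2, 3):
        if m not in piv.columns or piv[m].isna().any():
            raise ValueError(f"missing ratio entries for model {m}")
    rows = []
    for t, row in piv.iterrows():
        x = power_exponent(row[2], row[1], MODEL_DIAMETERS[2], MODEL_DIAMETERS[1])
        y = power_exponent(row[3], row[1], MODEL_DIAMETERS[3], MODEL_DIAMETERS[1])
        xy = x / y if y != 0 else math.nan
        rows.append((float(t), x, y, xy))
    table = pd.DataFrame(rows, columns=["time", "x", "y", "x_over_y"])
    rounded = table.copy()
    for col in ("x", "y", "x_over_y"):
        rounded[col] = rounded[col].map(round2)
    srows = []
    for a, b in zip(rounded.itertuples(), list(rounded.itertuples())[1:]):
        srows.append((a.time, b.time,
                      slope_between((a.time, a.x_over_y), (b.time, b.x_over_y))))
    slopes = pd.DataFrame(srows, columns=["t1", "t2", "slope"])
    return PowerLawResult(table=table, rounded=rounded, slopes=slopes)


def slope_between(p1: tuple, p2: tuple) -> float:
    """Finite-difference slope (v2 - v1)/(t2 - t1) between two (time, value) points."""
    (t1, v1), (t2, v2) = p1, p2
    if t1 == t2:
        raise ValueError("slope undefined for equal times")
    return (v2 - v1) / (t2 - t1)


@dataclass(frozen=True)
class FickInputs:
    """Inputs of the Fick-law rate relation R = D_f A dP / d.

    ``diffusion_coefficient`` (m^2/s) is the transport coefficient (distinct
    from the fenestra diameter), ``coverage_area`` (m^2) the diffusion
    coverage, ``pressure_difference`` (Pa) the driving difference and
    ``distance`` (m) the diffusion distance.
    """

    diffusion_coefficient: float
    coverage_area: float
    pressure_difference: float
    distance: float


def fick_rate(diffusion_coefficient: float, coverage_area: float,
              pressure_difference: float, distance: float) -> float:
    """Fick-law diffusion rate ``R = D_f A dP / d`` (inverse in distance)."""
    if distance <= 0:
        raise ValueError("diffusion distance must be positive")
    return diffusion_coefficient * coverage_area * pressure_difference / distance


def penetration_distance(
    plasma_fraction: np.ndarray,
    mask: GridMask,
    fenestra_exit: tuple,
    theta1: float = 1.0 / 3.0,
) -> tuple:
    """Max and mean Euclidean distance (um) of wetted cells from the fenestra exit.

    A cell counts as wetted (non-blue) when its plasma fraction reaches
    ``theta1``.  Returns (0.0, 0.0) when no plasma is present.
    """
    cls = mask.cell_class
    sel = (cls == CellClass.FLUID) & (np.asarray(plasma_fraction) >= theta1)
    if not np.any(sel):
        return (0.0, 0.0)
    X, Y = np.meshgrid(mask.xc, mask.yc, indexing="ij")
    d = np.hypot(X[sel] - fenestra_exit[0], Y[sel] - fenestra_exit[1])
    return (float(d.max()), float(d.mean()))
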