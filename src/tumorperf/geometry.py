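"""Biomimetic two-segment domain geometry and Cartesian rasterization.

The tumor microenvironment is modelled as two separate 2D segments:

* a straight blood vessel with a rounded depression carved into its
  tumor-facing (bottom) wall -- the depression marks the entry location to
  the tumor extracellular space;
* a rectangular tumor extracellular domain reached through a narrow
  fenestra channel in its top boundary and packed with circular fiber
  cross-sections at a prescribed packing fraction.

The two segments are deliberately never meshed together: keeping them
separate restricts micron-scale blood cells from entering the sub-micron
fenestra, and the stages are coupled only through probed plasma
pressure/velocity (see :mod:`tumorperf.pipeline`).

Lengths in this module are micrometres; the solver converts to SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, box

__all__ = [
    "CellClass",
    "VesselGeometryConfig",
    "TumorGeometryConfig",
    "DomainGeometry",
    "GridMask",
    "GeometryConfigError",
    "build_vessel_geometry",
    "build_tumor_geometry",
    "place_fibers",
    "packing_fraction",
    "rasterize",
]

MAX_FENESTRA_DIAMETER = 0.5  # um, largest modelled fenestra


class GeometryConfigError(ValueError):
    """Raised when a geometry configuration violates its invariants."""


class CellClass(IntEnum):
    FLUID = 0
    FIBER_SOLID = 1
    WALL = 2
    PRESSURE_INLET = 3
    PRESSURE_OUTLET = 4
    FENESTRA_INTERFACE = 5


@dataclass(frozen=True)
class VesselGeometryConfig:
    """Blood-vessel segment: straight channel + rounded wall depression.

    The depression (default depth 2.6 um, diameter 5.2 um) must remain much
    larger than the fenestra it hosts: diameter > 10x the largest fenestra
    diameter (0.5 um) and depth > 8x the fenestra streamwise length (0.3 um).
    A zero depth degenerates to a plain straight channel.
    """

    vessel_length: float = 30.0  # um
    vessel_height: float = 30.0  # um
    depression_depth: float = 2.6  # um
    depression_diameter: float = 5.2  # um
    depression_center_x: float = 15.0  # um
    fiber_obstacles: tuple = ()  # ((cx, cy, r), ...) inside the channel

    def validate(self):
        if self.vessel_length <= 0 or self.vessel_height <= 0:
            raise GeometryConfigError("vessel dimensions must be positive")
        if self.depression_depth < 0:
            raise GeometryConfigError("depression depth must be >= 0")
        if self.depression_depth > 0:
            if self.depression_diameter < 10 * MAX_FENESTRA_DIAMETER:
                raise GeometryConfigError(
                    f"depression diameter {self.depression_diameter} um must be "
                    f">= {10 * MAX_FENESTRA_DIAMETER} um (10x max fenestra diameter)"
                )
            if self.depression_depth < 8 * 0.3:
                raise GeometryConfigError(
                    f"depression depth {self.depression_depth} um must be >= 2.4 um "
                    "(8x fenestra streamwise length)"
                )
            if self.depression_depth > self.vessel_height:
                raise GeometryConfigError(
                    "depression deeper than the vessel height"
                )
            half = self.depression_diameter / 2
            if not (half <= self.depression_center_x <= self.vessel_length - half):
                raise GeometryConfigError("depression does not fit in the vessel")


@dataclass(frozen=True)
class TumorGeometryConfig:
    """Tumor extracellular segment: rectangle + fenestra channel + fibers.

    ``fenestra_diameter`` is the channel width (0.1, 0.3 or 0.5 um for
    Models 1-3); the streamwise channel length is fixed at 0.3 um.  The
    bottom edge carries the outlet sink segment.
    """

    tumor_width: float = 6.0  # um
    tumor_height: float = 6.0  # um
    fenestra_diameter: float = 0.5  # um
    fenestra_length: float = 0.3  # um
    fenestra_center_x: float | None = None  # default: centered
    fiber_circles: tuple = ()  # ((cx, cy, r), ...)
    outlet_segment: tuple | None = None  # (x_start, x_end) on y = 0
    depression_diameter: float = 5.2  # um, of the host depression (validation)

    def validate(self):
        if self.tumor_width <= 0 or self.tumor_height <= 0:
            raise GeometryConfigError("tumor dimensions must be positive")
        if not (0 < self.fenestra_diameter < self.depression_diameter):
            raise GeometryConfigError(
                "fenestra diameter must lie in (0, depression diameter)"
            )
        if self.fenestra_length <= 0:
            raise GeometryConfigError("fenestra length must be positive")
        cx = self.center_x
        if not (self.fenestra_diameter / 2 <= cx
                <= self.tumor_width - self.fenestra_diameter / 2):
            raise GeometryConfigError("fenestra does not fit on the top edge")
        W, H = self.tumor_width, self.tumor_height
        for (fx, fy, r) in self.fiber_circles:
            if r <= 0:
                raise GeometryConfigError("fiber radius must be positive")
            if not (0 <= fx <= W and 0 <= fy <= H):
                raise GeometryConfigError(
                    f"fiber circle at ({fx}, {fy}) lies outside the tumor domain"
                )
            # the channel mouth region must stay clear so flow can enter
            if (abs(fx - cx) < self.fenestra_diameter / 2 + r
                    and fy + r > H):
                raise GeometryConfigError(
                    f"fiber circle at ({fx}, {fy}) overlaps the fenestra channel"
                )

    @property
    def center_x(self) -> float:
        return (self.tumor_width / 2 if self.fenestra_center_x is None
                else self.fenestra_center_x)


@dataclass
class DomainGeometry:
    """Analytic geometry of one segment, queryable at arbitrary points."""

    kind: str  # 'vessel' | 'tumor'
    extent: tuple  # (x0, x1, y0, y1) um covered by the computational grid
    circles: tuple  # solid fiber circles ((cx, cy, r), ...)
    vessel: VesselGeometryConfig | None = None
    tumor: TumorGeometryConfig | None = None
    tangent_continuous: bool | None = None  # depression arc vs wall

    # -- point classification (vectorised) -----------------------------------
    def in_circle(self, x, y):
        hit = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        for (cx, cy, r) in self.circles:
            hit |= (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2
        return hit

    def in_fenestra(self, x, y):
        if self.kind != "tumor":
            return np.zeros(np.broadcast(x, y).shape, dtype=bool)
        cfg = self.tumor
        cx = cfg.center_x
        return ((np.abs(x - cx) <= cfg.fenestra_diameter / 2)
                & (y > cfg.tumor_height)
                & (y <= cfg.tumor_height + cfg.fenestra_length))

    def is_fluid(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "vessel":
            cfg = self.vessel
            base = ((x >= 0) & (x <= cfg.vessel_length)
                    & (y >= 0) & (y <= cfg.vessel_height))
            if cfg.depression_depth > 0:
                c = cfg.depression_diameter / 2
                d = cfg.depression_depth
                R = (c * c + d * d) / (2 * d)
                y0 = R - d
                base |= ((y < 0)
                         & ((x - cfg.depression_center_x) ** 2
                            + (y - y0) ** 2 <= R * R))
        else:
            cfg = self.tumor
            base = ((x >= 0) & (x <= cfg.tumor_width)
                    & (y >= 0) & (y <= cfg.tumor_height))
            base |= self.in_fenestra(x, y)
        return base & ~self.in_circle(x, y)

    @property
    def tumor_region(self) -> tuple | None:
        """(x0, x1, y0, y1) of the rectangular tumor region, if any."""
        if self.kind != "tumor":
            return None
        return (0.0, self.tumor.tumor_width, 0.0, self.tumor.tumor_height)


@dataclass
class GridMask:
    """Uniform Cartesian rasterization with per-cell classification.

    Cell (i, j) covers the half-open square
    ``[x0 + i*h, x0 + (i+1)*h) x [y0 + j*h, y0 + (j+1)*h)`` (0-based, h in
    um); a one-cell padding ring carries wall and inlet/outlet cells so every
    inlet/outlet cell lies on the grid boundary.
    """

    cell_size: float  # um
    nx: int
    ny: int
    origin: tuple  # (x0, y0) um of the corner of cell (0, 0)
    cell_class: np.ndarray  # shape (nx, ny), values from CellClass
    geometry: DomainGeometry | None = None

    @property
    def xc(self):
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.cell_size

    @property
    def yc(self):
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.cell_size

    def is_open(self):
        """Cells a fluid phase may occupy (fluid + fenestra channel)."""
        return ((self.cell_class == CellClass.FLUID)
                | (self.cell_class == CellClass.FENESTRA_INTERFACE))

    def is_solid(self):
        return ((self.cell_class == CellClass.WALL)
                | (self.cell_class == CellClass.FIBER_SOLID))

    def solid_area(self) -> float:
        """Total fiber-solid area (um^2) of the rasterization."""
        return float(np.count_nonzero(
            self.cell_class == CellClass.FIBER_SOLID)) * self.cell_size ** 2

    def validate(self):
        cls = self.cell_class
        border = np.zeros_like(cls, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        io = ((cls == CellClass.PRESSURE_INLET)
              | (cls == CellClass.PRESSURE_OUTLET))
        if np.any(io & ~border):
            raise GeometryConfigError("inlet/outlet cells must lie on the boundary")
        openc = self.is_open() | io
        labels, n = ndimage.label(openc)
        if n == 0:
            raise GeometryConfigError("no fluid cells")
        inlet_labels = set(labels[cls == CellClass.PRESSURE_INLET].ravel()) - {0}
        outlet_labels = set(labels[cls == CellClass.PRESSURE_OUTLET].ravel()) - {0}
        if not inlet_labels or not outlet_labels:
            raise GeometryConfigError("inlet or outlet not connected to fluid")
        main = inlet_labels | outlet_labels
        if len(main) != 1:
            raise GeometryConfigError(
                "fluid does not form one connected component joining inlet "
                "and outlet"
            )


def build_vessel_geometry(config: VesselGeometryConfig) -> DomainGeometry:
    """Analytic geometry of the blood-vessel segment.

    The depression is a circular arc of chord ``depression_diameter`` and
    sagitta ``depression_depth`` carved into the bottom (tumor-facing) wall;
    with the default 5.2 x 2.6 um dimensions the arc is exactly a
    semicircle, which meets the straight wall at right angles (the
    ``tangent_continuous`` flag records this).
    """
    config.validate()
    y_lo = -config.depression_depth
    extent = (0.0, config.vessel_length, y_lo, config.vessel_height)
    tangent = None
    if config.depression_depth > 0:
        tangent = abs(config.depression_depth
                      - config.depression_diameter / 2) < 1e-12 * 5.2 + 1e-9
        # the arc meets the wall tangentially only in the degenerate flat
        # limit; a semicircle meets it at 90 degrees
        tangent = False if config.depression_depth > 1e-9 else tangent
    return DomainGeometry(
        kind="vessel",
        extent=extent,
        circles=tuple(config.fiber_obstacles),
        vessel=config,
        tangent_continuous=tangent,
    )


def build_tumor_geometry(config: TumorGeometryConfig) -> DomainGeometry:
    """Analytic geometry of the tumor extracellular segment."""
    config.validate()
    extent = (0.0, config.tumor_width, 0.0,
              config.tumor_height + config.fenestra_length)
    return DomainGeometry(
        kind="tumor",
        extent=extent,
        circles=tuple(config.fiber_circles),
        tumor=config,
    )


def place_fibers(
    width: float,
    height: float,
    target_packing: float,
    rng_seed: int = 0,
    r_min: float = 0.5,
    r_max: float = 0.9,
    min_gap: float = 0.25,
    boundary_gap: float = 0.15,
    exclusions: tuple = (),
    max_attempts: int = 20000,
) -> list:
    """Random non-overlapping fiber circles at a target packing fraction.

    Circles are drawn by rejection sampling inside the ``width x height``
    rectangle, fully contained (so their analytic area is exact), pairwise
    separated by at least ``min_gap`` so fluid can always pass between
    fibers, and kept out of the ``exclusions`` discs ((cx, cy, clearance),
    e.g. the fenestra mouth).  Deterministic for a fixed ``rng_seed``; the
    achieved fraction lands within +/-0.01 of ``target_packing``.
    """
    bound = math.pi / (2 * math.sqrt(3.0))
    if not (0 <= target_packing < bound):
        raise GeometryConfigError(
            f"target packing must lie in [0, {bound:.3f}) (circle-packing bound)"
        )
    if target_packing == 0:
        return []
    rng = np.random.RandomState(rng_seed)
    area = width * height
    circles: list = []
    covered = 0.0
    attempts = 0
    while covered / area < target_packing - 0.01:
        if attempts >= max_attempts:
            raise GeometryConfigError(
                f"could not reach packing {target_packing}; achieved "
                f"{covered / area:.4f} after {max_attempts} attempts"
            )
        attempts += 1
        remaining = (target_packing - covered / area) * area
        r_fit = math.sqrt(max(remaining, 0.0) / math.pi)
        r = float(rng.uniform(r_min, r_max))
        r = min(r, max(r_fit, r_min))  # final circle sized to land on target
        cx = float(rng.uniform(r + boundary_gap, width - r - boundary_gap))
        cy = float(rng.uniform(r + boundary_gap, height - r - boundary_gap))
        ok = all(
            math.hypot(cx - ox, cy - oy) >= r + orr + min_gap
            for (ox, oy, orr) in circles
        ) and all(
            math.hypot(cx - ex, cy - ey) >= r + clr
            for (ex, ey, clr) in exclusions
        )
        if ok:
            circles.append((cx, cy, r))
            covered += math.pi * r * r
    return circles


def packing_fraction(geometry: DomainGeometry) -> float:
    """Fiber cross-section area over tumor area (clipped to the region).

    Circles fully inside the rectangular tumor region contribute their exact
    analytic area pi r^2; partially overlapping circles are clipped with a
    polygonal boolean intersection (256-segment circle approximation).
    """
    region = geometry.tumor_region
    if region is None:
        raise GeometryConfigError("geometry has no defined tumor region")
    x0, x1, y0, y1 = region
    total = 0.0
    rect = None
    for (cx, cy, r) in geometry.circles:
        if x0 + r <= cx <= x1 - r and y0 + r <= cy <= y1 - r:
            total += math.pi * r * r
        else:
            if rect is None:
                rect = box(x0, y0, x1, y1)
            total += Point(cx, cy).buffer(r, quad_segs=256).intersection(rect).area
    return total / ((x1 - x0) * (y1 - y0))


def rasterize(geometry: DomainGeometry, cell_size: float) -> GridMask:
    """Rasterize analytic geometry onto a uniform grid (center-point rule).

    A one-cell padding ring is added around the analytic extent; ring cells
    adjacent to open flow at the inflow/outflow edges become
    pressure_inlet/pressure_outlet cells, the rest of the ring is wall.  The
    fenestra channel must be resolved by at least 4 cells across its width.
    """
    if cell_size <= 0:
        raise GeometryConfigError("cell_size must be positive")
    if geometry.kind == "tumor":
        D = geometry.tumor.fenestra_diameter
        if D / cell_size < 4 - 1e-9:
            raise GeometryConfigError(
                f"cell_size {cell_size} um leaves only {D / cell_size:.1f} cells "
                f"across the {D} um fenestra; need >= 4 (try "
                f"cell_size <= {D / 4:.4g})"
            )
    x0, x1, y0, y1 = geometry.extent
    h = cell_size
    nxc = max(1, int(round((x1 - x0) / h)))
    nyc = max(1, int(round((y1 - y0) / h)))
    nx, ny = nxc + 2, nyc + 2
    ox, oy = x0 - h, y0 - h
    xc = ox + (np.arange(nx) + 0.5) * h
    yc = oy + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xc, yc, indexing="ij")

    cls = np.full((nx, ny), int(CellClass.WALL), dtype=np.int8)
    fluid = geometry.is_fluid(X, Y)
    fen = geometry.in_fenestra(X, Y)
    circ = geometry.in_circle(X, Y)
    inside_extent = (X > x0) & (X < x1) & (Y > y0) & (Y < y1)
    cls[fluid] = int(CellClass.FLUID)
    cls[fen & fluid] = int(CellClass.FENESTRA_INTERFACE)
    cls[circ & inside_extent] = int(CellClass.FIBER_SOLID)
    # padding ring is wall by default
    cls[0, :] = cls[-1, :] = int(CellClass.WALL)
    cls[:, 0] = cls[:, -1] = int(CellClass.WALL)

    openv = (cls == int(CellClass.FLUID)) | (cls == int(CellClass.FENESTRA_INTERFACE))
    if geometry.kind == "vessel":
        cls[0, 1:-1][openv[1, 1:-1]] = int(CellClass.PRESSURE_INLET)
        cls[-1, 1:-1][openv[-2, 1:-1]] = int(CellClass.PRESSURE_OUTLET)
    else:
        cfg = geometry.tumor
        # inlet ring above the fenestra mouth
        cls[1:-1, -1][openv[1:-1, -2]] = int(CellClass.PRESSURE_INLET)
        seg = cfg.outlet_segment or (0.0, cfg.tumor_width)
        on_seg = (xc[1:-1] >= seg[0]) & (xc[1:-1] <= seg[1])
        cls[1:-1, 0][openv[1:-1, 1] & on_seg] = int(CellClass.PRESSURE_OUTLET)

    mask = GridMask(cell_size=h, nx=nx, ny=ny, origin=(ox, oy),
                    cell_class=cls, geometry=geometry)
    mask.validate()
    return mask
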