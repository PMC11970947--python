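"""2D transient Eulerian multiphase finite-volume solver.

Each phase is an interpenetrating continuum with its own volume fraction
``Psi_i`` (cell-centered) and velocity ``v_i`` (staggered, face-centered),
all phases sharing one pressure field.  A time step performs, in order:

1. per-phase momentum prediction with first-order upwind convection and
   shear-dependent viscosity, both treated implicitly (the micron-scale flow
   is strongly viscous, which makes explicit diffusion impractical);
2. implicit interphase drag coupling between the continuous phase and each
   dispersed phase (pointwise linear systems per face), using the
   Schiller-Naumann exchange coefficient;
3. a SIMPLEC-style shared-pressure correction enforcing mixture continuity
   ``div(sum_i Psi_i v_i) = 0``, iterated so the upwind face fractions are
   consistent with the corrected velocities;
4. bounded first-order upwind advection of the dispersed volume fractions
   (sub-cycled to its own CFL limit), with the primary phase closing
   ``sum_i Psi_i = 1`` so dispersed mass is never created by rescaling; the
   clipping/closure correction magnitudes are logged.

All linear systems are solved with a sparse direct factorization; the
sparsity patterns are precomputed once per grid and reused.  Fields use SI
units internally (the grid mask's micrometre cell size is converted here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from . import constitutive as cst
from .constitutive import PhaseSpec, RheologyParams
from .geometry import CellClass, GridMask

log = logging.getLogger(__name__)

__all__ = [
    "FlowState",
    "BoundaryConditionSet",
    "SolverConfig",
    "SolverDivergenceError",
    "advance",
    "run_transient",
    "apply_boundary_conditions",
    "check_convergence",
    "initial_state",
    "shear_rate_field",
]

UM = 1e-6  # metres per micrometre


def _bc_value(value, t):
    """Boundary values may be constants or callables of time."""
    return float(value(t)) if callable(value) else float(value)


class SolverDivergenceError(RuntimeError):
    """Raised when residuals blow up; carries a diagnostic dump."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class FlowState:
    """Per-phase fields at one time instant (SI units).

    ``psi[name]`` has shape (nx, ny); ``u[name]`` (nx+1, ny) holds the
    x-velocity on vertical faces, ``v[name]`` (nx, ny+1) the y-velocity on
    horizontal faces; ``p`` (nx, ny) is the shared pressure.
    """

    t: float
    psi: dict
    u: dict
    v: dict
    p: np.ndarray

    def copy(self) -> "FlowState":
        return FlowState(
            t=self.t,
            psi={k: a.copy() for k, a in self.psi.items()},
            u={k: a.copy() for k, a in self.u.items()},
            v={k: a.copy() for k, a in self.v.items()},
            p=self.p.copy(),
        )

    def check_invariants(self, mask: GridMask, tol: float = 1e-8):
        openc = mask.is_open()
        total = sum(self.psi.values())
        if np.max(np.abs(total[openc] - 1.0)) > tol:
            raise AssertionError("volume fractions do not sum to 1")
        for name, a in self.psi.items():
            if a[openc].min() < -1e-12 or a[openc].max() > 1 + 1e-12:
                raise AssertionError(f"volume fraction of {name} out of [0, 1]")


@dataclass
class BoundaryConditionSet:
    """Inlet/outlet conditions; walls and fibers are always no-slip.

    ``inlet_velocity`` is a callable ``t -> speed (m/s)``; when provided the
    inlet is velocity-driven (the inlet pressure value then only serves as
    the reference/initial level), otherwise the inlet is a pure pressure
    inlet.  ``backflow_fractions`` are imposed at the outlet only where the
    local face velocity points back into the domain.
    """

    inlet_pressure: object = 3325.0  # Pa, or callable t -> Pa
    outlet_pressure: object = 2128.0  # Pa, or callable t -> Pa
    inlet_fractions: dict = field(default_factory=lambda: {"plasma": 1.0})
    backflow_fractions: dict | None = None
    inlet_velocity: object | None = None  # callable t -> m/s, or None

    def validate(self, phase_names):
        for nm, fr in (("inlet", self.inlet_fractions),
                       ("backflow", self.backflow_fractions or {})):
            if fr and abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"{nm} volume fractions must sum to 1")
            for k in fr:
                if k not in phase_names:
                    raise ValueError(f"{nm} fraction for unknown phase {k!r}")


@dataclass
class SolverConfig:
    dt: float = 1e-4  # s
    end_time: float = 0.0  # s
    tol_continuity: float = 1e-4
    tol_velocity: float = 1e-4
    n_pressure_outer: int = 2  # projection sweeps per mini-step (re-upwinded)
    mini_cfl: float = 1.6  # projection/advection recoupling interval (CFL units)
    under_relax_momentum: float = 0.7  # used when momentum is re-iterated
    under_relax_pressure: float = 1.0  # SIMPLEC convention
    cfl_warn: float = 0.9
    psi_floor: float = 1e-6  # floor in per-phase momentum/drag weighting
    rbc_visc_fallback: float = 6e-3  # kg/(m s) where Psi_rbc ~ 0
    divergence_factor: float = 1e3
    gravity: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tol_continuity <= 0 or self.tol_velocity <= 0:
            raise ValueError("tolerances must be positive")


# --------------------------------------------------------------------------
# workspace: static grid/topology data shared by every step
# --------------------------------------------------------------------------

_UNUSED, _DIRICHLET, _UNKNOWN = 0, 1, 2


class _Workspace:
    """Precomputed face/cell topology and sparse patterns for one grid."""

    def __init__(self, mask: GridMask, phases, bcs: BoundaryConditionSet):
        self.mask = mask
        self.h = mask.cell_size * UM
        nx, ny = mask.nx, mask.ny
        cls = mask.cell_class
        self.phases = list(phases)
        self.names = [p.name for p in phases]
        primary = [p for p in phases if p.role == "primary"]
        if len(primary) != 1:
            raise ValueError("exactly one primary phase is required")
        self.primary = primary[0].name
        bcs.validate(self.names)

        solid = np.asarray(mask.is_solid())
        openc = np.asarray(mask.is_open())
        inlet = cls == CellClass.PRESSURE_INLET
        outlet = cls == CellClass.PRESSURE_OUTLET
        self.solid, self.open, self.inlet, self.outlet = solid, openc, inlet, outlet
        self.bcp = inlet | outlet
        nonsolid = openc | self.bcp

        # orientation of the velocity inlet (if any): vessel feeds from the
        # left ring in +x, the tumor fenestra feeds from the top ring in -y
        self.inlet_axis = "x"
        if inlet.any():
            js = np.argwhere(inlet)
            if np.all(js[:, 1] == ny - 1):
                self.inlet_axis = "-y"
            elif np.all(js[:, 0] == 0):
                self.inlet_axis = "x"
            else:
                raise ValueError("unsupported inlet placement")
        self.velocity_driven = bcs.inlet_velocity is not None

        # ---- face categories ------------------------------------------------
        # interior u-faces are indices 1..nx-1 -> between cells i-1 and i
        ucat = np.zeros((nx + 1, ny), dtype=np.int8)
        vcat = np.zeros((nx, ny + 1), dtype=np.int8)
        cat = np.zeros((nx - 1, ny), dtype=np.int8)
        nsl, nsr = nonsolid[:-1, :], nonsolid[1:, :]
        sl, sr = solid[:-1, :], solid[1:, :]
        cat[(sl & nsr) | (nsl & sr)] = _DIRICHLET  # no-slip, value 0
        unknown = nsl & nsr & ~(self.bcp[:-1, :] & self.bcp[1:, :])
        cat[unknown] = _UNKNOWN
        if self.velocity_driven and self.inlet_axis == "x":
            vel_face = ((inlet[:-1, :] & openc[1:, :])
                        | (openc[:-1, :] & inlet[1:, :]))
            cat[vel_face] = _DIRICHLET
            self.u_inlet_faces = np.zeros((nx + 1, ny), dtype=bool)
            self.u_inlet_faces[1:-1, :] = vel_face
        else:
            self.u_inlet_faces = np.zeros((nx + 1, ny), dtype=bool)
        ucat[1:-1, :] = cat

        cat = np.zeros((nx, ny - 1), dtype=np.int8)
        nsb, nst = nonsolid[:, :-1], nonsolid[:, 1:]
        sb, st = solid[:, :-1], solid[:, 1:]
        cat[(sb & nst) | (nsb & st)] = _DIRICHLET
        unknown = nsb & nst & ~(self.bcp[:, :-1] & self.bcp[:, 1:])
        cat[unknown] = _UNKNOWN
        if self.velocity_driven and self.inlet_axis == "-y":
            vel_face = ((inlet[:, 1:] & openc[:, :-1])
                        | (openc[:, 1:] & inlet[:, :-1]))
            cat[vel_face] = _DIRICHLET
            self.v_inlet_faces = np.zeros((nx, ny + 1), dtype=bool)
            self.v_inlet_faces[:, 1:-1] = vel_face
        else:
            self.v_inlet_faces = np.zeros((nx, ny + 1), dtype=bool)
        vcat[:, 1:-1] = cat

        # convective (zero-gradient) outflow for velocity-driven runs: the
        # outlet-adjacent faces copy their upstream neighbour and are scaled
        # for global mass balance instead of being momentum-solved against
        # the ghost pressure (which is unstable at strong pulse crests)
        self.outflow = []  # (comp, fi, fj, src_i, src_j)
        if self.velocity_driven:
            for i, j in np.argwhere(outlet):
                for comp, f, srcs in (
                    ("u", (i, j), (i - 1, j)),       # outlet right of cell i-1
                    ("u", (i + 1, j), (i + 2, j)),   # outlet left
                    ("v", (i, j), (i, j - 1)),       # outlet above
                    ("v", (i, j + 1), (i, j + 2)),   # outlet below
                ):
                    cata = ucat if comp == "u" else vcat
                    if (0 <= f[0] < cata.shape[0] and 0 <= f[1] < cata.shape[1]
                            and cata[f] == _UNKNOWN):
                        cata[f] = _UNUSED
                        self.outflow.append((comp, f[0], f[1], srcs[0], srcs[1]))
        self.ucat, self.vcat = ucat, vcat

        # fully-developed (parabolic) inlet profile, discretely normalised to
        # unit mean: a plug profile meeting no-slip corners seeds an entrance
        # singularity that destabilises the pulse crest
        self.u_inlet_profile = np.zeros_like(self.u_inlet_faces, dtype=float)
        if self.u_inlet_faces.any():
            fi, fj = np.where(self.u_inlet_faces)
            lo, hi = fj.min(), fj.max()
            xi = (fj - (lo + hi) / 2.0) / max((hi - lo + 1) / 2.0, 1e-12)
            prof = np.maximum(1.0 - xi ** 2, 0.0)
            self.u_inlet_profile[fi, fj] = prof / prof.mean()
        self.v_inlet_profile = np.zeros_like(self.v_inlet_faces, dtype=float)
        if self.v_inlet_faces.any():
            fi, fj = np.where(self.v_inlet_faces)
            lo, hi = fi.min(), fi.max()
            xi = (fi - (lo + hi) / 2.0) / max((hi - lo + 1) / 2.0, 1e-12)
            prof = np.maximum(1.0 - xi ** 2, 0.0)
            self.v_inlet_profile[fi, fj] = prof / prof.mean()

        self._build_momentum_topology()
        self._build_pressure_topology()
        self.lu_cache: dict = {}

    # -- momentum system topology (shared by all phases) ---------------------
    def _build_momentum_topology(self):
        self.mom = {}
        for comp in ("u", "v"):
            cat = self.ucat if comp == "u" else self.vcat
            nfx, nfy = cat.shape
            unk = np.argwhere(cat == _UNKNOWN)
            nunk = len(unk)
            index = -np.ones(cat.shape, dtype=np.int64)
            index[cat == _UNKNOWN] = np.arange(nunk)
            fi, fj = unk[:, 0], unk[:, 1]
            # neighbour faces in W, E, S, N order
            shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
            nb_idx = np.full((4, nunk), -1, dtype=np.int64)
            nb_kind = np.zeros((4, nunk), dtype=np.int8)
            # kinds: 0 unknown, 1 dirichlet, 2 zerograd, 3 mirror
            for k, (di, dj) in enumerate(shifts):
                ni, nj = fi + di, fj + dj
                inside = (ni >= 0) & (ni < nfx) & (nj >= 0) & (nj < nfy)
                kind = np.full(nunk, 2, dtype=np.int8)  # default zero-gradient
                ncat = np.zeros(nunk, dtype=np.int8)
                ncat[inside] = cat[ni[inside], nj[inside]]
                kind[inside & (ncat == _UNKNOWN)] = 0
                kind[inside & (ncat == _DIRICHLET)] = 1
                if dj != 0:
                    # unused lateral neighbour: mirror across a no-slip wall
                    # when the neighbouring cell row is solid
                    unused = inside & (ncat == _UNUSED)
                    if comp == "u":
                        srow = np.zeros(nunk, dtype=bool)
                        cj = fj + (0 if dj < 0 else 0) + dj
                        ok = (cj >= 0) & (cj < self.mask.ny)
                        s = self.solid
                        srow[ok] = (s[np.clip(fi - 1, 0, None)[ok], cj[ok]]
                                    & s[np.minimum(fi, self.mask.nx - 1)[ok], cj[ok]])
                        kind[unused & srow] = 3
                    else:
                        kind[unused] = 2
                if di != 0 and comp == "v":
                    # unused x-neighbour of a v-face: mirror if that column is wall
                    unused = inside & (ncat == _UNUSED)
                    scol = np.zeros(nunk, dtype=bool)
                    ci = fi + di
                    ok = (ci >= 0) & (ci < self.mask.nx)
                    s = self.solid
                    scol[ok] = (s[ci[ok], np.clip(fj - 1, 0, None)[ok]]
                                & s[ci[ok], np.minimum(fj, self.mask.ny - 1)[ok]])
                    kind[unused & scol] = 3
                idx = np.full(nunk, -1, dtype=np.int64)
                m = kind == 0
                idx[m] = index[ni[m], nj[m]]
                nb_idx[k], nb_kind[k] = idx, kind
                # dirichlet values are resolved at solve time (inlet faces)
            # static sparse pattern: diagonal + unknown neighbours
            rows = [np.arange(nunk)]
            cols = [np.arange(nunk)]
            for k in range(4):
                m = nb_kind[k] == 0
                rows.append(np.arange(nunk)[m])
                cols.append(nb_idx[k][m])
            self.mom[comp] = dict(
                unk=unk, index=index, nb_idx=nb_idx, nb_kind=nb_kind,
                rows=np.concatenate(rows), cols=np.concatenate(cols),
                nunk=nunk,
            )

    # -- pressure-correction topology ----------------------------------------
    def _build_pressure_topology(self):
        nx, ny = self.mask.nx, self.mask.ny
        cells = np.argwhere(self.open)
        ncell = len(cells)
        index = -np.ones((nx, ny), dtype=np.int64)
        index[self.open] = np.arange(ncell)
        ci, cj = cells[:, 0], cells[:, 1]
        # faces in W, E, S, N order; a face couples iff it is an UNKNOWN
        # velocity face (dirichlet/solid faces carry no correction)
        self.prs = dict(cells=cells, index=index, ncell=ncell)
        nb_idx = np.full((4, ncell), -1, dtype=np.int64)
        nb_open = np.zeros((4, ncell), dtype=bool)
        nb_bcp = np.zeros((4, ncell), dtype=bool)
        face_unknown = np.zeros((4, ncell), dtype=bool)
        self.face_ij = {}
        for k, (di, dj, comp, foff) in enumerate(
            [(-1, 0, "u", (0, 0)), (1, 0, "u", (1, 0)),
             (0, -1, "v", (0, 0)), (0, 1, "v", (0, 1))]
        ):
            ni, nj = ci + di, cj + dj
            inside = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj < ny)
            nb_open[k][inside] = self.open[ni[inside], nj[inside]]
            nb_bcp[k][inside] = self.bcp[ni[inside], nj[inside]]
            m = nb_open[k]
            nb_idx[k][m] = index[ni[m], nj[m]]
            fi, fj = ci + foff[0], cj + foff[1]
            cat = self.ucat if comp == "u" else self.vcat
            face_unknown[k] = cat[fi, fj] == _UNKNOWN
            self.face_ij[k] = (fi, fj, comp)
        self.prs.update(nb_idx=nb_idx, nb_open=nb_open, nb_bcp=nb_bcp,
                        face_unknown=face_unknown)


class _ReusedLU:
    """Direct solve with factorization reuse across slowly drifting operators.

    The LU of an earlier matrix preconditions iterative refinement on the
    current one; when refinement fails to reach ``rtol`` (operator drifted
    too far) the matrix is refactored.  Exact to ``rtol`` by construction.
    """

    def __init__(self, rtol: float = 1e-8, max_refine: int = 15):
        self.lu = None
        self.rtol = rtol
        self.max_refine = max_refine

    def solve(self, A, b):
        bn = float(np.linalg.norm(b))
        if bn == 0.0:
            return np.zeros_like(b)
        if self.lu is None:
            self.lu = splu(A)
            return self.lu.solve(b)
        x = self.lu.solve(b)
        r_prev = None
        for _ in range(self.max_refine):
            r = b - A @ x
            rn = float(np.linalg.norm(r))
            if rn <= self.rtol * bn:
                return x
            if r_prev is not None and rn > 0.5 * r_prev:
                break  # slow contraction: the operator drifted too far
            r_prev = rn
            x = x + self.lu.solve(r)
        self.lu = splu(A)
        return self.lu.solve(b)


_WS_CACHE: dict = {}


def _workspace(mask: GridMask, phases, bcs) -> _Workspace:
    key = (id(mask), tuple(p.name for p in phases),
           bcs.inlet_velocity is not None)
    ws = _WS_CACHE.get(key)
    if ws is None or ws.mask is not mask:
        if len(_WS_CACHE) > 8:  # bound memory across many small runs
            _WS_CACHE.clear()
        ws = _Workspace(mask, phases, bcs)
        _WS_CACHE[key] = ws
    return ws


# --------------------------------------------------------------------------
# field helpers
# --------------------------------------------------------------------------

def cell_velocity(state: FlowState, name: str):
    """Cell-centered velocity of one phase (average of face values)."""
    u = state.u[name]
    v = state.v[name]
    return 0.5 * (u[:-1, :] + u[1:, :]), 0.5 * (v[:, :-1] + v[:, 1:])


def shear_rate_field(state: FlowState, mask: GridMask):
    """Scalar shear rate ``sqrt(2 S:S)`` of the mixture velocity (1/s)."""
    h = mask.cell_size * UM
    uc = np.zeros((mask.nx, mask.ny))
    vc = np.zeros((mask.nx, mask.ny))
    for name in state.psi:
        pu, pv = cell_velocity(state, name)
        uc += state.psi[name] * pu
        vc += state.psi[name] * pv
    dudx, dudy = np.gradient(uc, h, edge_order=1)
    dvdx, dvdy = np.gradient(vc, h, edge_order=1)
    g = np.sqrt(2.0 * (dudx ** 2 + dvdy ** 2) + (dudy + dvdx) ** 2)
    g[~np.asarray(mask.is_open())] = 0.0
    return g


def _phase_viscosity(ws: _Workspace, state: FlowState, gdot, config,
                     rheo: RheologyParams):
    """Cell-centered dynamic viscosity (kg/(m s)) per phase."""
    out = {}
    for ph in ws.phases:
        if ph.viscosity_model == "constant":
            out[ph.name] = np.full((ws.mask.nx, ws.mask.ny), ph.viscosity)
        else:
            psi_r = state.psi[ph.name]
            eta = np.full(psi_r.shape, config.rbc_visc_fallback)
            sel = psi_r > 1e-3
            if np.any(sel):
                vf = {
                    "plasma": state.psi[ws.primary][sel],
                    "rbc": psi_r[sel],
                    "wbc": state.psi.get(
                        "wbc", np.zeros_like(psi_r))[sel],
                }
                # floored at the plasma viscosity: where extreme shear drives
                # the correlation below the plasma bound, a concentrated RBC
                # suspension still cannot be thinner than its carrier (a
                # near-inviscid RBC phase destabilises outlet corners)
                eta[sel] = cst.rbc_viscosity(
                    vf, gdot[sel],
                    {p.name: p for p in ws.phases}, rheo,
                    floor=1e-3)
            out[ph.name] = eta
    return out


def _face_avg_u(cellfield):
    out = np.zeros((cellfield.shape[0] + 1, cellfield.shape[1]))
    out[1:-1, :] = 0.5 * (cellfield[:-1, :] + cellfield[1:, :])
    out[0, :], out[-1, :] = cellfield[0, :], cellfield[-1, :]
    return out


def _face_avg_v(cellfield):
    out = np.zeros((cellfield.shape[0], cellfield.shape[1] + 1))
    out[:, 1:-1] = 0.5 * (cellfield[:, :-1] + cellfield[:, 1:])
    out[:, 0], out[:, -1] = cellfield[:, 0], cellfield[:, -1]
    return out


def _upwind_face_psi(psi, u, v):
    """Upwind (donor-cell) volume fraction on u- and v-faces."""
    fx = np.zeros_like(u)
    fx[1:-1, :] = np.where(u[1:-1, :] >= 0, psi[:-1, :], psi[1:, :])
    fy = np.zeros_like(v)
    fy[:, 1:-1] = np.where(v[:, 1:-1] >= 0, psi[:, :-1], psi[:, 1:])
    return fx, fy


# --------------------------------------------------------------------------
# boundary conditions
# --------------------------------------------------------------------------

def apply_boundary_conditions(state: FlowState, mask: GridMask,
                              bcs: BoundaryConditionSet, t: float,
                              phases=None) -> FlowState:
    """Impose ghost-cell values: BC pressures, inlet fractions, backflow.

    Outlet backflow fractions are only *felt* where the local face velocity
    points inward, because the upwind advection takes its donor value from
    the outlet cell exactly in that case.
    """
    if phases is None:
        phases = [PhaseSpec(n, "primary" if i == 0 else "secondary",
                            1000.0, "constant", 1e-3,
                            None if i == 0 else 1e-6)
                  for i, n in enumerate(state.psi)]
    ws = _workspace(mask, phases, bcs)
    state.p[ws.inlet] = _bc_value(bcs.inlet_pressure, t)
    state.p[ws.outlet] = _bc_value(bcs.outlet_pressure, t)
    names = list(state.psi)
    back = bcs.backflow_fractions or bcs.inlet_fractions
    for name in names:
        state.psi[name][ws.inlet] = bcs.inlet_fractions.get(name, 0.0)
        state.psi[name][ws.outlet] = back.get(name, 0.0)
        state.psi[name][ws.solid] = 0.0
        if ws.velocity_driven:
            sp = bcs.inlet_velocity(t)
            state.u[name][ws.u_inlet_faces] = (
                sp * ws.u_inlet_profile[ws.u_inlet_faces])
            if ws.inlet_axis == "-y":
                state.v[name][ws.v_inlet_faces] = (
                    -sp * ws.v_inlet_profile[ws.v_inlet_faces])
        else:
            state.u[name][ws.u_inlet_faces] = 0.0
    return state


# --------------------------------------------------------------------------
# the time step
# --------------------------------------------------------------------------

def _momentum_predict(ws, state, comp, name, nu_face, pgrad_rhs, adv_u, adv_v,
                      dt, ubc):
    """Solve one implicit advection-diffusion momentum system.

    Returns the full face array with Dirichlet/unused values already set.
    """
    top = ws.mom[comp]
    nunk = top["nunk"]
    field_old = (state.u if comp == "u" else state.v)[name]
    if nunk == 0:
        return field_old.copy()
    h = ws.h
    unk = top["unk"]
    fi, fj = unk[:, 0], unk[:, 1]
    uc = adv_u[fi, fj]
    vc = adv_v[fi, fj]
    nu = nu_face[fi, fj]
    up, um = np.maximum(uc, 0), np.minimum(uc, 0)
    vp, vm = np.maximum(vc, 0), np.minimum(vc, 0)
    diag = 1.0 / dt + (up - um + vp - vm) / h + 4.0 * nu / h ** 2
    cW = -up / h - nu / h ** 2
    cE = um / h - nu / h ** 2
    cS = -vp / h - nu / h ** 2
    cN = vm / h - nu / h ** 2
    coefs = [cW, cE, cS, cN]
    rhs = field_old[fi, fj] / dt + pgrad_rhs
    nb_idx, nb_kind = top["nb_idx"], top["nb_kind"]
    cat = ws.ucat if comp == "u" else ws.vcat
    inlet_faces = ws.u_inlet_faces if comp == "u" else ws.v_inlet_faces
    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    data = [diag.copy()]
    for k in range(4):
        c = coefs[k]
        kind = nb_kind[k]
        m_dir = kind == 1
        if np.any(m_dir):
            ni = fi[m_dir] + shifts[k][0]
            nj = fj[m_dir] + shifts[k][1]
            prof = (ws.u_inlet_profile if comp == "u"
                    else ws.v_inlet_profile)
            vals = np.where(inlet_faces[ni, nj], ubc * prof[ni, nj], 0.0)
            rhs[m_dir] -= c[m_dir] * vals
        m_zg = kind == 2
        data[0][m_zg] += c[m_zg]
        m_mir = kind == 3
        data[0][m_mir] -= c[m_mir]
        data.append(c[kind == 0])
    A = csc_matrix(
        (np.concatenate(data), (top["rows"], top["cols"])), shape=(nunk, nunk))
    cache = ws.lu_cache.setdefault(("mom", comp, name), _ReusedLU())
    sol = cache.solve(A, rhs)
    out = np.zeros_like(field_old)
    prof = ws.u_inlet_profile if comp == "u" else ws.v_inlet_profile
    out[inlet_faces] = ubc * prof[inlet_faces]
    out[fi, fj] = sol
    diag_full = np.full_like(field_old, 1.0 / dt)
    diag_full[fi, fj] = data[0]  # operator diagonal incl. BC adjustments
    return out, diag_full


def _drag_couple(ws, state, ustar, vstar, gdot, eta_cell, dt, psi_floor,
                 diag_u=None, diag_v=None):
    """Implicit pairwise drag between the primary and each secondary phase.

    Solves a small linear system per face (vectorised over faces) so that
    very stiff couplings -- e.g. the sub-nanometre air particle diameter --
    relax stably to equal velocities within one step.

    Also returns the drag-consistent pressure response coefficients
    ``r_i = (M^-1 Psi)_i`` per face: the velocity change of phase i per unit
    (negative) pressure-correction gradient.  Tightly coupled phases then
    receive a common mixture-like correction instead of the per-density kick
    ``dt/rho_i`` that would fling a near-massless phase apart from its
    carrier.  For a single phase ``r = dt/rho`` exactly.
    """
    names = ws.names
    prim = ws.primary
    P = len(names)
    rho = {p.name: p.density for p in ws.phases}
    resp_u = {n: np.zeros_like(ustar[n]) for n in names}
    resp_v = {n: np.zeros_like(vstar[n]) for n in names}
    if diag_u is None:
        diag_u = {n: np.full_like(ustar[n], 1.0 / dt) for n in names}
    if diag_v is None:
        diag_v = {n: np.full_like(vstar[n], 1.0 / dt) for n in names}
    if P == 1:
        for comp, resp in (("u", resp_u), ("v", resp_v)):
            unk = ws.mom[comp]["unk"]
            if len(unk):
                resp[prim][unk[:, 0], unk[:, 1]] = dt / rho[prim]
        return ustar, vstar, resp_u, resp_v
    # cell-centred slip magnitude and exchange coefficients
    alphas = {}
    rheop = RheologyParams()
    prim_spec = next(p for p in ws.phases if p.name == prim)
    uc0, vc0 = cell_velocity(state, prim)
    for ph in ws.phases:
        if ph.name == prim:
            continue
        uck, vck = cell_velocity(state, ph.name)
        slip = np.hypot(uck - uc0, vck - vc0)
        xi = (cst.shape_factor(gdot, rheop)
              if ph.shape_factor_model == "rbc_dynamic" else 1.0)
        # fractions are floored here (not in the constitutive law itself) so
        # a locally vanished phase stays drag-slaved to the carrier instead
        # of developing an unconstrained ghost velocity
        alphas[ph.name] = cst.exchange_coefficient(
            prim_spec.density, eta_cell[prim], ph.diameter, xi,
            np.maximum(state.psi[prim], 1e-3),
            np.maximum(state.psi[ph.name], 1e-3), slip)

    out_u = {n: ustar[n].copy() for n in names}
    out_v = {n: vstar[n].copy() for n in names}
    for comp in ("u", "v"):
        top = ws.mom[comp]
        unk = top["unk"]
        if len(unk) == 0:
            continue
        fi, fj = unk[:, 0], unk[:, 1]
        favg = _face_avg_u if comp == "u" else _face_avg_v
        nf = len(fi)
        M = np.zeros((nf, P, P))
        b = np.zeros((nf, P))
        star = ustar if comp == "u" else vstar
        for i, n in enumerate(names):
            c = rho[n] * np.maximum(favg(state.psi[n])[fi, fj], psi_floor) / dt
            M[:, i, i] += c
            b[:, i] = c * star[n][fi, fj]
        i0 = names.index(prim)
        for i, n in enumerate(names):
            if n == prim:
                continue
            a = favg(alphas[n])[fi, fj]
            M[:, i0, i0] += a
            M[:, i, i] += a
            M[:, i0, i] -= a
            M[:, i, i0] -= a
        sol = np.linalg.solve(M, b[..., None])[..., 0]
        for i, n in enumerate(names):
            (out_u if comp == "u" else out_v)[n][fi, fj] = sol[:, i]
        # drag-consistent pressure response r = M^-1 Psi (impulse form)
        psi_vec = np.stack(
            [np.maximum(favg(state.psi[n])[fi, fj], psi_floor)
             for n in names], axis=-1)
        r = np.linalg.solve(M, psi_vec[..., None])[..., 0]
        for i, n in enumerate(names):
            (resp_u if comp == "u" else resp_v)[n][fi, fj] = r[:, i]
    return out_u, out_v, resp_u, resp_v




def _apply_outflow(ws, psi, u, v, bcs, t):
    """Zero-gradient convective outflow with global mixture-mass scaling."""
    if not ws.outflow:
        return
    h = ws.h
    # copy upstream values per phase
    for n in ws.names:
        for comp, fi, fj, si, sj in ws.outflow:
            arr = (u if comp == "u" else v)[n]
            arr[fi, fj] = arr[si, sj]
    # mixture inflow through the velocity inlet (fractions sum to 1 there)
    q_in = 0.0
    if ws.u_inlet_faces.any():
        q_in += float(np.abs(
            u[ws.primary][ws.u_inlet_faces]).sum()) * h
    if ws.v_inlet_faces.any():
        q_in += float(np.abs(
            v[ws.primary][ws.v_inlet_faces]).sum()) * h
    # mixture outflow through the outflow faces
    q_out = 0.0
    for n in ws.names:
        fx, fy = _upwind_face_psi(psi[n], u[n], v[n])
        for comp, fi, fj, si, sj in ws.outflow:
            vel = (u if comp == "u" else v)[n][fi, fj]
            pf = (fx if comp == "u" else fy)[fi, fj]
            q_out += abs(vel) * pf * h
    if q_out > 1e-30:
        scale = q_in / q_out
        for n in ws.names:
            for comp, fi, fj, si, sj in ws.outflow:
                (u if comp == "u" else v)[n][fi, fj] *= scale


def _project(ws, psi, p, u, v, dt, bcs, n_outer, resp_u, resp_v,
             urf_p=0.7):
    """SIMPLEC-style shared-pressure correction enforcing mixture continuity.

    The face mobility and the per-phase velocity corrections both use the
    drag-consistent pressure responses from the drag coupling step, so the
    correction cannot decouple tightly dragged phases.
    """
    h = ws.h
    prs = ws.prs
    ncell = prs["ncell"]
    cells = prs["cells"]
    ci, cj = cells[:, 0], cells[:, 1]

    # face mobility beta = sum_i Psi_face_i * r_face_i (fixed per step)
    beta = {}
    for k in range(4):
        fi, fj, comp = ws.face_ij[k]
        bsum = np.zeros(ncell)
        for n in ws.names:
            favg = _face_avg_u if comp == "u" else _face_avg_v
            resp = (resp_u if comp == "u" else resp_v)[n]
            bsum += favg(psi[n])[fi, fj] * resp[fi, fj]
        bsum[~prs["face_unknown"][k]] = 0.0
        beta[k] = bsum

    rows, cols, data = [np.arange(ncell)], [np.arange(ncell)], []
    diag = np.zeros(ncell)
    anchored = False
    for k in range(4):
        c = beta[k] / h ** 2
        couple = prs["nb_open"][k] & prs["face_unknown"][k]
        diag += np.where(prs["face_unknown"][k], c, 0.0)
        anchored = anchored or bool(
            np.any(prs["nb_bcp"][k] & prs["face_unknown"][k]))
        rows.append(np.arange(ncell)[couple])
        cols.append(prs["nb_idx"][k][couple])
        data.append(-c[couple])
    if not anchored:
        # pure-Neumann system (convective outflow): pin one reference cell
        diag[0] += diag.max() if diag.max() > 0 else 1.0
    A = csc_matrix(
        (np.concatenate([diag] + data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ncell, ncell))
    lu = ws.lu_cache.setdefault(("prs",), _ReusedLU())

    sgn = np.array([-1.0, 1.0, -1.0, 1.0])  # W, E, S, N outward normals

    def mixture_divergence():
        div = np.zeros(ncell)
        for n in ws.names:
            fx, fy = _upwind_face_psi(psi[n], u[n], v[n])
            Fx, Fy = fx * u[n], fy * v[n]
            for k in range(4):
                fi, fj, comp = ws.face_ij[k]
                F = Fx if comp == "u" else Fy
                div += sgn[k] * F[fi, fj] / h
        return div

    for _ in range(max(1, n_outer)):
        div = mixture_divergence()
        pc = lu.solve(A, -div)
        # correct phase velocities on unknown faces
        pfield = np.zeros((ws.mask.nx, ws.mask.ny))
        pfield[ci, cj] = pc
        for comp in ("u", "v"):
            top = ws.mom[comp]
            unk = top["unk"]
            if len(unk) == 0:
                continue
            fi, fj = unk[:, 0], unk[:, 1]
            if comp == "u":
                dp = (pfield[fi, fj] - pfield[fi - 1, fj]) / h
            else:
                dp = (pfield[fi, fj] - pfield[fi, fj - 1]) / h
            for n in ws.names:
                resp = (resp_u if comp == "u" else resp_v)[n]
                (u if comp == "u" else v)[n][fi, fj] -= resp[fi, fj] * dp
        p[ci, cj] += urf_p * pc
    # residual mixture-continuity defect after the final sweep
    return float(np.max(np.abs(mixture_divergence())) * dt)


def _advect_psi(ws, psi0, u, v, dt, cfl_target=0.8, max_subcycles=400):
    """Conservative bounded upwind advection of every volume fraction.

    The explicit donor-cell update is sub-cycled so its internal CFL stays
    below ``cfl_target`` even when the (implicit, unconditionally stable)
    momentum step runs at a much larger advective CFL -- the standard
    phase-fraction sub-cycling of Eulerian/VOF practice.

    Returns (new_psi, clip_mag, renorm_mag, boundary_volume_flux_per_phase).
    """
    h = ws.h
    openc = ws.open
    umax = max((float(np.max(np.abs(u[n]))) for n in ws.names), default=0.0)
    vmax = max((float(np.max(np.abs(v[n]))) for n in ws.names), default=0.0)
    cfl = max(umax, vmax) * dt / h
    nsub = min(max(1, int(np.ceil(cfl / cfl_target))), max_subcycles)
    dts = dt / nsub
    new = {n: psi0[n].copy() for n in ws.names}
    bflux = {n: 0.0 for n in ws.names}
    clip_mag = 0.0
    for _ in range(nsub):
        for n in ws.names:
            psi = new[n]
            fx, fy = _upwind_face_psi(psi, u[n], v[n])
            Fx = fx * u[n]
            Fy = fy * v[n]
            divF = (Fx[1:, :] - Fx[:-1, :] + Fy[:, 1:] - Fy[:, :-1]) / h
            psi[openc] -= dts * divF[openc]
            # net volume inflow through faces bordering BC cells (unit depth)
            flux = 0.0
            for k in range(4):
                fi, fj, comp = ws.face_ij[k]
                onbc = ws.prs["nb_bcp"][k]
                vel = (u if comp == "u" else v)[n]
                pf = (fx if comp == "u" else fy)
                s = -1.0 if k in (0, 2) else 1.0  # outward positive
                flux -= s * np.sum(
                    pf[fi[onbc], fj[onbc]] * vel[fi[onbc], fj[onbc]]) * h
            bflux[n] += flux * dts / dt
    for n in ws.names:
        a = new[n]
        clip_mag = max(clip_mag,
                       float(np.max(np.maximum(a[openc] - 1, 0))),
                       float(np.max(np.maximum(-a[openc], 0))))
        np.clip(a, 0.0, 1.0, out=a)
    # the dispersed phases are advected conservatively; the primary (carrier)
    # phase closes the sum to 1 and absorbs the mixture-continuity defect.
    # Rescaling ALL phases by 1/sum would instead create/destroy dispersed
    # mass wherever the carrier locally out- or under-runs it -- a bias that
    # accumulates into spurious phase enrichment over thousands of steps.
    secondaries = [n for n in ws.names if n != ws.primary]
    if secondaries:
        sec_sum = sum(new[n] for n in secondaries)
        over = sec_sum > 1.0
        if np.any(over & openc):
            scale = np.where(over, 1.0 / np.maximum(sec_sum, 1e-300), 1.0)
            for n in secondaries:
                new[n] = np.where(openc, new[n] * scale, new[n])
            sec_sum = np.minimum(sec_sum, 1.0)
        closed = 1.0 - sec_sum
        renorm = float(np.max(np.abs(
            closed[openc] - new[ws.primary][openc])))
        new[ws.primary] = np.where(openc, closed, new[ws.primary])
    else:
        renorm = float(np.max(np.abs(new[ws.primary][openc] - 1.0)))
        new[ws.primary] = np.where(openc, 1.0, new[ws.primary])
    return new, clip_mag, renorm, bflux


def advance(state: FlowState, mask: GridMask, phases, bcs: BoundaryConditionSet,
            config: SolverConfig, rheo: RheologyParams = RheologyParams(),
            log_entry: dict | None = None) -> FlowState:
    """Advance the multiphase state by one time step of ``config.dt``."""
    ws = _workspace(mask, phases, bcs)
    dt = config.dt
    h = ws.h
    state = state.copy()
    apply_boundary_conditions(state, mask, bcs, state.t + dt, phases)

    gdot = shear_rate_field(state, mask)
    eta_cell = _phase_viscosity(ws, state, gdot, config, rheo)
    rho = {p.name: p.density for p in phases}

    # CFL advisory
    umax = max((float(np.max(np.abs(state.u[n]))) for n in ws.names), default=0.0)
    vmax = max((float(np.max(np.abs(state.v[n]))) for n in ws.names), default=0.0)
    cfl = max(umax, vmax) * dt / h
    if cfl > config.cfl_warn and (log_entry is None or log_entry.get("step") in (None, 1)):
        warnings.warn(f"advective CFL {cfl:.2f} exceeds {config.cfl_warn}; "
                      "the implicit scheme stays stable but loses accuracy",
                      stacklevel=2)

    ubc = bcs.inlet_velocity(state.t + dt) if ws.velocity_driven else 0.0
    if ws.inlet_axis == "-y":
        ubc_u, ubc_v = 0.0, -ubc
    else:
        ubc_u, ubc_v = ubc, 0.0

    ustar, vstar = {}, {}
    diag_u, diag_v = {}, {}
    for ph in phases:
        n = ph.name
        nu_u = _face_avg_u(eta_cell[n]) / rho[n]
        nu_v = _face_avg_v(eta_cell[n]) / rho[n]
        # advecting velocity of the phase itself, interpolated to faces
        ucc, vcc = cell_velocity(state, n)
        adv_uu = state.u[n]
        adv_uv = _face_avg_u(vcc)
        adv_vu = _face_avg_v(ucc)
        adv_vv = state.v[n]
        # pressure gradient terms on unknown faces
        topu = ws.mom["u"]
        fi, fj = topu["unk"][:, 0], topu["unk"][:, 1]
        dpdx = (state.p[fi, fj] - state.p[fi - 1, fj]) / h
        gx = -dpdx / rho[n] + config.gravity[0]
        ustar[n], diag_u[n] = _momentum_predict(ws, state, "u", n, nu_u, gx,
                                                adv_uu, adv_uv, dt, ubc_u)
        topv = ws.mom["v"]
        fi, fj = topv["unk"][:, 0], topv["unk"][:, 1]
        dpdy = (state.p[fi, fj] - state.p[fi, fj - 1]) / h
        gy = -dpdy / rho[n] + config.gravity[1]
        vstar[n], diag_v[n] = _momentum_predict(ws, state, "v", n, nu_v, gy,
                                                adv_vu, adv_vv, dt, ubc_v)

    ustar, vstar, resp_u, resp_v = _drag_couple(
        ws, state, ustar, vstar, gdot, eta_cell, dt, config.psi_floor,
        diag_u, diag_v)

    # re-couple the continuity projection with fraction advection in
    # CFL-limited mini-steps: at a large step CFL the fractions move many
    # cells per dt, and a single projection against the start-of-step field
    # would let the mixture constraint drift
    umax_s = max((float(np.max(np.abs(ustar[n]))) for n in ws.names),
                 default=0.0)
    vmax_s = max((float(np.max(np.abs(vstar[n]))) for n in ws.names),
                 default=0.0)
    cfl_s = max(umax_s, vmax_s) * dt / h
    nmini = min(max(1, int(np.ceil(cfl_s / config.mini_cfl))), 100)
    dtm = dt / nmini
    new_psi = {n: state.psi[n].copy() for n in ws.names}
    res_cont, clip_mag, renorm = 0.0, 0.0, 0.0
    bflux = {n: 0.0 for n in ws.names}
    _apply_outflow(ws, new_psi, ustar, vstar, bcs, state.t)
    for _ in range(nmini):
        r = _project(ws, new_psi, state.p, ustar, vstar, dtm, bcs,
                     config.n_pressure_outer, resp_u, resp_v,
                     config.under_relax_pressure)
        res_cont = max(res_cont, r * nmini)
        new_psi, clip_i, renorm_i, bflux_i = _advect_psi(
            ws, new_psi, ustar, vstar, dtm)
        clip_mag = max(clip_mag, clip_i)
        renorm = max(renorm, renorm_i)
        for n in ws.names:
            bflux[n] += bflux_i[n] / nmini

    # velocity residual: normalized change over the step
    uref = max(umax, vmax, abs(ubc), 1e-12)
    res_vel = 0.0
    for n in ws.names:
        res_vel = max(res_vel,
                      float(np.max(np.abs(ustar[n] - state.u[n]))) / uref,
                      float(np.max(np.abs(vstar[n] - state.v[n]))) / uref)

    # mixture mass bookkeeping (per unit depth): compare the change in
    # sum_i rho_i Psi_i h^2 with the net boundary mass influx
    dm = 0.0
    influx = 0.0
    for i, n in enumerate(ws.names):
        dm += rho[n] * float(np.sum(new_psi[n][ws.open] - state.psi[n][ws.open])) * h * h
        influx += rho[n] * bflux[n] * dt
    mass_tot = sum(rho[n] * float(np.sum(new_psi[n][ws.open])) for n in ws.names) * h * h
    mass_err = abs(dm - influx) / max(mass_tot, 1e-300)

    if ws.outflow:
        # pressure is defined up to a constant under pure-Neumann projection:
        # anchor the outlet-adjacent interior level at the BC value
        sel = np.zeros((ws.mask.nx, ws.mask.ny), dtype=bool)
        for comp, fi, fj, si, sj in ws.outflow:
            ci = (fi - 1, fj) if comp == "u" else (fi, fj - 1)
            if ws.open[ci]:
                sel[ci] = True
            ci2 = (fi, fj)
            if ci2[0] < ws.mask.nx and ci2[1] < ws.mask.ny and ws.open[ci2]:
                sel[ci2] = True
        if sel.any():
            shift = _bc_value(bcs.outlet_pressure, state.t + dt) - float(
                state.p[sel].mean())
            state.p[ws.open] += shift

    new = FlowState(t=state.t + dt, psi=new_psi, u=ustar, v=vstar, p=state.p)
    apply_boundary_conditions(new, mask, bcs, new.t, phases)
    if log_entry is not None:
        log_entry.update(
            time=new.t, res_continuity=res_cont, res_velocity=res_vel,
            clip=clip_mag, renorm=renorm, mass_balance_error=mass_err,
            cfl=cfl)
    return new


def initial_state(mask: GridMask, phases, bcs: BoundaryConditionSet,
                  init_fractions: dict | None = None) -> FlowState:
    """Quiescent initial state with BC-consistent pressure and fractions.

    The pressure is initialised linearly between the inlet and outlet values
    along the inflow axis; velocities start at rest.
    """
    ws = _workspace(mask, phases, bcs)
    nx, ny = mask.nx, mask.ny
    fr = init_fractions or bcs.inlet_fractions
    psi = {}
    for ph in phases:
        a = np.zeros((nx, ny))
        a[ws.open] = fr.get(ph.name, 0.0)
        psi[ph.name] = a
    p_in = _bc_value(bcs.inlet_pressure, 0.0)
    p_out = _bc_value(bcs.outlet_pressure, 0.0)
    if ws.velocity_driven:
        # a velocity-driven inlet fixes no pressure level at the inlet: the
        # dynamically consistent start is the outlet level everywhere
        p = np.full((nx, ny), p_out, dtype=float)
    elif ws.inlet_axis == "-y":
        ramp = np.linspace(p_out, p_in, ny)
        p = np.tile(ramp, (nx, 1))
    else:
        ramp = np.linspace(p_in, p_out, nx)
        p = np.tile(ramp[:, None], (1, ny))
    u = {ph.name: np.zeros((nx + 1, ny)) for ph in phases}
    v = {ph.name: np.zeros((nx, ny + 1)) for ph in phases}
    st = FlowState(t=0.0, psi=psi, u=u, v=v, p=p)
    apply_boundary_conditions(st, mask, bcs, 0.0, phases)
    return st


def run_transient(mask: GridMask, phases, bcs: BoundaryConditionSet,
                  config: SolverConfig,
                  snapshot_times=(0.10, 0.15, 0.30),
                  callbacks=(), state: FlowState | None = None,
                  rheo: RheologyParams = RheologyParams()):
    """March the solution to ``config.end_time``.

    Returns ``(snapshots, residual_log)`` where snapshots maps the requested
    times (plus 0 and the end time) to FlowState copies and the residual log
    is a list of per-step dicts.  ``callbacks`` are called as ``cb(state)``
    after every step (used by the pipeline to probe the depression).
    """
    for ts in snapshot_times:
        if ts < 0 or ts > config.end_time + 1e-12:
            raise ValueError(f"snapshot time {ts} outside [0, end_time]")
    if state is None:
        state = initial_state(mask, phases, bcs)
    snaps = {0.0: state.copy()}
    residual_log = []
    nsteps = int(round(config.end_time / config.dt))
    remaining = sorted(t for t in snapshot_times if t > 1e-15)
    for k in range(nsteps):
        entry = {"step": k + 1}
        state = advance(state, mask, phases, bcs, config, rheo, entry)
        residual_log.append(entry)
        r = entry["res_continuity"]
        # reference: the recent residual history (a pulse crest grows the
        # residual gradually; true divergence outruns it by orders)
        res_ref = max((e["res_continuity"] for e in residual_log[-51:-1]),
                      default=0.0)
        blowup = (not np.isfinite(r)) or (r > 5.0) or (
            k >= 20 and r > config.divergence_factor * max(res_ref, 1e-12))
        if blowup:
            raise SolverDivergenceError(
                f"continuity residual {r:.3g} blew up at t={state.t:.4g} "
                f"(recent reference {res_ref:.3g})",
                diagnostics={"log": residual_log, "state": state})
        for cb in callbacks:
            cb(state)
        while remaining and state.t >= remaining[0] - config.dt / 2:
            snaps[remaining.pop(0)] = state.copy()
    if config.end_time not in snaps:
        snaps[round(state.t, 12)] = state.copy()
    return snaps, residual_log


def check_convergence(residual_log, tol_continuity: float = 1e-4,
                      tol_velocity: float = 1e-4, window: int = 10):
    """Classify the tail of a residual log.

    'converged' when the final step meets both tolerances and the last
    ``window`` steps do too; 'marginal' when the final step passes but
    recent steps oscillate around the tolerance (the violation count is
    returned); 'not_converged' otherwise.
    """
    if not residual_log:
        raise ValueError("empty residual log")
    tail = residual_log[-window:]
    last = residual_log[-1]
    ok = (last["res_continuity"] < tol_continuity
          and last["res_velocity"] < tol_velocity)
    viol = sum(1 for e in tail
               if e["res_continuity"] >= tol_continuity
               or e["res_velocity"] >= tol_velocity)
    if ok and viol == 0:
        return {"status": "converged", "violations": 0}
    if ok:
        return {"status": "marginal", "violations": viol}
    return {"status": "not_converged", "violations": viol}
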