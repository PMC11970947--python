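"""Closed-form constitutive physics for the multiphase blood/perfusion model.

The blood mixture is treated as three interpenetrating continua -- plasma
(continuous), red blood cells (RBCs) and white blood cells (WBCs) -- whose
coupling is governed by:

* a hematocrit- and shear-dependent relative mixture viscosity
  ``mu_mix = a * [1 + (tau*gdot)^2]^((b-1)/2)`` (a Carreau-type shear-thinning
  law with polynomial hematocrit coefficients ``a``, ``b``),
* a dynamic RBC shape factor ``xi`` modelling agglomeration at low shear,
* Schiller-Naumann drag with an interphase momentum-exchange coefficient
  ``alpha = (3/4) Cd rho_cp Psi_cp Psi_dp |v_cp - v_dp| / (d_dp xi)``.

All functions accept scalars or numpy arrays and are vectorised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "RheologyParams",
    "PhaseSpec",
    "InletWaveform",
    "coeff_a",
    "coeff_b",
    "relative_mixture_viscosity",
    "rbc_viscosity",
    "shape_factor",
    "drag_coefficient",
    "particle_reynolds",
    "exchange_coefficient",
    "inlet_velocity",
    "default_blood_phases",
    "default_tumor_phases",
    "default_waveform",
]


@dataclass(frozen=True)
class RheologyParams:
    """Parameters of the shear-thinning blood-mixture viscosity law.

    The ``a``/``b`` polynomials are cubics in hematocrit (constant term last
    is NOT used here; coefficients are stored highest power first with the
    constant included), with separate fits above and below the shear-rate
    switch ``gdot_switch`` = 6 1/s.  ``k = ln(ln gdot)/ln gdot`` enters the
    low-shear ``b`` relation and is undefined for ``gdot <= 1``; the shear
    rate inside ``k`` is clamped to ``k_clamp`` and ``b`` is capped at 1 so
    viscosity stays bounded at vanishing shear.
    """

    tau: float = 0.11  # Carreau time constant, s
    a_high: tuple = (122.28, -51.213, 16.305, 1.0)
    b_high: tuple = (0.8092, -0.8246, -0.3503, 1.0)
    a_low: tuple = (70.782, -22.454, 9.7193, 1.0)
    # low-shear relation: (b - 1)/k = c3*Psi^3 + c2*Psi^2 + c1*Psi
    b_low_poly: tuple = (-0.8913, 2.0679, -1.7814)
    gdot_switch: float = 6.0  # 1/s, high/low shear regime boundary
    shape_amp: float = 1.5
    shape_exp: float = 0.058997
    shape_cutoff: float = 300.0  # 1/s, xi = 1 above this
    k_clamp: float = 1.0 + 1e-6

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (self.shape_cutoff > self.gdot_switch > 0):
            raise ValueError("require shape_cutoff > gdot_switch > 0")


@dataclass(frozen=True)
class PhaseSpec:
    """Physical description of one phase of the Eulerian mixture.

    Exactly one phase per simulation has ``role='primary'`` (the continuous
    carrier, plasma here); the others are dispersed secondary phases with a
    representative particle diameter ``diameter`` used in the drag closure.
    """

    name: str
    role: str  # 'primary' | 'secondary'
    density: float  # kg/m^3
    viscosity_model: str = "constant"  # 'constant' | 'rbc_shear_thinning'
    viscosity: float | None = None  # kg/(m s), for the constant model
    diameter: float | None = None  # m, particle diameter of dispersed phase
    shape_factor_model: str = "unity"  # 'unity' | 'rbc_dynamic'

    def __post_init__(self):
        if self.role not in ("primary", "secondary"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.viscosity_model == "constant" and (
            self.viscosity is None or self.viscosity <= 0
        ):
            raise ValueError(f"phase {self.name}: constant model needs viscosity > 0")
        if self.role == "secondary" and (self.diameter is None or self.diameter <= 0):
            raise ValueError(f"phase {self.name}: secondary phase needs diameter > 0")


def default_blood_phases() -> list[PhaseSpec]:
    """Plasma / RBC / WBC property registry for the vessel stage.

    Plasma 1030 kg/m^3 and 1e-3 kg/(m s); RBC 1100 kg/m^3, d = 7 um, shear
    thinning viscosity and dynamic shape factor; WBC 1080 kg/m^3,
    1.1e-2 kg/(m s), d = 14 um.
    """
    return [
        PhaseSpec("plasma", "primary", 1030.0, "constant", 0.001),
        PhaseSpec("rbc", "secondary", 1100.0, "rbc_shear_thinning", None, 7e-6,
                  "rbc_dynamic"),
        PhaseSpec("wbc", "secondary", 1080.0, "constant", 0.011, 14e-6),
    ]


def default_tumor_phases() -> list[PhaseSpec]:
    """Plasma / air registry for the tumor perfusion stage.

    Air (1.225 kg/m^3, 1.7894e-5 kg/(m s), particle diameter 4.12e-4 um)
    fills the tumor at t = 0 and acts as a vacuum surrogate that plasma
    progressively displaces.
    """
    return [
        PhaseSpec("plasma", "primary", 1030.0, "constant", 0.001),
        PhaseSpec("air", "secondary", 1.225, "constant", 1.7894e-5, 4.12e-10),
    ]


def _cubic(coeffs, x):
    c3, c2, c1, c0 = coeffs
    return ((c3 * x + c2) * x + c1) * x + c0


def coeff_a(hematocrit, shear_rate, params: RheologyParams = RheologyParams()):
    """Carreau prefactor ``a`` as a cubic in hematocrit, branch by shear regime."""
    psi = np.asarray(hematocrit, dtype=float)
    gdot = np.asarray(shear_rate, dtype=float)
    high = _cubic(params.a_high, psi)
    low = _cubic(params.a_low, psi)
    out = np.where(gdot >= params.gdot_switch, high, low)
    return out if out.ndim else float(out)


def coeff_b(hematocrit, shear_rate, params: RheologyParams = RheologyParams()):
    """Carreau exponent parameter ``b``.

    High shear (gdot >= 6): cubic in hematocrit.  Low shear: ``b = 1 + k*poly``
    with ``k = ln(ln gdot)/ln gdot`` on the clamped shear rate, capped at 1
    (viscosity must not grow without bound as shear vanishes).
    """
    psi = np.asarray(hematocrit, dtype=float)
    gdot = np.asarray(shear_rate, dtype=float)
    high = _cubic(params.b_high, psi)
    g = np.maximum(gdot, params.k_clamp)
    lng = np.log(g)
    k = np.log(lng) / lng
    c3, c2, c1 = params.b_low_poly
    low = 1.0 + k * (((c3 * psi + c2) * psi) + c1) * psi
    low = np.minimum(low, 1.0)
    out = np.where(gdot >= params.gdot_switch, high, low)
    return out if out.ndim else float(out)


def relative_mixture_viscosity(
    hematocrit, shear_rate, params: RheologyParams = RheologyParams()
):
    """Dimensionless relative blood-mixture viscosity.

    ``mu_mix = a(Psi, gdot) * [1 + (tau*gdot)^2]^((b(Psi, gdot) - 1)/2)``.
    Equals 1 for pure plasma (``Psi = 0`` gives ``a = b = 1``).
    """
    a = coeff_a(hematocrit, shear_rate, params)
    b = coeff_b(hematocrit, shear_rate, params)
    gdot = np.asarray(shear_rate, dtype=float)
    bracket = 1.0 + (params.tau * gdot) ** 2
    out = a * bracket ** ((np.asarray(b) - 1.0) / 2.0)
    return out if np.ndim(out) else float(out)


def rbc_viscosity(
    vol_fracs: dict,
    shear_rate,
    phases: dict | None = None,
    params: RheologyParams = RheologyParams(),
    floor: float = 1e-6,
):
    """Effective RBC shear viscosity (kg/(m s)) from the mixture identity.

    The mixture law defines ``mu_mix`` implicitly through

        mu_mix = (Psi_rbc*eta_rbc + Psi_plasma*eta_plasma + Psi_wbc*eta_wbc)
                 / eta_plasma

    and is solved explicitly for ``eta_rbc``.  The result is floored at
    ``floor`` (a warning is logged when the floor engages).

    Parameters
    ----------
    vol_fracs : mapping with keys 'plasma', 'rbc', 'wbc' (fractions, sum to 1)
    shear_rate : scalar or array, 1/s
    phases : optional mapping name -> PhaseSpec for the constant viscosities;
        defaults to the packaged blood registry.
    """
    if phases is None:
        phases = {p.name: p for p in default_blood_phases()}
    eta_p = phases["plasma"].viscosity
    eta_w = phases["wbc"].viscosity if "wbc" in phases else 0.0
    psi_r = np.asarray(vol_fracs["rbc"], dtype=float)
    psi_p = np.asarray(vol_fracs["plasma"], dtype=float)
    psi_w = np.asarray(vol_fracs.get("wbc", 0.0), dtype=float)
    if np.any(psi_r <= 0):
        raise ValueError("rbc_viscosity undefined for Psi_rbc = 0; "
                         "use a constant-viscosity fallback")
    mu = relative_mixture_viscosity(psi_r, shear_rate, params)
    eta = (mu * eta_p - psi_p * eta_p - psi_w * eta_w) / psi_r
    if np.any(np.asarray(eta) <= floor):
        global _floor_warned
        if not _floor_warned:
            log.warning("rbc_viscosity floored at %g kg/(m s) (logged once; "
                        "the correlation thinned below the plasma bound)", floor)
            _floor_warned = True
        else:
            log.debug("rbc_viscosity floored at %g kg/(m s)", floor)
        eta = np.maximum(eta, floor)
    return eta if np.ndim(eta) else float(eta)


_floor_warned = False


def shape_factor(shear_rate, params: RheologyParams = RheologyParams()):
    """Dynamic RBC shape factor ``xi`` (drag correction for agglomeration).

    ``xi = 1.5 * [1 + (tau*gdot)^2]^0.058997`` for ``gdot <= 300`` 1/s and 1
    above the cutoff (the branch switch is discontinuous, as specified).
    """
    gdot = np.asarray(shear_rate, dtype=float)
    agg = params.shape_amp * (1.0 + (params.tau * gdot) ** 2) ** params.shape_exp
    out = np.where(gdot <= params.shape_cutoff, agg, 1.0)
    return out if out.ndim else float(out)


def drag_coefficient(re_p):
    """Schiller-Naumann drag coefficient of a single sphere.

    ``Cd = (24/Re)(1 + 0.15 Re^0.687)`` for ``0 < Re <= 1000``, 0.44 above.
    ``Re = 0`` yields inf here; the exchange coefficient uses the finite
    product ``Cd*Re -> 24`` instead (Stokes limit).
    """
    re = np.asarray(re_p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        smooth = 24.0 / re * (1.0 + 0.15 * re ** 0.687)
    out = np.where(re > 1000.0, 0.44, smooth)
    return out if out.ndim else float(out)


def particle_reynolds(rho_cp, d_dp, xi, slip_speed, eta_cp):
    """Particle Reynolds number ``Re_p = rho_cp d_dp xi |v_cp - v_dp| / eta_cp``."""
    return rho_cp * d_dp * xi * np.abs(slip_speed) / eta_cp


def exchange_coefficient(
    rho_cp, eta_cp, d_dp, xi, psi_cp, psi_dp, slip_speed
):
    """Interphase momentum-exchange coefficient ``alpha`` (kg/(m^3 s)).

    ``alpha = (3/4) Cd rho_cp Psi_cp Psi_dp |v_slip| / (d_dp xi)`` evaluated
    in the product form

        alpha = 18 eta_cp Psi_cp Psi_dp (1 + 0.15 Re^0.687) / (d_dp^2 xi^2)

    for ``Re <= 1000`` so the Stokes limit ``Cd*Re -> 24`` keeps alpha finite
    and nonzero as the slip velocity vanishes.  Symmetric in the sense that
    the same alpha couples both phases of the pair.
    """
    re = particle_reynolds(rho_cp, d_dp, xi, slip_speed, eta_cp)
    re = np.asarray(re, dtype=float)
    stokes_like = (
        18.0 * eta_cp * psi_cp * psi_dp * (1.0 + 0.15 * re ** 0.687)
        / (d_dp ** 2 * xi ** 2)
    )
    newton = 0.75 * 0.44 * rho_cp * psi_cp * psi_dp * np.abs(slip_speed) / (d_dp * xi)
    out = np.where(re > 1000.0, newton, stokes_like)
    out = np.where(np.asarray(psi_dp) <= 0.0, 0.0, out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class InletWaveform:
    """Pulsatile inlet velocity as a truncated Fourier series.

    ``u(t) = mean_velocity * (1 + sum_n a_n cos(2 pi n t / T)
    + b_n sin(2 pi n t / T))``, T-periodic with T = 0.735 s (one cardiac
    cycle).  The packaged default coefficients produce a systolic peak and a
    diastolic plateau and keep ``u >= 0`` over the whole period.
    """

    period: float = 0.735  # s
    mean_velocity: float = 3e-4  # m/s
    cos_coeffs: tuple = ()
    sin_coeffs: tuple = ()

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if len(self.cos_coeffs) != len(self.sin_coeffs):
            raise ValueError("cosine and sine coefficient lists must align")


#: Five-harmonic default pulse shape (dimensionless perturbation of the mean).
#: Chosen to mimic a cardiac cycle qualitatively: sharp systolic rise,
#: dicrotic shoulder, non-negative everywhere.
_DEFAULT_COS = (0.30, -0.10, -0.06, -0.02, -0.01)
_DEFAULT_SIN = (0.45, 0.18, 0.04, 0.01, 0.0)


def default_waveform(mean_velocity: float = 3e-4) -> InletWaveform:
    """Packaged default pulsatile waveform (period 0.735 s).

    The mean speed default (3e-4 m/s) is a typical tumor-microvessel flow
    speed; it keeps the 0.3 s study window within about one vessel transit
    and places the shear field in the low-shear regime where the RBC
    agglomeration (shape factor) physics is active; see the methods note.
    """
    return InletWaveform(0.735, mean_velocity, _DEFAULT_COS, _DEFAULT_SIN)


def inlet_velocity(t, waveform: InletWaveform):
    """Evaluate the pulsatile inlet speed (m/s) at time ``t`` (T-periodic)."""
    t = np.asarray(t, dtype=float)
    tm = np.mod(t, waveform.period)
    omega = 2.0 * math.pi / waveform.period
    s = np.ones_like(tm)
    for n, (ac, as_) in enumerate(
        zip(waveform.cos_coeffs, waveform.sin_coeffs), start=1
    ):
        s = s + ac * np.cos(n * omega * tm) + as_ * np.sin(n * omega * tm)
    out = waveform.mean_velocity * s
    return out if out.ndim else float(out)
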