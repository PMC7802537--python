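"""Thermophysical property submodels for the bread-baking simulation.

All temperatures are kelvin internally; conversion to degrees Celsius happens
only at reporting boundaries.  Moisture ``W`` is dry-basis (kg water per kg
dry solid) throughout.

The module provides

* :class:`ParameterSet` — one formulation's physical constants and initial
  state, loadable from the packaged ``control.params`` / ``guar.params``
  key-value files;
* :class:`PhysicalConstants` — universal constants of the surface
  heat/mass-transfer closure;
* pure property functions: specific heats of the solid matrix and of liquid
  water, latent heat of vaporization, the apparent (effective) specific heat
  that folds the latent heat of the evaporation front into ``Cp``, the water
  activity (sorption) relation, surface and ambient vapor pressures, and the
  Chilton–Colburn mass-transfer coefficient.

Two corrupted printed correlations (liquid-water specific heat and water
activity) are implemented with their coefficients exposed as arguments so
alternate readings can be evaluated without touching the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "PhysicalConstants",
    "load_parameters",
    "specific_heat_solid",
    "specific_heat_water",
    "latent_heat",
    "smoothed_delta",
    "apparent_specific_heat",
    "water_activity",
    "saturation_pressure",
    "surface_vapor_pressure",
    "ambient_vapor_pressure",
    "mass_transfer_coefficient",
    "MassTransferResult",
    "BOILING_POINT_K",
]

#: Normal boiling point of water, center of the apparent-heat-capacity peak (K).
BOILING_POINT_K = 373.15

#: Default width (standard deviation, K) of the smoothed evaporation peak.
DEFAULT_DELTA_WIDTH_K = 0.5

#: Adopted coefficients of the liquid-water specific-heat polynomial
#: Cp_w(T) = (c0 + c1*T + c2*T^2) * 1000  [J/(kg K)], T in kelvin.
CP_WATER_COEFFS = (5.207, -73.17e-4, 1.35e-5)

#: Water-activity relation a_w = [(100 W exp(slope*T + c))^(-power) + 1]^(-1).
AW_SLOPE = -0.0056
AW_C = 55.0
AW_POWER = 10.38


class DomainError(ValueError):
    """An input lies outside the physical domain of a property function."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSet:
    """Physical constants and initial state of one dough formulation.

    Fields mirror the packaged parameter files field-for-field.  ``W0`` is
    dry-basis.  ``delta_const`` is the constant value of the delta-type
    function used by the literal evaporation mode; the default smoothed mode
    replaces it with a narrow Gaussian at the boiling point.
    """

    formulation: str            # "control" | "guar"
    P_sat: float                # saturation vapor pressure, Pa
    RH: float                   # ambient relative humidity, %
    T0: float                   # initial temperature, K
    W0: float                   # initial moisture, kg/kg dry basis
    r: float                    # cylinder radius, m
    rho: float                  # dough density, kg/m^3
    rho_s: float                # solid-matrix density, kg/m^3
    epsilon: float              # surface emissivity, dimensionless
    delta_const: float          # delta-type function value (literal mode)
    h: float                    # surface heat-transfer coefficient, W/(m^2 K)
    lambda_v_ref: float         # tabulated latent heat, J/kg
    D: float                    # moisture diffusion coefficient, m^2/s
    nu: float                   # kinematic viscosity of air, m^2/s
    alpha: float                # thermal diffusivity, m^2/s
    Cp_meas: float              # measured specific heat, J/(kg K)
    k: float                    # thermal conductivity, W/(m K)

    def __post_init__(self) -> None:
        if self.formulation not in ("control", "guar"):
            raise DomainError(f"unknown formulation {self.formulation!r}")
        positive = (
            "P_sat", "T0", "W0", "r", "rho", "rho_s", "h",
            "lambda_v_ref", "D", "nu", "alpha", "Cp_meas", "k",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if not 0 <= self.RH <= 100:
            raise DomainError("RH must lie in [0, 100] %")
        if not 0 < self.epsilon <= 1:
            raise DomainError("emissivity must lie in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        names = {f.name for f in fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
        # YAML 1.1 reads exponents without a sign (e.g. 2.33e6) as strings.
        coerced = {
            key: value if key == "formulation" else float(value)
            for key, value in raw.items()
        }
        return cls(**coerced)

    def to_file(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def replace(self, **changes) -> "ParameterSet":
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update(changes)
        return ParameterSet(**data)


def load_parameters(formulation: str) -> ParameterSet:
    """Load a packaged parameter set (``"control"`` or ``"guar"``)."""
    ref = resources.files("toastbake").joinpath(f"data/{formulation}.params")
    with resources.as_file(ref) as path:
        return ParameterSet.from_file(path)


@dataclass(frozen=True)
class PhysicalConstants:
    """Universal constants of the surface transfer closure.

    The molar masses, atmospheric pressure and air heat capacity appear in
    the Chilton–Colburn analogy; standard values are supplied and all are
    overridable.  ``kg_correction`` is the empirical correction factor
    applied to the analogy's raw mass-transfer coefficient.
    """

    sigma: float = 5.67e-8          # Stefan–Boltzmann constant, W/(m^2 K^4)
    M_air: float = 0.028966         # molar mass of dry air, kg/mol
    M_w: float = 0.018015           # molar mass of water, kg/mol
    P_atm: float = 101_325.0        # atmospheric pressure, Pa
    Cp_air: float = 1006.0          # specific heat of air, J/(kg K)
    kg_correction: float = 7.83e-3  # empirical correction of kg*

    def __post_init__(self) -> None:
        for name in ("sigma", "M_air", "M_w", "P_atm", "Cp_air", "kg_correction"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# Specific heats and latent heat
# ---------------------------------------------------------------------------


def specific_heat_solid(T):
    """Specific heat of the dry solid matrix, ``5 T + 24`` J/(kg K)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("temperature must be positive (kelvin)")
    out = 5.0 * T + 24.0
    return float(out) if out.ndim == 0 else out


def specific_heat_water(T, coeffs: tuple[float, float, float] = CP_WATER_COEFFS):
    """Specific heat of liquid water, ``(c0 + c1 T + c2 T^2) * 1000`` J/(kg K).

    The quadratic-in-T polynomial (times 1000, i.e. coefficients in kJ) is the
    standard shape for liquid-water Cp; the default coefficients give values
    in the 4.1–4.4 kJ/(kg K) band over 273–500 K.  Restricted to 200–600 K.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 200.0) or np.any(T > 600.0):
        raise DomainError("liquid-water Cp correlation valid for 200-600 K only")
    c0, c1, c2 = coeffs
    out = (c0 + c1 * T + c2 * T * T) * 1000.0
    return float(out) if out.ndim == 0 else out


def latent_heat(T):
    """Latent heat of vaporization of water, J/kg, linear in (T - 273)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("temperature must be positive (kelvin)")
    out = 2_502_535.259 - 212.56384 * (T - 273.0)
    return float(out) if out.ndim == 0 else out


def smoothed_delta(T, center: float = BOILING_POINT_K, width: float = DEFAULT_DELTA_WIDTH_K):
    """Normalized Gaussian peak in temperature (unit integral over T, 1/K).

    Used by the apparent-heat-capacity method to smear the latent heat of the
    evaporation front over a narrow band around the boiling point instead of
    tracking the front explicitly.
    """
    if width <= 0:
        raise DomainError("delta width must be positive")
    T = np.asarray(T, dtype=float)
    z = (T - center) / width
    out = np.exp(-0.5 * z * z) / (width * math.sqrt(2.0 * math.pi))
    return float(out) if out.ndim == 0 else out


def apparent_specific_heat(
    T,
    W,
    params: ParameterSet | None = None,
    *,
    delta_mode: str = "smoothed",
    delta_width: float = DEFAULT_DELTA_WIDTH_K,
    cp_water_coeffs: tuple[float, float, float] = CP_WATER_COEFFS,
):
    """Apparent specific heat ``Cp* + lambda_v(T) W delta(T)`` in J/(kg K).

    ``Cp* = Cp_s(T) + W Cp_w(T)`` is the sensible part.  The evaporation term
    adds the latent heat of the water present:

    * ``delta_mode="smoothed"`` (default): delta is a normalized Gaussian at
      373.15 K with standard deviation ``delta_width`` (K), the standard
      apparent-heat-capacity treatment — integrating ``Cp - Cp*`` across the
      peak recovers ``lambda_v(373.15) * W`` exactly;
    * ``delta_mode="literal"``: delta is the tabulated constant
      (``params.delta_const``, 1 by default), which spreads the latent heat
      over every kelvin of heating.
    """
    T = np.asarray(T, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise DomainError("moisture content W must be non-negative")
    cp_star = specific_heat_solid(T) + W * specific_heat_water(T, cp_water_coeffs)
    if delta_mode == "smoothed":
        delta = smoothed_delta(T, width=delta_width)
    elif delta_mode == "literal":
        delta = (params.delta_const if params is not None else 1.0) * np.ones_like(T)
    else:
        raise DomainError(f"unknown delta_mode {delta_mode!r}")
    out = cp_star + latent_heat(T) * W * delta
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Water activity and vapor pressures
# ---------------------------------------------------------------------------


def water_activity(T, W, *, c: float = AW_C, slope: float = AW_SLOPE, power: float = AW_POWER):
    """Water activity ``a_w(T, W)`` of the dough, in [0, 1].

    Implements ``a_w = [(100 W exp(slope*T + c))^(-power) + 1]^(-1)`` computed
    in log space so that extreme arguments neither overflow nor underflow.
    ``a_w -> 0`` as ``W -> 0`` and ``a_w -> 1`` as ``W -> inf``; it is
    non-decreasing in ``W`` at fixed ``T``.  With the printed constant
    ``c = 55`` the relation saturates at 1 for any realistic moisture; the
    alternate reading ``c = 5.5`` can be passed instead.
    """
    T = np.asarray(T, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise DomainError("moisture content W must be non-negative")
    if np.any(T <= 0):
        raise DomainError("temperature must be positive (kelvin)")
    with np.errstate(divide="ignore"):
        log_inner = np.log(100.0 * W) + slope * T + c  # ln of (100 W e^{...})
    # a_w = 1 / (exp(-power * log_inner) + 1): a logistic in log_inner.
    expo = np.clip(-power * log_inner, -700.0, 700.0)
    out = np.where(np.isneginf(log_inner), 0.0, 1.0 / (np.exp(expo) + 1.0))
    return float(out) if out.ndim == 0 else out


# Antoine constants for water, log10(P/mmHg) = A - B/(C + T_C).
_ANTOINE_LOW = (8.07131, 1730.63, 233.426)     # 1-100 C
_ANTOINE_HIGH = (8.14019, 1810.94, 244.485)    # 99-374 C
_MMHG_TO_PA = 133.322


def saturation_pressure(T, params: ParameterSet | None = None, mode: str = "constant"):
    """Saturation vapor pressure of water, Pa.

    ``mode="constant"`` (default) returns the tabulated single value
    (``params.P_sat``, 0.98e5 Pa); ``mode="correlation"`` evaluates an
    Antoine-type correlation so that ``P_sat`` grows with temperature, which
    matters when the surface passes the boiling point.
    """
    T = np.asarray(T, dtype=float)
    if mode == "constant":
        p = params.P_sat if params is not None else 0.98e5
        out = np.full_like(T, float(p))
    elif mode == "correlation":
        if np.any(T <= 0):
            raise DomainError("temperature must be positive (kelvin)")
        Tc = T - 273.15
        A_lo, B_lo, C_lo = _ANTOINE_LOW
        A_hi, B_hi, C_hi = _ANTOINE_HIGH
        log10p = np.where(
            Tc < 99.0,
            A_lo - B_lo / (C_lo + Tc),
            A_hi - B_hi / (C_hi + Tc),
        )
        out = _MMHG_TO_PA * 10.0 ** log10p
    else:
        raise DomainError(f"unknown P_sat mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def surface_vapor_pressure(
    Ts,
    Ws,
    params: ParameterSet,
    *,
    psat_mode: str = "constant",
    aw_c: float = AW_C,
):
    """Vapor pressure at the bread surface, ``a_w(Ts, Ws) * P_sat(Ts)`` in Pa."""
    aw = water_activity(Ts, Ws, c=aw_c)
    return aw * saturation_pressure(Ts, params, mode=psat_mode)


def ambient_vapor_pressure(T_inf, RH, params: ParameterSet, *, psat_mode: str = "constant"):
    """Vapor pressure of the oven air, ``(RH/100) * P_sat(T_inf)`` in Pa."""
    RH = np.asarray(RH, dtype=float)
    if np.any(RH < 0) or np.any(RH > 100):
        raise DomainError("RH must lie in [0, 100] %")
    out = (RH / 100.0) * saturation_pressure(T_inf, params, mode=psat_mode)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Chilton–Colburn mass-transfer closure
# ---------------------------------------------------------------------------


class MassTransferResult(NamedTuple):
    """Corrected mass-transfer coefficient with its intermediates."""

    kg: float        # corrected coefficient, kg/(Pa m^2 s)
    kg_star: float   # raw analogy coefficient, kg/(Pa m^2 s)
    Sc: float        # Schmidt number
    Pr: float        # Prandtl number


def mass_transfer_coefficient(
    h: float,
    params: ParameterSet,
    consts: PhysicalConstants = PhysicalConstants(),
) -> MassTransferResult:
    """Convert the heat-transfer coefficient ``h`` to a mass-transfer one.

    Chilton–Colburn analogy:
    ``kg* = h / [(M_air/M_w) P_atm Cp_air (Sc/Pr)^(2/3)]`` with
    ``Sc = nu/D`` and ``Pr = nu/alpha``, then ``kg = correction * kg*``.
    ``kg`` scales linearly in ``h``.
    """
    if h <= 0:
        raise DomainError("h must be strictly positive")
    if params.D <= 0 or params.alpha <= 0:
        raise DomainError("D and alpha must be strictly positive")
    Sc = params.nu / params.D
    Pr = params.nu / params.alpha
    denom = (consts.M_air / consts.M_w) * consts.P_atm * consts.Cp_air * (Sc / Pr) ** (2.0 / 3.0)
    kg_star = h / denom
    kg = consts.kg_correction * kg_star
    return MassTransferResult(kg=kg, kg_star=kg_star, Sc=Sc, Pr=Pr)
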