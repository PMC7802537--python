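"""Reduction of raw lab measurements to thermophysical properties.

Two instruments are covered:

* **Mixing calorimetry** for specific heat capacity: a thermally isolated
  flask is calibrated by mixing hot and cold water, an aluminium capsule is
  calibrated against the flask, and the bread sample's specific heat follows
  from the equilibrium temperature reached by the hot capsule + sample in
  cold water.
* **Transient hot wire** for thermal conductivity: a line heat source of
  known power raises the temperature of the surrounding sample; in the
  intermediate-time regime the temperature grows linearly in ln(t) and the
  conductivity is ``k = I^2 R' / (4 pi S)`` with ``S`` the T-vs-ln(t) slope
  and ``R'`` the heater resistance per unit length.

The printed groupings of the calorimetry relations are ambiguous in places;
each reduction takes a ``grouping`` argument ("tight" — the default reading,
with the flask term grouped as ``(Hf + Mcw Cw)`` — or "loose", where
``Mcw Cw`` multiplies the temperature rise on its own) so alternates can be
evaluated.  All reductions are covered by synthetic round-trip tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .properties import DomainError

__all__ = [
    "CalorimetryRecord",
    "HotWireRecord",
    "DegenerateRunError",
    "flask_heat_capacity",
    "capsule_heat_capacity",
    "sample_specific_heat",
    "fit_log_slope",
    "hotwire_conductivity",
    "read_calorimetry_csv",
    "read_hotwire_csv",
]

#: Default heat capacity of liquid water used in calorimetry, J/(kg K).
WATER_HEAT_CAPACITY = 4186.0


class DegenerateRunError(ValueError):
    """A measurement run carries no usable signal (e.g. zero temperature drop)."""


@dataclass(frozen=True)
class CalorimetryRecord:
    """One calorimetry run (fields unused by a given stage may be None).

    Masses in kg, temperatures in K.  ``C_w`` is the heat capacity of water
    in J/(kg K).  A valid mixing run has ``T_hw > T_e > T_cw``.
    """

    M_cw: float                     # cold water mass
    T_cw: float                     # cold water temperature
    T_e: float                      # equilibrium temperature
    C_w: float = WATER_HEAT_CAPACITY
    M_hw: float | None = None       # hot water mass (flask calibration)
    T_hw: float | None = None       # hot water temperature (flask calibration)
    T_c: float | None = None        # capsule temperature (capsule calibration)
    M_m: float | None = None        # sample mass (sample run)
    T_m: float | None = None        # sample temperature (sample run)

    def __post_init__(self) -> None:
        for name in ("M_cw", "C_w"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        for name in ("M_hw", "M_m"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class HotWireRecord:
    """One transient hot-wire run.

    ``I`` is the heater current (A), ``R`` the total wire resistance (Ohm),
    ``heater_length`` the wire length (m), and ``samples`` the recorded
    (time s, temperature K) trace, strictly increasing in time.
    """

    I: float
    R: float
    samples: tuple
    heater_length: float = 0.235

    def __post_init__(self) -> None:
        if self.I <= 0 or self.R <= 0 or self.heater_length <= 0:
            raise DomainError("I, R and heater_length must be strictly positive")
        t = np.asarray([s[0] for s in self.samples], dtype=float)
        if t.size < 10:
            raise DomainError("a hot-wire record needs at least 10 samples")
        if np.any(t <= 0):
            raise DomainError("sample times must be positive")
        if np.any(np.diff(t) <= 0):
            raise DomainError("sample times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([s[0] for s in self.samples], dtype=float)

    @property
    def temperatures(self) -> np.ndarray:
        return np.asarray([s[1] for s in self.samples], dtype=float)

    @property
    def resistance_per_length(self) -> float:
        return self.R / self.heater_length

    @property
    def power_per_length(self) -> float:
        """Dissipated line power q = I^2 R', W/m."""
        return self.I**2 * self.resistance_per_length


# ---------------------------------------------------------------------------
# Calorimetry (mixing method)
# ---------------------------------------------------------------------------


def flask_heat_capacity(rec: CalorimetryRecord) -> float:
    """Heat capacity of the calorimeter flask, J/K.

    ``Hf = [Mcw Cw (Te - Tcw) - Mhw Cw (Thw - Te)] / (Thw - Te)``.
    A lossless symmetric mix (equal masses, equal temperature swings) gives
    exactly zero.
    """
    if rec.M_hw is None or rec.T_hw is None:
        raise DomainError("flask calibration requires M_hw and T_hw")
    if rec.T_hw == rec.T_e:
        raise DegenerateRunError("T_hw equals T_e: no temperature drop to evaluate")
    num = rec.M_cw * rec.C_w * (rec.T_e - rec.T_cw) - rec.M_hw * rec.C_w * (rec.T_hw - rec.T_e)
    return num / (rec.T_hw - rec.T_e)


def capsule_heat_capacity(rec: CalorimetryRecord, Hf: float, grouping: str = "tight") -> float:
    """Heat capacity of the aluminium sample capsule, J/K.

    Default ("tight") grouping: ``Hc = (Hf + Mcw Cw)(Te - Tcw) / (Tc - Te)``.
    The "loose" alternate reads ``Hc = [Hf + Mcw Cw (Te - Tcw)] / (Tc - Te)``.
    """
    if rec.T_c is None:
        raise DomainError("capsule calibration requires T_c")
    if rec.T_c == rec.T_e:
        raise DegenerateRunError("T_c equals T_e: no temperature drop to evaluate")
    if grouping == "tight":
        num = (Hf + rec.M_cw * rec.C_w) * (rec.T_e - rec.T_cw)
    elif grouping == "loose":
        num = Hf + rec.M_cw * rec.C_w * (rec.T_e - rec.T_cw)
    else:
        raise DomainError(f"unknown grouping {grouping!r}")
    return num / (rec.T_c - rec.T_e)


def sample_specific_heat(
    rec: CalorimetryRecord, Hf: float, Hc: float, grouping: str = "tight"
) -> float:
    """Specific heat capacity of the bread sample, J/(kg K).

    Default grouping:
    ``Cp = [(Hf + Mcw Cw)(Te - Tcw) - Hc (Tm - Te)] / [Mm (Tm - Te)]``.
    """
    if rec.M_m is None or rec.T_m is None:
        raise DomainError("a sample run requires M_m and T_m")
    if rec.T_m == rec.T_e:
        raise DegenerateRunError("T_m equals T_e: no temperature drop to evaluate")
    if grouping == "tight":
        absorbed = (Hf + rec.M_cw * rec.C_w) * (rec.T_e - rec.T_cw)
    elif grouping == "loose":
        absorbed = Hf + rec.M_cw * rec.C_w * (rec.T_e - rec.T_cw)
    else:
        raise DomainError(f"unknown grouping {grouping!r}")
    num = absorbed - Hc * (rec.T_m - rec.T_e)
    return num / (rec.M_m * (rec.T_m - rec.T_e))


# ---------------------------------------------------------------------------
# Hot wire (line heat source)
# ---------------------------------------------------------------------------


def fit_log_slope(
    samples: Sequence | HotWireRecord,
    window: tuple[int, int] | str = "auto",
) -> tuple[float, float]:
    """Slope ``S`` (K per ln s) and R^2 of temperature against ln(time).

    ``window`` selects the sample range to fit: an explicit ``(start, stop)``
    index pair (stop exclusive), or ``"auto"``, which scans every contiguous
    window of at least half the samples and keeps the one with the highest
    coefficient of determination (ties broken toward the earliest window).
    The slope is invariant to rescaling the time unit; only the intercept
    shifts.
    """
    if isinstance(samples, HotWireRecord):
        t, T = samples.times, samples.temperatures
    else:
        arr = np.asarray(samples, dtype=float)
        t, T = arr[:, 0], arr[:, 1]
    if np.any(t <= 0):
        raise DomainError("sample times must be positive")
    x = np.log(t)

    def ols(i0: int, i1: int) -> tuple[float, float]:
        xs, ys = x[i0:i1], T[i0:i1]
        if np.ptp(ys) == 0:
            raise DegenerateRunError("constant temperature trace: slope undefined")
        sxx = np.sum((xs - xs.mean()) ** 2)
        if sxx == 0:
            raise DegenerateRunError("degenerate window: identical times")
        sxy = np.sum((xs - xs.mean()) * (ys - ys.mean()))
        slope = sxy / sxx
        resid = ys - (ys.mean() + slope * (xs - xs.mean()))
        ss_tot = np.sum((ys - ys.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        return slope, r2

    n = t.size
    if window == "auto":
        min_len = max(5, (n + 1) // 2)
        best: tuple[float, float] | None = None
        best_start = -1
        for length in range(n, min_len - 1, -1):
            for start in range(0, n - length + 1):
                try:
                    slope, r2 = ols(start, start + length)
                except DegenerateRunError:
                    continue
                # strict improvement keeps the earliest window on ties
                if best is None or r2 > best[1] + 1e-15:
                    best, best_start = (slope, r2), start
        if best is None:
            raise DegenerateRunError("no usable fitting window found")
        return best
    i0, i1 = window
    if i1 - i0 < 5:
        raise DomainError("fitting window must contain at least 5 points")
    return ols(i0, i1)


def hotwire_conductivity(
    rec: HotWireRecord,
    window: tuple[int, int] | str = "auto",
    resistance_mode: str = "per_length",
) -> float:
    """Thermal conductivity from a hot-wire run, ``k = I^2 R' / (4 pi S)``.

    ``resistance_mode="per_length"`` (default) derives the line resistance
    from the total resistance and heater length, which is what dimensional
    analysis of the line-source solution requires; ``"total"`` uses the
    recorded resistance literally.
    """
    S, _ = fit_log_slope(rec, window=window)
    if S <= 0:
        raise DegenerateRunError("non-positive log-time slope: invalid run")
    if resistance_mode == "per_length":
        R = rec.resistance_per_length
    elif resistance_mode == "total":
        R = rec.R
    else:
        raise DomainError(f"unknown resistance_mode {resistance_mode!r}")
    return rec.I**2 * R / (4.0 * math.pi * S)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CAL_COLUMNS = ("M_cw", "T_cw", "T_e", "C_w", "M_hw", "T_hw", "T_c", "M_m", "T_m")


def read_calorimetry_csv(path) -> list[CalorimetryRecord]:
    """Read calorimetry runs, one row per run; empty cells become None."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _CAL_COLUMNS:
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        records.append(CalorimetryRecord(**kwargs))
    return records


def read_hotwire_csv(path) -> HotWireRecord:
    """Read a hot-wire trace: long format with constant metadata columns.

    Expected columns: ``time_s``, ``temperature_K``, ``I_A``, ``R_ohm`` and
    optionally ``heater_length_m``.
    """
    df = pd.read_csv(path)
    kwargs = {}
    if "heater_length_m" in df.columns:
        kwargs["heater_length"] = float(df["heater_length_m"].iloc[0])
    return HotWireRecord(
        I=float(df["I_A"].iloc[0]),
        R=float(df["R_ohm"].iloc[0]),
        samples=tuple(zip(df["time_s"].astype(float), df["temperature_K"].astype(float))),
        **kwargs,
    )
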