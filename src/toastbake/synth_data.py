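"""Synthetic datasets with known ground truth for every pipeline input.

The study's raw measurements are not published; this module generates
stand-ins that follow the same experimental design:

* pseudo-experimental bake curves — the deterministic model sampled at the
  8 sampling times (5..40 min) for the 5 oven temperatures and 2
  formulations, with independent Gaussian measurement noise per replicate
  (3 replicates by default);
* calorimetry record sets constructed to be exactly consistent with chosen
  true flask/capsule heat capacities and sample specific heat, so the
  reductions invert them to the generating truth;
* hot-wire traces from the line-source model ``T(t) = T0 + q/(4 pi k) ln t``
  sampled every 3 s, with the power per unit length inside the instrument's
  2.5-6 W/m operating range and the total temperature rise kept within the
  observed 5-14 K band.

Every generator draws all randomness from one explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baking_sim import solve_bake
from .lab_reduction import (
    CalorimetryRecord,
    HotWireRecord,
)
from .properties import DomainError

__all__ = [
    "NoiseSpec",
    "CalorimetrySet",
    "generate_bake_dataset",
    "mean_curves",
    "generate_calorimetry",
    "generate_hotwire",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for pseudo-experimental bake curves.

    ``sd_T`` is the crust-temperature noise (K, equivalently deg C on the
    reported scale), ``sd_WL`` the weight-loss noise in percentage points.
    The defaults are stand-ins chosen at the scale of thermocouple and
    balance repeatability; nothing downstream depends on their exact values.
    """

    sd_T: float = 1.5           # K
    sd_WL: float = 0.8          # percentage points
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_T < 0 or self.sd_WL < 0:
            raise DomainError("noise standard deviations must be non-negative")
        if self.replicates < 1:
            raise DomainError("at least one replicate is required")


def generate_bake_dataset(configs, noise: NoiseSpec) -> pd.DataFrame:
    """Pseudo-experimental bake table for a sweep of configurations.

    Runs ``solve_bake`` for each config, samples the configured sampling
    times, and adds independent Gaussian noise per replicate.  Returns one
    row per (config, sampling time, replicate) — the full study design (2
    formulations x 5 oven temperatures x 8 times x 3 replicates) gives 240
    rows — with both the noiseless model value and the noisy measurement,
    so predicted/experimental pairs need no second solve.  Fully
    reproducible from ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    rows = []
    for cfg in configs:
        result = solve_bake(cfg)
        for t in result.sample_times:
            at = result.at(t)
            for rep in range(1, noise.replicates + 1):
                rows.append({
                    "formulation": cfg.params.formulation,
                    "T_oven_C": cfg.T_oven - 273.15,
                    "time_min": t / 60.0,
                    "replicate": rep,
                    "model_crust_T_C": at["crust_T_C"],
                    "model_weight_loss_pct": at["weight_loss_pct"],
                    "crust_T_C": at["crust_T_C"] + rng.normal(0.0, noise.sd_T),
                    "weight_loss_pct": at["weight_loss_pct"] + rng.normal(0.0, noise.sd_WL),
                })
    return pd.DataFrame(rows)


def mean_curves(dataset: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean experimental curves of a generated bake dataset."""
    keys = ["formulation", "T_oven_C", "time_min"]
    agg = dataset.groupby(keys, as_index=False).agg(
        model_crust_T_C=("model_crust_T_C", "mean"),
        model_weight_loss_pct=("model_weight_loss_pct", "mean"),
        crust_T_C=("crust_T_C", "mean"),
        weight_loss_pct=("weight_loss_pct", "mean"),
        n_replicates=("replicate", "size"),
    )
    return agg


# ---------------------------------------------------------------------------
# Calorimetry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalorimetrySet:
    """The three runs of one calorimetry campaign (flask, capsule, sample)."""

    flask: CalorimetryRecord
    capsule: CalorimetryRecord
    sample: CalorimetryRecord


def generate_calorimetry(
    true_Hf: float,
    true_Hc: float,
    true_Cp: float,
    seed: int = 0,
    noise_sd_T: float = 0.0,
    *,
    M_cw: float = 0.12,
    M_hw: float = 0.10,
    C_w: float = 4186.0,
    T_cw: float = 296.15,
    T_hw: float = 343.15,
    T_c: float = 368.15,
    T_m: float = 368.15,
    M_m: float = 0.015,
) -> CalorimetrySet:
    """Calorimetry records exactly consistent with the given truths.

    Each stage's equilibrium temperature is obtained by inverting the
    corresponding reduction, so at zero noise the reductions recover
    ``true_Hf``, ``true_Hc`` and ``true_Cp`` to round-off.  Optional
    Gaussian noise (``noise_sd_T``, K) perturbs the recorded equilibrium
    temperatures.  Generated runs honor ``T_hw > T_e > T_cw``.
    """
    for name, v in (("true_Hf", true_Hf), ("true_Hc", true_Hc), ("true_Cp", true_Cp)):
        if v <= 0:
            raise DomainError(f"{name} must be strictly positive")
    rng = np.random.default_rng(seed)
    A = M_cw * C_w
    B = M_hw * C_w

    # flask: Hf = [A (Te-Tcw) - B (Thw-Te)] / (Thw-Te)  =>  solve for Te
    Te_f = (A * T_cw + (B + true_Hf) * T_hw) / (A + B + true_Hf)
    # capsule: Hc = (Hf + A)(Te-Tcw)/(Tc-Te)
    Te_c = (true_Hc * T_c + (true_Hf + A) * T_cw) / (true_Hc + true_Hf + A)
    # sample: Cp Mm (Tm-Te) = (Hf + A)(Te-Tcw) - Hc (Tm-Te)
    CM = true_Cp * M_m
    Te_s = ((CM + true_Hc) * T_m + (true_Hf + A) * T_cw) / (CM + true_Hc + true_Hf + A)

    if noise_sd_T > 0:
        Te_f += rng.normal(0.0, noise_sd_T)
        Te_c += rng.normal(0.0, noise_sd_T)
        Te_s += rng.normal(0.0, noise_sd_T)

    if not (T_hw > Te_f > T_cw):
        raise DomainError("generated flask run violates T_hw > T_e > T_cw")
    return CalorimetrySet(
        flask=CalorimetryRecord(M_cw=M_cw, M_hw=M_hw, C_w=C_w,
                                T_cw=T_cw, T_hw=T_hw, T_e=Te_f),
        capsule=CalorimetryRecord(M_cw=M_cw, C_w=C_w, T_cw=T_cw, T_c=T_c, T_e=Te_c),
        sample=CalorimetryRecord(M_cw=M_cw, C_w=C_w, T_cw=T_cw,
                                 T_m=T_m, M_m=M_m, T_e=Te_s),
    )


# ---------------------------------------------------------------------------
# Hot wire
# ---------------------------------------------------------------------------

#: Observed temperature-rise band of the instrument, K.
HOTWIRE_RISE_BAND = (5.0, 14.0)


def generate_hotwire(
    true_k: float,
    I: float = 0.32,
    R: float = 11.49,
    seed: int = 0,
    noise_sd_T: float = 0.0,
    *,
    heater_length: float = 0.235,
    T0: float = 298.15,
    t_start: float = 3.0,
    t_end: float = 120.0,
    dt: float = 3.0,
) -> HotWireRecord:
    """Hot-wire trace from the line-source model with known conductivity.

    ``T(t) = T0 + [q / (4 pi k)] ln t`` with ``q = I^2 R / heater_length``,
    sampled every ``dt`` seconds (the logger's 3 s cadence).  If the rise
    from ``t_start`` to ``t_end`` would exceed the instrument's observed
    14 K band the duration is shortened accordingly.
    """
    if true_k <= 0 or I <= 0 or R <= 0:
        raise DomainError("true_k, I and R must be strictly positive")
    rng = np.random.default_rng(seed)
    q = I**2 * (R / heater_length)
    slope = q / (4.0 * math.pi * true_k)
    max_rise = HOTWIRE_RISE_BAND[1]
    # clamp the duration so slope * ln(t_end/t_start) <= max_rise
    t_cap = t_start * math.exp(max_rise / slope)
    t_end = min(t_end, t_cap)
    # keep at least 10 samples even when the rise cap shortens the trace
    if (t_end - t_start) / dt < 9.0:
        dt = (t_end - t_start) / 9.0
    times = np.arange(t_start, t_end + dt / 2, dt)
    temps = T0 + slope * np.log(times)
    if noise_sd_T > 0:
        temps = temps + rng.normal(0.0, noise_sd_T, size=times.size)
    return HotWireRecord(
        I=I, R=R, heater_length=heater_length,
        samples=tuple(zip(times.tolist(), temps.tolist())),
    )
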