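"""Coupled 1D radial heat- and moisture-transfer solver for bread baking.

The loaf is treated as an infinite cylinder of radius ``r``.  Heat moves
inward by conduction,

    rho Cp(T, W) dT/dt = (1/r) d/dr ( r k dT/dr ),

with a combined convective + radiative flux at the surface,

    -k dT/dr |_R = h (Ts - T_oven) + eps sigma (Ts^4 - T_oven^4),

and liquid moisture (dry basis) by Fickian diffusion,

    dW/dt = (1/r) d/dr ( r D dW/dr ),

with an evaporative surface flux driven by the vapor-pressure difference
between the surface and the oven air,

    -D rho_s dW/dr |_R = kg (Ps(Ts, Ws) - Pinf),

where ``kg`` comes from the Chilton–Colburn analogy.  Both fields obey
zero-gradient symmetry at the axis.  The latent heat of the crumb->crust
evaporation front enters through the apparent specific heat ``Cp(T, W)``
(smoothed-Dirac peak at the boiling point by default), so no explicit front
tracking is needed; crust/crumb are diagnostic labels on the temperature
field.

Discretization is a conservative node-centered finite-volume scheme on a
uniform radial grid (second order; the axis singularity is handled by the
half-cell volume at r = 0), integrated in time with SciPy's stiff BDF method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .properties import (
    BOILING_POINT_K,
    DomainError,
    ParameterSet,
    PhysicalConstants,
    ambient_vapor_pressure,
    apparent_specific_heat,
    latent_heat,
    mass_transfer_coefficient,
    specific_heat_solid,
    specific_heat_water,
    surface_vapor_pressure,
)

__all__ = [
    "RadialGrid",
    "BakeState",
    "BakeConfig",
    "BakeResult",
    "SolverError",
    "PAPER_SAMPLE_TIMES_S",
    "PAPER_OVEN_TEMPS_C",
    "printed_config",
    "solve_bake",
    "weight_loss_series",
    "crust_temperature_series",
    "run_grid",
    "paper_sweep_configs",
]

#: The study's sampling times (5..40 min) in seconds.
PAPER_SAMPLE_TIMES_S = tuple(60.0 * m for m in (5, 10, 15, 20, 25, 30, 35, 40))

#: The study's oven settings, deg C.
PAPER_OVEN_TEMPS_C = (190, 200, 210, 220, 230)

#: Default initial dough temperature (K); 24 C, consistent with the reported
#: t = 0 crust temperature.  The tabulated 293 K is selectable via ``T0``.
DEFAULT_T0_K = 297.15

#: Fraction of the initial moisture below which the surface drying flux is
#: ramped smoothly to zero (regularizes complete local dry-out).
DRYOUT_RAMP_FRACTION = 1e-3

#: Default liquid (crumb) moisture diffusivities, m^2/s, per formulation.
#: Guar gum binds water and lowers liquid moisture mobility, hence the lower
#: guar value.  Calibrated against the reported 40-min crust temperatures at
#: 190 and 230 C; within the typical range for doughs.
DEFAULT_D_CRUMB = {"control": 5.0e-8, "guar": 3.0e-8}


class SolverError(RuntimeError):
    """The time integration failed; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class RadialGrid:
    """Uniform node-centered radial grid; node 0 on the axis, last at the surface."""

    n_nodes: int
    radius: float

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise DomainError("n_nodes must be at least 10")
        if self.radius <= 0:
            raise DomainError("radius must be positive")

    @property
    def dr(self) -> float:
        return self.radius / (self.n_nodes - 1)

    @property
    def node_positions(self) -> np.ndarray:
        return np.linspace(0.0, self.radius, self.n_nodes)

    @property
    def face_positions(self) -> np.ndarray:
        """Radii of the interior cell faces (midpoints between nodes)."""
        r = self.node_positions
        return 0.5 * (r[1:] + r[:-1])

    @property
    def cell_volumes(self) -> np.ndarray:
        """Cell measures ``int r dr`` per unit angle and length.

        Their sum is exactly ``radius^2 / 2``, which makes the scheme
        discretely conservative.
        """
        r = self.node_positions
        dr = self.dr
        lo = np.maximum(r - dr / 2.0, 0.0)
        hi = np.minimum(r + dr / 2.0, self.radius)
        return 0.5 * (hi**2 - lo**2)

    def volume_average(self, f: np.ndarray) -> np.ndarray:
        """Volume-weighted cross-section average of a nodal field."""
        v = self.cell_volumes
        return np.asarray(f) @ v / v.sum()


@dataclass(frozen=True)
class BakeState:
    """Snapshot of the radial temperature and moisture fields."""

    t: float            # s
    T: np.ndarray       # K, per node
    W: np.ndarray       # kg/kg dry basis, per node


@dataclass(frozen=True)
class BakeConfig:
    """Full specification of one bake simulation.

    The default configuration is the package's physically closed model:
    liquid moisture diffuses through the crumb (``moisture_mode="front"``
    with a formulation-specific ``D_crumb``), water crossing the boiling
    point vaporizes and vents through the porous crust (first-order sink,
    ``tau_vent``), the surface evaporative flux carries its latent heat out
    of the energy balance (``surface_evap_cooling``), and the surface vapor
    pressure follows an Antoine correlation (``psat_mode="correlation"``).

    Every switch can be set back to the literal tabulated reading (see
    :func:`printed_config`): a single uniform moisture diffusivity equal to
    the tabulated ``D``, constant saturation pressure, and no surface latent
    term.  Mode switches are echoed into the result metadata:

    * ``delta_mode`` — evaporation-peak treatment in the apparent Cp
      ("smoothed" Gaussian at 373.15 K, "literal" tabulated constant, or
      "off");
    * ``psat_mode`` / ``pinf_mode`` — saturation-pressure closure for the
      surface and for the oven-air reference;
    * ``moisture_mode`` — crumb/crust ("front") vs single-D ("uniform")
      moisture transport;
    * ``wl_basis`` — whether the parameter file's ``W0`` is read as dry- or
      wet-basis moisture;
    * ``aw_c`` — additive constant of the water-activity relation;
    * ``D`` / ``T0`` / ``h`` / ``kg`` — overrides of the tabulated transport
      parameters (``None`` = use the parameter set / analogy value).
    """

    params: ParameterSet
    T_oven: float                       # K
    duration: float = 2400.0            # s
    n_nodes: int = 101
    delta_mode: str = "smoothed"        # "smoothed" | "literal" | "off"
    delta_width: float = 0.5            # K
    psat_mode: str = "correlation"      # "constant" | "correlation" (surface P_sat)
    pinf_mode: str = "constant"         # ambient P_sat reference for Pinf
    wl_basis: str = "dry"               # "dry" | "wet"
    aw_c: float = 55.0
    T0: float | None = None             # K; None -> 297.15
    D: float | None = None              # m^2/s; None -> params.D
    moisture_mode: str = "front"        # "front" | "uniform"
    D_crumb: float | None = None        # liquid moisture diffusivity (front mode), m^2/s
    tau_vent: float = 60.0              # s, vapor escape time constant above boiling (front mode)
    D_switch_width: float = 2.0         # K, width of the crumb->crust transition
    h: float | None = None              # W/(m^2 K); None -> params.h
    kg: float | None = None             # kg/(Pa m^2 s); None -> Chilton-Colburn
    radiation: bool = True
    moisture: bool = True
    surface_evap_cooling: bool = True   # latent-heat sink lambda_v(Ts)*J at the surface
    constant_cp: float | None = None    # J/(kg K); bypasses the apparent Cp
    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = 5.0               # s
    sample_times: tuple = PAPER_SAMPLE_TIMES_S
    n_dense: int = 121                  # dense output grid size
    initial_W: tuple | None = None      # optional nonuniform initial profile
    consts: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DomainError("duration must be positive")
        if self.T_oven < self.resolved_T0:
            raise DomainError("T_oven must not be below the initial temperature")
        if self.delta_mode not in ("smoothed", "literal", "off"):
            raise DomainError(f"unknown delta_mode {self.delta_mode!r}")
        if self.psat_mode not in ("constant", "correlation"):
            raise DomainError(f"unknown psat_mode {self.psat_mode!r}")
        if self.pinf_mode not in ("constant", "correlation"):
            raise DomainError(f"unknown pinf_mode {self.pinf_mode!r}")
        if self.wl_basis not in ("dry", "wet"):
            raise DomainError(f"unknown wl_basis {self.wl_basis!r}")
        if self.moisture_mode not in ("uniform", "front"):
            raise DomainError(f"unknown moisture_mode {self.moisture_mode!r}")

    @property
    def resolved_T0(self) -> float:
        return DEFAULT_T0_K if self.T0 is None else self.T0

    @property
    def resolved_D_crumb(self) -> float:
        if self.D_crumb is not None:
            return self.D_crumb
        return DEFAULT_D_CRUMB.get(self.params.formulation, 5.0e-8)

    @property
    def W0_db(self) -> float:
        """Initial moisture on a dry basis under the configured reading."""
        w = self.params.W0
        if self.wl_basis == "wet":
            if w >= 1:
                raise DomainError("wet-basis W0 must be < 1")
            return w / (1.0 - w)
        return w

    def grid(self) -> RadialGrid:
        return RadialGrid(self.n_nodes, self.params.r)

    def mode_metadata(self) -> dict[str, Any]:
        return {
            "formulation": self.params.formulation,
            "T_oven_K": self.T_oven,
            "duration_s": self.duration,
            "n_nodes": self.n_nodes,
            "delta_mode": self.delta_mode,
            "delta_width_K": self.delta_width,
            "psat_mode": self.psat_mode,
            "pinf_mode": self.pinf_mode,
            "wl_basis": self.wl_basis,
            "aw_c": self.aw_c,
            "T0_K": self.resolved_T0,
            "D_m2s": self.params.D if self.D is None else self.D,
            "moisture_mode": self.moisture_mode,
            "D_crumb_m2s": self.resolved_D_crumb,
            "tau_vent_s": self.tau_vent,
            "h_Wm2K": self.params.h if self.h is None else self.h,
            "radiation": self.radiation,
            "moisture": self.moisture,
            "surface_evap_cooling": self.surface_evap_cooling,
            "constant_cp": self.constant_cp,
            "rtol": self.rtol,
            "atol": self.atol,
        }


@dataclass(frozen=True)
class BakeResult:
    """Solved bake: saved fields plus the derived reporting series.

    ``times`` is the dense output grid (it contains the 8 study sampling
    times); ``T``/``W`` have shape ``(len(times), n_nodes)``.  Crust and
    center temperatures are reported in deg C, weight loss in percent of the
    initial wet mass.
    """

    config: BakeConfig
    grid: RadialGrid
    times: np.ndarray
    T: np.ndarray
    W: np.ndarray
    crust_T: np.ndarray
    center_T: np.ndarray
    mean_W: np.ndarray
    weight_loss: np.ndarray
    metadata: dict

    @property
    def sample_times(self) -> np.ndarray:
        return np.asarray(self.config.sample_times, dtype=float)

    def states(self) -> list[BakeState]:
        return [BakeState(t, self.T[i], self.W[i]) for i, t in enumerate(self.times)]

    def at(self, t: float) -> dict[str, float]:
        """Interpolated reporting quantities at time ``t`` (s)."""
        return {
            "time_s": float(t),
            "crust_T_C": float(np.interp(t, self.times, self.crust_T)),
            "center_T_C": float(np.interp(t, self.times, self.center_T)),
            "mean_W_db": float(np.interp(t, self.times, self.mean_W)),
            "weight_loss_pct": float(np.interp(t, self.times, self.weight_loss)),
        }

    def to_frame(self, sample_only: bool = False) -> pd.DataFrame:
        """Long-format reporting table (time_s, crust_T_C, center_T_C, ...)."""
        if sample_only:
            rows = [self.at(t) for t in self.sample_times]
            return pd.DataFrame(rows)
        return pd.DataFrame(
            {
                "time_s": self.times,
                "crust_T_C": self.crust_T,
                "center_T_C": self.center_T,
                "mean_W_db": self.mean_W,
                "weight_loss_pct": self.weight_loss,
            }
        )

    def crust_thickness(self, i: int) -> float:
        """Radial depth (m) of the crust zone (T > 373.15 K) at saved step i."""
        r = self.grid.node_positions
        hot = self.T[i] > BOILING_POINT_K
        if not hot.any():
            return 0.0
        return float(self.grid.radius - r[hot].min())


def printed_config(params: ParameterSet, T_oven: float, **overrides) -> BakeConfig:
    """A :class:`BakeConfig` using the literal tabulated correlations.

    Single uniform moisture diffusivity equal to the tabulated ``D``,
    constant saturation pressure on both sides of the surface flux, and no
    surface latent-heat term — the model exactly as published.  Keyword
    overrides are passed through to :class:`BakeConfig`.
    """
    base = dict(
        params=params,
        T_oven=T_oven,
        moisture_mode="uniform",
        psat_mode="constant",
        pinf_mode="constant",
        surface_evap_cooling=False,
    )
    base.update(overrides)
    return BakeConfig(**base)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------


def _build_rhs(config: BakeConfig):
    """Assemble the method-of-lines right-hand side and its sparsity."""
    p = config.params
    grid = config.grid()
    n = grid.n_nodes
    dr = grid.dr
    R = grid.radius
    vol = grid.cell_volumes
    r_face = grid.face_positions

    k = p.k
    rho = p.rho
    rho_s = p.rho_s
    D = p.D if config.D is None else config.D
    h = p.h if config.h is None else config.h
    eps = p.epsilon if config.radiation else 0.0
    sigma = config.consts.sigma
    T_oven = config.T_oven
    if config.kg is not None:
        kg = config.kg
    elif config.moisture:
        kg = mass_transfer_coefficient(max(h, 1e-12), p, config.consts).kg
    else:
        kg = 0.0
    # Ambient vapor pressure of the oven air.  The default keeps the
    # tabulated saturation reference: oven air humidity is set by the
    # moisture load of the oven, and referencing it to saturation at the
    # oven temperature (>1 MPa at 463-503 K) would condense water onto the
    # loaf throughout the bake.
    P_inf = ambient_vapor_pressure(T_oven, p.RH, p, psat_mode=config.pinf_mode)
    W_ramp = DRYOUT_RAMP_FRACTION * config.W0_db

    def rhs(t, y):
        T = y[:n]
        W = np.maximum(y[n:], 0.0)
        # Implicit-solver trial iterates can transiently leave the physical
        # range; clamp property evaluation to the correlations' domain.
        Tp = np.clip(T, 250.0, 599.0)

        # --- heat -----------------------------------------------------
        if config.constant_cp is not None:
            cp = config.constant_cp
        elif config.delta_mode == "off":
            # sensible heat only (no evaporation peak)
            cp = specific_heat_solid(Tp) + W * specific_heat_water(Tp)
        else:
            cp = apparent_specific_heat(
                Tp, W, p, delta_mode=config.delta_mode, delta_width=config.delta_width
            )
        # --- moisture -------------------------------------------------
        dW = np.zeros(n)
        J = 0.0  # surface drying flux, kg water / (m^2 s), positive = drying
        if config.moisture:
            D_liq = config.resolved_D_crumb if config.moisture_mode == "front" else D
            G = r_face * D_liq * np.diff(W) / dr
            dW[0] = G[0]
            dW[1:-1] = np.diff(G)
            if kg != 0.0:
                Ps = surface_vapor_pressure(
                    Tp[-1], W[-1], p, psat_mode=config.psat_mode, aw_c=config.aw_c
                )
                J = kg * (Ps - P_inf)
                # C1 ramp: the evaporative exchange shuts off smoothly as the
                # surface dries out, regularizing the sorption step at W ~ 0.
                x = min(1.0, max(0.0, W[-1] / W_ramp))
                J *= x * x * (3.0 - 2.0 * x)
            dW[-1] = -G[-1] + R * (-J / rho_s)
            dW /= vol
            if config.moisture_mode == "front":
                # Water above the boiling point vaporizes and vents through
                # the porous crust (vapor diffusion there is orders of
                # magnitude faster than liquid diffusion, so escape is
                # modeled as a first-order local sink).
                z = np.clip((Tp - BOILING_POINT_K) / config.D_switch_width, -50.0, 50.0)
                dW -= W / config.tau_vent / (1.0 + np.exp(-z))

        # --- heat -----------------------------------------------------
        # interior conductive fluxes through faces (per unit angle/length)
        F = r_face * k * np.diff(T) / dr
        dT = np.empty(n)
        dT[0] = F[0]
        dT[1:-1] = np.diff(F)
        Ts = T[-1]
        q_in = h * (T_oven - Ts) + eps * sigma * (T_oven**4 - Ts**4)
        if config.surface_evap_cooling and J > 0.0:
            q_in -= latent_heat(Tp[-1]) * J
        dT[-1] = -F[-1] + R * q_in
        dT /= rho * cp * vol
        return np.concatenate([dT, dW])

    # Jacobian sparsity: tridiagonal blocks plus Cp(T,W) and Ps(Ts) couplings.
    spar = lil_matrix((2 * n, 2 * n))
    for i in range(n):
        for j in (i - 1, i, i + 1):
            if 0 <= j < n:
                spar[i, j] = 1
                spar[n + i, n + j] = 1
        spar[i, n + i] = 1          # Cp depends on local W
        spar[n + i, i] = 1          # vapor sink depends on local T
    spar[2 * n - 1, n - 1] = 1      # surface moisture flux depends on Ts
    return rhs, spar.tocsc(), grid, kg


def solve_bake(config: BakeConfig) -> BakeResult:
    """Solve one bake and derive the reporting series.

    Returns a :class:`BakeResult`; raises :class:`SolverError` on
    non-convergence or non-finite fields.  Moisture transiently driven below
    zero by discretization error is clipped to zero in the stored fields and
    the number of clipped values is logged in ``metadata["w_clip_events"]``.
    """
    rhs, sparsity, grid, kg = _build_rhs(config)
    n = grid.n_nodes
    T0 = config.resolved_T0
    W0 = config.W0_db
    if config.initial_W is not None:
        Winit = np.asarray(config.initial_W, dtype=float)
        if Winit.shape != (n,):
            raise DomainError("initial_W must have one value per node")
    else:
        Winit = np.full(n, W0)
    y0 = np.concatenate([np.full(n, T0), Winit])

    t_dense = np.linspace(0.0, config.duration, config.n_dense)
    t_eval = np.union1d(t_dense, [t for t in config.sample_times if t <= config.duration])

    sol = solve_ivp(
        rhs,
        (0.0, config.duration),
        y0,
        method="BDF",
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
        max_step=config.max_step,
        jac_sparsity=sparsity,
    )
    diagnostics = {
        "success": bool(sol.success),
        "message": sol.message,
        "n_rhs_evaluations": int(sol.nfev),
        "n_steps": int(sol.t.size),
        "kg": kg,
    }
    if not sol.success:
        raise SolverError(f"time integration failed: {sol.message}", diagnostics)

    T = sol.y[:n].T.copy()
    W = sol.y[n:].T.copy()
    if not (np.isfinite(T).all() and np.isfinite(W).all()):
        raise SolverError("non-finite fields in solution", diagnostics)

    clip_events = int((W < 0).sum())
    np.clip(W, 0.0, None, out=W)

    mean_W = np.array([grid.volume_average(w) for w in W])
    wl = weight_loss_from_mean(mean_W, W0)
    result = BakeResult(
        config=config,
        grid=grid,
        times=sol.t.copy(),
        T=T,
        W=W,
        crust_T=T[:, -1] - 273.15,
        center_T=T[:, 0] - 273.15,
        mean_W=mean_W,
        weight_loss=wl,
        metadata={**config.mode_metadata(), **diagnostics, "w_clip_events": clip_events},
    )
    return result


# ---------------------------------------------------------------------------
# Derived series
# ---------------------------------------------------------------------------


def weight_loss_from_mean(mean_W, W0_db: float):
    """Percent weight loss from the mean dry-basis moisture.

    ``WL(t) = 100 (W0 - Wbar(t)) / (1 + W0)`` — evaporated water as a
    fraction of the initial wet mass (dry solid + initial water).
    """
    mean_W = np.asarray(mean_W, dtype=float)
    out = 100.0 * (W0_db - mean_W) / (1.0 + W0_db)
    return float(out) if out.ndim == 0 else out


def weight_loss_series(result: BakeResult, params: ParameterSet | None = None,
                       basis: str | None = None) -> np.ndarray:
    """Weight-loss trajectory (%) of a solved bake.

    ``basis`` ("dry" | "wet") re-interprets the parameter file's ``W0``; by
    default the basis the bake was solved under is used.  Weight loss is
    zero at t = 0 and non-decreasing for heating problems.
    """
    params = params or result.config.params
    basis = basis or result.config.wl_basis
    if basis == "wet":
        w = params.W0
        if w >= 1:
            raise DomainError("wet-basis W0 must be < 1")
        W0 = w / (1.0 - w)
    elif basis == "dry":
        W0 = params.W0
    else:
        raise DomainError(f"unknown weight-loss basis {basis!r}")
    return weight_loss_from_mean(result.mean_W, W0)


def crust_temperature_series(result: BakeResult) -> np.ndarray:
    """Surface-node temperature trajectory in deg C."""
    return result.T[:, -1] - 273.15


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def paper_sweep_configs(
    control: ParameterSet,
    guar: ParameterSet,
    oven_temps_c: Sequence[float] = PAPER_OVEN_TEMPS_C,
    **config_kwargs,
) -> list[BakeConfig]:
    """The study's 10-run design: 5 oven temperatures x 2 formulations."""
    configs = []
    for params in (control, guar):
        for tc in oven_temps_c:
            configs.append(BakeConfig(params=params, T_oven=tc + 273.15, **config_kwargs))
    return configs


def run_grid(configs: Iterable[BakeConfig]) -> pd.DataFrame:
    """Run a list of bake configs and tabulate their end-of-bake summaries.

    One row per config, in input order, with the final-time crust temperature
    and weight loss.  A failing run yields a row with ``status`` set to the
    error message instead of aborting the sweep.
    """
    rows = []
    for cfg in configs:
        row: dict[str, Any] = {
            "formulation": cfg.params.formulation,
            "T_oven_C": cfg.T_oven - 273.15,
            "duration_s": cfg.duration,
        }
        try:
            res = solve_bake(cfg)
            end = res.at(cfg.duration)
            row.update(
                crust_T_C=end["crust_T_C"],
                center_T_C=end["center_T_C"],
                mean_W_db=end["mean_W_db"],
                weight_loss_pct=end["weight_loss_pct"],
                status="ok",
            )
        except (SolverError, DomainError) as exc:  # pragma: no cover - defensive
            row.update(
                crust_T_C=np.nan,
                center_T_C=np.nan,
                mean_W_db=np.nan,
                weight_loss_pct=np.nan,
                status=f"error: {exc}",
            )
        rows.append(row)
    columns = [
        "formulation", "T_oven_C", "duration_s",
        "crust_T_C", "center_T_C", "mean_W_db", "weight_loss_pct", "status",
    ]
    return pd.DataFrame(rows, columns=columns)
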