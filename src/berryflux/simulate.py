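"""Hourly integration of the coupled fruit state and the what-if scenarios.

The two state variables — dry mass s(t) and water mass w(t), both mg — are
advanced with a fixed-step explicit Euler scheme at the weather resolution
(1 h), optionally with integer substeps during which the drivers are held
constant.  Each step recomputes, in order: thermal time and the ABA signal;
fruit geometry and pressures; the turgor closure and water fluxes; and the
sugar fluxes and respiration (the carbon side consumes the phloem water
influx for mass flow, so water runs first).  Fresh mass is s + w by
definition at every row.

Scenario helpers reproduce the model's what-if experiments: a uniform
temperature offset with humidity untouched, and anthesis-date shifts over a
fixed weather record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import carbon as C
from . import water as W
from .params import ParameterSet, default_parameters
from .phenology import aba_concentration, aba_normalize, gdh_increment
from .weather import EnvironmentDrivers, SyntheticWeatherSpec, WeatherSeries, \
    generate_synthetic_weather

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "initialize_state",
    "simulate",
    "scenario_temperature_offset",
    "scenario_anthesis_shift",
    "harvest_summary",
]

logger = logging.getLogger("berryflux")

#: Output table columns, in order.
RESULT_COLUMNS = [
    "t_h", "daa", "tair_K", "rh_frac", "psi_stem", "C_p_mM",
    "s_mg", "w_mg", "fresh_mg", "cGDH", "ABA_conc", "ABA_norm",
    "U_a", "U_mf", "U_diff", "U_s", "R_f", "ds_dt",
    "U_x", "U_p", "T_f", "dw_dt", "P_f", "pi_f", "A_f", "L", "rho_skin",
    "turgor_residual",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything a run needs: parameters, weather, clock and resolution."""

    params: ParameterSet = field(default_factory=default_parameters)
    weather: WeatherSeries | None = None
    drivers: EnvironmentDrivers | None = None
    duration_days: float = 80.0
    substeps: int = 2

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration must be > 0 days")
        if self.substeps < 1 or int(self.substeps) != self.substeps:
            raise ValueError("substeps must be a positive integer")

    def resolved_weather(self) -> WeatherSeries:
        if self.weather is not None:
            return self.weather
        return generate_synthetic_weather(SyntheticWeatherSpec())

    def resolved_drivers(self) -> EnvironmentDrivers:
        if self.drivers is not None:
            return self.drivers
        return EnvironmentDrivers(season_hours=self.duration_days * 24.0)

    def replace(self, **kw) -> "SimulationConfig":
        from dataclasses import replace as _replace
        return _replace(self, **kw)


@dataclass(frozen=True)
class SimulationResult:
    """Hourly trajectory plus run metadata."""

    table: pd.DataFrame
    metadata: dict

    def at_hour(self, t_h: float) -> pd.Series:
        """Row at the output hour closest to ``t_h``."""
        i = int(np.argmin(np.abs(self.table["t_h"].to_numpy() - float(t_h))))
        return self.table.iloc[i]

    @property
    def final(self) -> pd.Series:
        return self.table.iloc[-1]


def initialize_state(s_0: float, w_0: float, params: ParameterSet) -> dict:
    """State at anthesis: t = 0, cGDH = 0, ABA at its initial value."""
    if s_0 <= 0 or w_0 <= 0:
        raise ValueError("initial masses must be > 0")
    return {"t": 0.0, "s": float(s_0), "w": float(w_0), "cGDH": 0.0,
            "ABA_conc": params.ABA_0, "ABA_norm": 0.0}


def step(state: dict, tair_K: float, rh: float, psi_stem: float, C_p_mM: float,
         params: ParameterSet, dt: float) -> tuple[dict, dict]:
    """Advance the state by ``dt`` hours; return (new state, diagnostics).

    Drivers are held constant over the step.  Explicit Euler; masses are
    clamped at zero (with a logged warning) if a degenerate parameterisation
    drives them negative.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    aba_p, carb_p, wat_p = params.aba, params.carbon, params.water
    s, w, t = state["s"], state["w"], state["t"]
    ABA_norm = state["ABA_norm"]

    # --- geometry and pressures -------------------------------------
    fresh = s + w
    V = W.fruit_volume(s, w, wat_p)
    A_f = W.fruit_surface_area(fresh, wat_p)
    A_m = wat_p.a_mem * A_f
    C_f = C.fruit_sugar_concentration(s, w, carb_p)          # mass fraction
    C_f_molar = C_f * 1.0e6 / C.SUCROSE_MOLAR_MASS           # mol m^-3
    pi_f = W.osmotic_pressure(C_f_molar, tair_K) + wat_p.osm_other
    pi_p = W.osmotic_pressure(C_p_mM, tair_K)
    boundary = W.PressureState(P_f=0.0, pi_f=pi_f,
                               P_x=psi_stem, pi_x=0.0,
                               P_p=psi_stem + pi_p, pi_p=pi_p)

    # --- water side ---------------------------------------------------
    L = W.hydraulic_conductivity(ABA_norm, wat_p)
    T_f = W.transpiration(A_f, tair_K, rh, ABA_norm, wat_p)
    phi = W.extensibility(t, wat_p)
    P_f, growth = W.solve_turgor(V, A_m, L, boundary, pi_f, T_f, phi, wat_p)
    U_x, U_p = W.water_uptake(P_f, pi_f, boundary, A_m, L, wat_p)
    dw_dt = W.water_mass_rate(U_x, U_p, T_f)
    # residual of the balance the turgor closure solved (0 when the
    # non-negativity clamp on P_f binds: the solved equation is then P_f = 0)
    if P_f > 0.0:
        turgor_residual = dw_dt / wat_p.rho_water - growth
    else:
        turgor_residual = 0.0

    # --- carbon side --------------------------------------------------
    C_p = C.mM_to_mass_fraction(C_p_mM)
    U_a = C.active_sugar_uptake(s, C_p, t, ABA_norm, carb_p)
    U_mf, U_diff = C.passive_sugar_fluxes(U_p, C_p, C_f, A_m, carb_p)
    U_s = U_a + U_mf + U_diff
    ds_dt, R_f = C.dry_mass_rate(U_s, s, tair_K, ABA_norm, carb_p)

    for name, value in (("ds_dt", ds_dt), ("dw_dt", dw_dt)):
        if not math.isfinite(value):
            raise ArithmeticError(
                f"non-finite {name} at t={t} h: state={state}, "
                f"T={tair_K}, RH={rh}, psi={psi_stem}, C_p={C_p_mM}")

    # --- integrate ----------------------------------------------------
    s_new = s + ds_dt * dt
    w_new = w + dw_dt * dt
    clamped = s_new < 0.0 or w_new < 0.0
    if clamped:
        s_new = max(s_new, 0.0)
        w_new = max(w_new, 0.0)
    inc = max(0.0, min(tair_K, aba_p.T_o) - aba_p.T_b)
    cGDH_new = state["cGDH"] + inc * dt
    ABA_new = float(aba_concentration(cGDH_new, aba_p))
    new_state = {"t": t + dt, "s": s_new, "w": w_new, "cGDH": cGDH_new,
                 "ABA_conc": ABA_new,
                 "ABA_norm": float(aba_normalize(ABA_new, aba_p))}
    diag = {"U_a": U_a, "U_mf": U_mf, "U_diff": U_diff, "U_s": U_s,
            "R_f": R_f, "ds_dt": ds_dt, "U_x": U_x, "U_p": U_p, "T_f": T_f,
            "dw_dt": dw_dt, "P_f": P_f, "pi_f": pi_f, "A_f": A_f, "L": L,
            "rho_skin": W.skin_permeability(ABA_norm, wat_p),
            "growth": growth, "turgor_residual": turgor_residual,
            "clamped": clamped}
    return new_state, diag


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the model over ``duration_days`` from anthesis; hourly output.

    The output table has one row per hour from t = 0 to the end of the run
    (duration*24 + 1 rows); the flux columns of row i describe the step
    taken from row i to row i+1 (zero in the final row).
    """
    weather = config.resolved_weather()
    drivers = config.resolved_drivers()
    params = config.params

    n_hours = int(round(config.duration_days * 24.0))
    hours = weather.hours_since_anthesis()
    i0_candidates = np.flatnonzero(hours >= 0.0)
    if len(i0_candidates) == 0:
        raise ValueError("weather record ends before anthesis")
    i0 = int(i0_candidates[0])
    if hours[i0] != 0.0:
        raise ValueError(f"anthesis {weather.anthesis} is not an hourly grid "
                         f"point inside the weather record")
    if i0 + n_hours > len(weather) - 1:
        raise ValueError(
            f"weather does not cover anthesis + {config.duration_days:g} days "
            f"(record ends {weather.end})")

    tair = weather.frame["tair_K"].to_numpy()
    rh = weather.frame["rh_frac"].to_numpy()
    hod = weather.hour_of_day()

    state = initialize_state(params.s_0, params.w_0, params)
    dt = 1.0 / config.substeps
    n_clamped = 0
    rows = np.empty((n_hours + 1, len(RESULT_COLUMNS)))
    zero_diag = dict.fromkeys(
        ("U_a", "U_mf", "U_diff", "U_s", "R_f", "ds_dt", "U_x", "U_p", "T_f",
         "dw_dt", "P_f", "pi_f", "A_f", "L", "rho_skin", "turgor_residual"),
        0.0)

    for k in range(n_hours + 1):
        i = i0 + k
        psi = drivers.psi_stem(hod[i])
        c_p = drivers.c_phloem(state["t"])
        if k < n_hours:
            sub = state
            for _ in range(config.substeps):
                sub, diag = step(sub, tair[i], rh[i], psi, c_p, params, dt)
                n_clamped += diag["clamped"]
            next_state = sub
        else:
            diag = zero_diag
            next_state = None
        rows[k] = [state["t"], state["t"] / 24.0, tair[i], rh[i], psi, c_p,
                   state["s"], state["w"], state["s"] + state["w"],
                   state["cGDH"], state["ABA_conc"], state["ABA_norm"],
                   diag["U_a"], diag["U_mf"], diag["U_diff"], diag["U_s"],
                   diag["R_f"], diag["ds_dt"], diag["U_x"], diag["U_p"],
                   diag["T_f"], diag["dw_dt"], diag["P_f"], diag["pi_f"],
                   diag["A_f"], diag["L"], diag["rho_skin"],
                   diag["turgor_residual"]]
        if next_state is not None:
            state = next_state

    if n_clamped:
        logger.warning("state clamped at zero in %d of %d substeps",
                       n_clamped, n_hours * config.substeps)
    index = weather.frame.index[i0:i0 + n_hours + 1]
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS, index=index)
    meta = {"parameter_hash": params.hash(),
            "n_clamped_substeps": n_clamped,
            "anthesis": str(weather.anthesis),
            "duration_days": config.duration_days,
            "substeps": config.substeps,
            "n_rows": len(table)}
    return SimulationResult(table=table, metadata=meta)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def scenario_temperature_offset(config: SimulationConfig,
                                offset_K: float) -> SimulationResult:
    """Re-run with every hourly temperature shifted by ``offset_K``; RH fixed."""
    weather = config.resolved_weather().with_temperature_offset(offset_K)
    return simulate(config.replace(weather=weather))


def scenario_anthesis_shift(config: SimulationConfig,
                            anthesis_dates) -> pd.DataFrame:
    """One run per anthesis date; summarise fresh mass at the end of each run.

    Returns a table indexed by anthesis date with columns ``fresh_mg``,
    ``dry_mg``, ``water_mg`` taken at ``duration_days`` (default 80 DAA).
    """
    base_weather = config.resolved_weather()
    records = []
    for date in anthesis_dates:
        weather = base_weather.with_anthesis(date)
        result = simulate(config.replace(weather=weather))
        records.append({"anthesis": pd.Timestamp(date),
                        "fresh_mg": result.final["fresh_mg"],
                        "dry_mg": result.final["s_mg"],
                        "water_mg": result.final["w_mg"]})
    return pd.DataFrame.from_records(records).set_index("anthesis")


def harvest_summary(result: SimulationResult, window_start,
                    window_end) -> pd.DataFrame:
    """Mean/min/max of dry, water and fresh mass over a calendar window.

    Bounds are inclusive; a bare date as the end bound covers that whole day
    (pandas partial-string slicing).  Raises if the window does not overlap
    the run.
    """
    sub = result.table.loc[window_start:window_end]
    if len(sub) == 0:
        raise ValueError(
            f"harvest window {window_start}..{window_end} does not overlap "
            f"the simulated period {result.table.index[0]}..{result.table.index[-1]}")
    out = {}
    for label, col in (("dry_mg", "s_mg"), ("water_mg", "w_mg"),
                       ("fresh_mg", "fresh_mg")):
        vals = sub[col]
        out[label] = {"mean": vals.mean(), "min": vals.min(), "max": vals.max()}
    return pd.DataFrame(out).T[["mean", "min", "max"]]
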