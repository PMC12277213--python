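"""Carbon flux: sugar uptake, respiration, and the dry-mass balance.

Dry mass changes as the net of sugar import from the phloem and respiratory
carbon loss (per hour):

    ds/dt = U_s - R_f

Sugar uptake U_s has three routes across the composite membrane separating
the fruit "single cell" from the vasculature:

* active (apoplastic) uptake U_a — Michaelis-Menten in the phloem sugar
  concentration, proportional to dry mass (sink size), gated by a logistic
  inhibitor of age, and scaled by the ABA signal through a beta-shaped
  factor: ABA stimulates transporter activity up to an optimum and
  suppresses it beyond;
* symplastic mass flow U_mf — sugar carried along with the phloem water
  influx (no reverse flow: a negative phloem water flux carries no sugar
  out of the fruit);
* passive diffusion U_diff — down the phloem-to-fruit concentration
  gradient across the membrane area.

Respiration is partitioned into growth respiration (proportional to
positive ds/dt), Q10 maintenance respiration (proportional to s), and a
ripening component q_r * ABA_norm driven by the ABA ripening signal.

Sugar concentrations here are mass fractions (mg sugar per mg solution
water); the mM phloem driver is converted with the sucrose molar mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .phenology import ParameterError

__all__ = [
    "CarbonParams",
    "CarbonFluxes",
    "SUCROSE_MOLAR_MASS",
    "mM_to_mass_fraction",
    "aba_sugar_factor",
    "inhibitor_activity",
    "active_sugar_uptake",
    "passive_sugar_fluxes",
    "maintenance_coeff",
    "dry_mass_rate",
]

#: Molar mass of sucrose, g mol^-1.
SUCROSE_MOLAR_MASS = 342.30


def mM_to_mass_fraction(c_mM: float) -> float:
    """Convert a sucrose concentration in mM (mol m^-3) to a mass fraction.

    1 mol m^-3 of sucrose = 342.3 g m^-3 of solution; with ~1e6 g water per
    m^3 the mass fraction is c * M / 1e6 (mg sugar per mg water).
    """
    return float(c_mM) * SUCROSE_MOLAR_MASS / 1.0e6


@dataclass(frozen=True)
class CarbonParams:
    v_m: float        # maximal active transport rate, h^-1 (per mg dry mass)
    K_m: float        # Michaelis-Menten constant, mass-fraction units
    t_star: float     # inhibitor midpoint, h since anthesis
    tau: float        # inhibitor time constant, h
    k_ABA: float      # scaling of the ABA sugar-uptake factor, dimensionless
    STP_m: float      # lower ABA_norm threshold, dimensionless
    STP_e: float      # upper ABA_norm threshold (factor peak), dimensionless
    q_g: float        # growth respiration coefficient, dimensionless
    q_m_ref: float    # maintenance coefficient at T_ref, h^-1
    T_ref: float      # reference temperature for Q10, K
    Q10: float        # respiration temperature quotient
    q_r: float        # ripening respiration coefficient, mg h^-1
    p_s: float        # membrane solute permeability, cm h^-1
    ssr: float        # soluble-sugar fraction of dry mass, dimensionless

    def __post_init__(self) -> None:
        for name in ("v_m", "K_m", "t_star", "k_ABA", "q_g", "q_m_ref",
                     "q_r", "p_s", "ssr"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 <= self.STP_m < self.STP_e <= 1:
            raise ParameterError("require 0 <= STP_m < STP_e <= 1")
        if self.tau <= 0:
            raise ParameterError("tau must be > 0")
        if self.Q10 < 1:
            raise ParameterError("Q10 must be >= 1")


@dataclass(frozen=True)
class CarbonFluxes:
    """Per-step carbon diagnostics (all mg h^-1)."""

    U_a: float
    U_mf: float
    U_diff: float
    U_s: float
    R_f: float
    ds_dt: float


def aba_sugar_factor(ABA_norm: float, params: CarbonParams) -> float:
    """ABA-modulated sugar-uptake factor (dimensionless).

    Beta-shaped in the normalised ABA signal u: ~0 below STP_m's influence,
    maximum k_ABA exactly at u = STP_e, declining beyond — ABA stimulates
    transport up to an optimal concentration, then effectiveness wanes.
    """
    e, m = params.STP_e, params.STP_m
    if e == m:
        raise ParameterError("STP_e must differ from STP_m")
    u = float(ABA_norm)
    b = max(0.0, (1.0 + (e - u) / (e - m)) * (max(u, 0.0) / e) ** (e / (e - m)))
    return params.k_ABA * b


def inhibitor_activity(t: float, t_star: float, tau: float) -> float:
    """Logistic age gate on active uptake: 1/(1 + exp((t - t*)/tau)).

    Decays from ~1 early in development to ~0 after ``t_star`` hours,
    standing in for the accumulation of an uptake inhibitor.
    """
    if tau <= 0:
        raise ParameterError("tau must be > 0")
    z = (float(t) - float(t_star)) / float(tau)
    # guard exp overflow; the limit values are exact
    if z > 500.0:
        return 0.0
    if z < -500.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def active_sugar_uptake(s: float, C_p: float, t: float, ABA_norm: float,
                        params: CarbonParams) -> float:
    """Active (apoplastic) sugar uptake U_a, mg h^-1.

    U_a = ABA_sugar(u) * v_m * s * C_p/(K_m + C_p) * inhibitor(t); C_p is the
    phloem sugar mass fraction.
    """
    if C_p <= 0.0:
        return 0.0
    mm = C_p / (params.K_m + C_p)
    return (aba_sugar_factor(ABA_norm, params) * params.v_m * max(s, 0.0)
            * mm * inhibitor_activity(t, params.t_star, params.tau))


def fruit_sugar_concentration(s: float, w: float, params: CarbonParams) -> float:
    """Fruit sugar mass fraction C_f = ssr * s / w (mg sugar per mg water)."""
    if w <= 0.0:
        raise ValueError("degenerate state: water mass must be > 0 to form C_f")
    return params.ssr * s / w


def passive_sugar_fluxes(U_p: float, C_p: float, C_f: float, A_m: float,
                         params: CarbonParams) -> tuple[float, float]:
    """Mass-flow and diffusive sugar uptake (U_mf, U_diff), mg h^-1.

    U_mf = max(0, U_p) * C_p — sugar advected with phloem water inflow only
    (no reverse sugar flow from fruit to phloem).  U_diff = max(0,
    p_s * A_m * (C_p - C_f)) — down-gradient diffusion across the composite
    membrane, likewise one-way into the fruit.
    """
    U_mf = max(0.0, U_p) * C_p
    U_diff = max(0.0, params.p_s * A_m * (C_p - C_f))
    return U_mf, U_diff


def maintenance_coeff(T_air: float, params: CarbonParams) -> float:
    """Maintenance respiration coefficient q_m(T) = q_m_ref * Q10^((T-T_ref)/10)."""
    return params.q_m_ref * params.Q10 ** ((float(T_air) - params.T_ref) / 10.0)


def dry_mass_rate(U_s: float, s: float, T_air: float, ABA_norm: float,
                  params: CarbonParams) -> tuple[float, float]:
    """Solve the growth-respiration coupling; return (ds/dt, R_f), mg h^-1.

    R_f = q_g * max(0, ds/dt) + q_m(T) * s + q_r * ABA_norm with
    ds/dt = U_s - R_f.  Growth respiration applies only when growth is
    positive, so a late-season dry-mass decline does not generate a spurious
    negative respiration term.  The returned pair satisfies
    ds/dt = U_s - R_f exactly.
    """
    base = maintenance_coeff(T_air, params) * max(s, 0.0) + params.q_r * ABA_norm
    ds = (U_s - base) / (1.0 + params.q_g)
    if ds < 0.0:
        ds = U_s - base
    return ds, U_s - ds
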