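"""Water flux: geometry, pressures, Lockhart expansion and transpiration.

The fruit is a single compartment behind a composite membrane.  Water enters
from the xylem and phloem down water-potential gradients and leaves as skin
transpiration; turgor above a yield threshold drives irreversible (plastic)
volume expansion per Lockhart:

    dw/dt = U_x + U_p - T_f
    U_j   = A_m * L * (P_j - P_f - sigma_j * (pi_j - pi_f)),  j in {x, p}
    dV/dt = V * phi(t) * (P_f - Y)            while P_f > Y

The turgor P_f is the closure variable: it is solved each step so the net
water-volume exchange equals the plastic volume growth (elastic storage
neglected).  ABA enters twice, through the hydraulic conductivity
L = L_max * exp(-k_L * ABA_norm) and the skin permeability
rho = rho_min + rho_0 * exp(-k_p * ABA_norm): a ripening fruit both uncouples
hydraulically from the plant and seals its skin, which damps late-season
water loss (and heat-spike shrivel).

Boundary conditions: the xylem is at stem water potential with negligible
osmolarity (P_x = psi_stem, pi_x = 0); the phloem is in local water-potential
equilibrium with the stem, so P_p = psi_stem + pi_p(C_p) with the van't Hoff
osmotic pressure of its sucrose load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .phenology import ParameterError

__all__ = [
    "WaterParams",
    "PressureState",
    "WaterFluxes",
    "R_GAS",
    "fruit_volume",
    "fruit_surface_area",
    "osmotic_pressure",
    "hydraulic_conductivity",
    "skin_permeability",
    "transpiration",
    "extensibility",
    "solve_turgor",
    "water_uptake",
    "water_mass_rate",
]

from .weather import R_GAS, vapor_concentration


@dataclass(frozen=True)
class WaterParams:
    L_max: float      # maximal hydraulic conductivity, mg cm^-2 MPa^-1 h^-1
    k_L: float        # ABA sensitivity of conductivity, dimensionless
    a_mem: float      # surface-to-composite-membrane area coefficient
    sigma_p: float    # phloem reflection coefficient, [0, 1]
    sigma_x: float    # xylem reflection coefficient, [0, 1]
    rho_min: float    # minimum skin permeability, cm h^-1
    rho_0: float      # skin permeability scaling factor, cm h^-1
    k_p: float        # exponential decay rate of permeability vs ABA
    H_f: float        # within-fruit relative humidity, fraction
    Y: float          # Lockhart yield-threshold turgor, MPa
    phi_max: float    # maximal cell-wall extensibility, MPa^-1 h^-1
    t_phi: float      # extensibility decay midpoint, h
    s_phi: float      # extensibility decay scale, h
    c_area: float     # surface-area allometry coefficient, cm^2 g^(-2/3)
    osm_other: float  # non-sugar osmotic contribution, MPa
    rho_water: float  # water density, mg cm^-3
    rho_dry: float    # dry-matter density, mg cm^-3

    def __post_init__(self) -> None:
        for name in ("L_max", "k_L", "a_mem", "rho_min", "rho_0", "k_p",
                     "Y", "t_phi", "s_phi", "c_area", "osm_other"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("sigma_p", "sigma_x"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        if not 0 < self.H_f <= 1:
            raise ParameterError("H_f must be in (0, 1]")
        if self.phi_max <= 0:
            raise ParameterError("phi_max must be > 0")
        if self.s_phi == 0:
            raise ParameterError("s_phi must be nonzero")
        if self.rho_water <= 0 or self.rho_dry <= 0:
            raise ParameterError("densities must be > 0")


@dataclass(frozen=True)
class PressureState:
    """Hydrostatic/osmotic decomposition on both sides of the membrane (MPa)."""

    P_f: float
    pi_f: float
    P_x: float
    pi_x: float
    P_p: float
    pi_p: float

    @property
    def psi_f(self) -> float:
        return self.P_f - self.pi_f


@dataclass(frozen=True)
class WaterFluxes:
    """Per-step water diagnostics (mg h^-1)."""

    U_x: float
    U_p: float
    T_f: float
    dw_dt: float


def fruit_volume(s: float, w: float, params: WaterParams) -> float:
    """Fruit volume (cm^3) from component masses: V = w/rho_water + s/rho_dry."""
    return w / params.rho_water + s / params.rho_dry


def fruit_surface_area(fresh_mass: float, params: WaterParams) -> float:
    """Allometric fruit surface area A_f = c_area * (fresh/1000)^(2/3), cm^2.

    Fresh mass in mg; the 2/3 exponent is the isometric surface-volume
    scaling of a near-spherical berry.
    """
    return params.c_area * (max(fresh_mass, 0.0) / 1000.0) ** (2.0 / 3.0)


def membrane_area(fresh_mass: float, params: WaterParams) -> float:
    """Composite membrane exchange area A_m = a_mem * A_f, cm^2."""
    return params.a_mem * fruit_surface_area(fresh_mass, params)


def osmotic_pressure(C: float, T_air: float) -> float:
    """Van't Hoff osmotic pressure pi = R*T*C * 1e-6 MPa, C in mol m^-3."""
    if C < 0:
        raise ValueError("solute concentration must be >= 0")
    return R_GAS * float(T_air) * float(C) * 1.0e-6


def hydraulic_conductivity(ABA_norm: float, params: WaterParams) -> float:
    """L = L_max * exp(-k_L * ABA_norm); same value serves xylem and phloem."""
    return params.L_max * math.exp(-params.k_L * float(ABA_norm))


def skin_permeability(ABA_norm: float, params: WaterParams) -> float:
    """Skin permeability rho = rho_min + rho_0 * exp(-k_p * ABA_norm), cm h^-1.

    ABA-driven cuticular wax deposition seals the skin: rho decreases with
    the ripening signal toward the floor rho_min.
    """
    return params.rho_min + params.rho_0 * math.exp(-params.k_p * float(ABA_norm))


def transpiration(A_f: float, T_air: float, H_a: float, ABA_norm: float,
                  params: WaterParams) -> float:
    """Skin transpiration T_f, mg h^-1.

    T_f = A_f * alpha(T) * rho(ABA) * max(0, H_f - H_a) * 1000, with alpha
    the saturated vapour density (g cm^-3); condensation is clamped to zero.
    """
    if not 0 <= H_a <= 1:
        raise ValueError("ambient relative humidity must be in [0, 1]")
    grad = max(0.0, params.H_f - float(H_a))
    return (A_f * vapor_concentration(T_air)
            * skin_permeability(ABA_norm, params) * grad * 1000.0)


def extensibility(t: float, params: WaterParams) -> float:
    """Cell-wall extensibility phi(t) = phi_max / (1 + exp((t - t_phi)/s_phi)).

    Walls stiffen as the fruit matures: phi decays logistically from phi_max
    to ~0 around ``t_phi`` hours after anthesis.
    """
    if params.s_phi == 0:
        raise ParameterError("s_phi must be nonzero")
    z = (float(t) - params.t_phi) / params.s_phi
    if z > 500.0:
        return 0.0
    if z < -500.0:
        return params.phi_max
    return params.phi_max / (1.0 + math.exp(z))


def solve_turgor(V: float, A_m: float, L: float, boundary: "PressureState",
                 pi_f: float, T_f: float, phi: float,
                 params: WaterParams) -> tuple[float, float]:
    """Solve for fruit turgor P_f; return (P_f, plastic growth rate cm^3 h^-1).

    The closure balances net water-volume exchange against Lockhart plastic
    growth:

        [G*(a_x - P_f) + G*(a_p - P_f) - T_f] / rho_water = V*phi*(P_f - Y)

    with G = A_m*L and a_j = P_j - sigma_j*(pi_j - pi_f) the effective
    driving potential of pathway j.  Linear in P_f.  If the solution falls
    below the yield threshold Y there is no plastic growth; P_f is re-solved
    with the growth term removed (volume change = net water exchange only)
    and clamped at >= 0.  The two branches agree at P_f = Y, so the closure
    is continuous there.
    """
    G = A_m * L
    a_x = boundary.P_x - params.sigma_x * (boundary.pi_x - pi_f)
    a_p = boundary.P_p - params.sigma_p * (boundary.pi_p - pi_f)
    rho_w = params.rho_water
    inflow = G * (a_x + a_p) - T_f          # mg h^-1 at P_f = 0
    Vphi = V * phi                          # cm^3 MPa^-1 h^-1

    denom = 2.0 * G / rho_w + Vphi
    if denom > 0.0:
        P_f = (inflow / rho_w + Vphi * params.Y) / denom
    else:
        P_f = params.Y                      # degenerate: no exchange, no growth
    if not math.isfinite(P_f):
        raise ArithmeticError(
            f"turgor solve produced non-finite pressure: V={V}, A_m={A_m}, "
            f"L={L}, T_f={T_f}, phi={phi}, boundary={boundary}")

    if P_f > params.Y:
        return P_f, Vphi * (P_f - params.Y)

    # sub-yield branch: no plastic growth
    if G > 0.0:
        P_f = max(0.0, (G * (a_x + a_p) - T_f) / (2.0 * G))
    else:
        P_f = 0.0
    return P_f, 0.0


def water_uptake(P_f: float, pi_f: float, boundary: "PressureState",
                 A_m: float, L: float, params: WaterParams) -> tuple[float, float]:
    """Pathway water fluxes (U_x, U_p), mg h^-1; either may be negative."""
    G = A_m * L
    U_x = G * (boundary.P_x - P_f - params.sigma_x * (boundary.pi_x - pi_f))
    U_p = G * (boundary.P_p - P_f - params.sigma_p * (boundary.pi_p - pi_f))
    return U_x, U_p


def water_mass_rate(U_x: float, U_p: float, T_f: float) -> float:
    """dw/dt = U_x + U_p - T_f, mg h^-1 (exact identity)."""
    return U_x + U_p - T_f
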