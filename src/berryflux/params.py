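"""Parameter registry: values, units, provenance and (de)serialisation.

Every model constant lives in one registry with its units, source flag and
calibration bounds.  Thirteen parameters are flagged ``calibrated`` — the
set tuned against observed fruit data (ABA thermal-time thresholds, membrane
area, skin permeability, conductivity sensitivity, yield turgor, and the
active-uptake/ripening-respiration constants); the remainder are literature
values for the inherited biophysical machinery or structural constants of
the adopted closures.  Values that could not be sourced are flagged
``placeholder`` and sit inside literature ranges — they are defaults, not
measurements.

The on-disk format is a flat sectioned key-value (TOML) file with sections
``[aba] [carbon] [water] [init]`` holding values only; metadata stays in the
registry.  Round-trips are lossless.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass

from .phenology import ABAParams, ParameterError
from .carbon import CarbonParams
from .water import WaterParams

__all__ = ["ParamSpec", "ParameterSet", "REGISTRY", "CALIBRATED",
           "load_parameters", "save_parameters", "default_parameters"]


@dataclass(frozen=True)
class ParamSpec:
    name: str
    section: str          # aba | carbon | water | init
    default: float
    units: str
    source: str           # calibrated | literature | placeholder
    bounds: tuple[float, float]
    description: str


def _p(name, section, default, units, source, bounds, description):
    return ParamSpec(name, section, default, units, source, bounds, description)


#: The 13 calibrated parameters (sensitivity-analysis set).
CALIBRATED = ("ABA_m", "ABA_e", "a_mem", "rho_0", "rho_min", "k_p", "k_L",
              "Y", "v_m", "k_ABA", "STP_m", "STP_e", "q_r")

_SPECS = [
    # --- ABA accumulation ---
    _p("ABA_0", "aba", 0.5, "ug g^-1", "placeholder", (0.0, 5.0),
       "initial ABA concentration (dry-mass basis)"),
    _p("ABA_f", "aba", 32.30, "ug g^-1", "literature", (10.0, 60.0),
       "peak/final ABA concentration (dry-mass basis)"),
    _p("ABA_m", "aba", 14000.0, "K h", "calibrated", (2000.0, 28000.0),
       "cGDH baseline triggering ABA accumulation"),
    _p("ABA_e", "aba", 26000.0, "K h", "calibrated", (8000.0, 60000.0),
       "cGDH equilibrium point (ABA peak abscissa)"),
    _p("T_b", "aba", 278.15, "K", "literature", (273.15, 285.15),
       "base temperature for growing degree hours"),
    _p("T_o", "aba", 303.15, "K", "literature", (295.15, 313.15),
       "optimal (capping) temperature for growing degree hours"),
    # --- carbon flux ---
    _p("v_m", "carbon", 0.01, "h^-1", "calibrated", (0.001, 0.5),
       "maximal active sugar transport rate per unit dry mass"),
    _p("K_m", "carbon", 0.02, "mass fraction", "literature", (0.01, 0.3),
       "Michaelis-Menten constant of active transport"),
    _p("t_star", "carbon", 1250.0, "h", "placeholder", (200.0, 2400.0),
       "active-uptake inhibitor midpoint"),
    _p("tau", "carbon", 100.0, "h", "placeholder", (10.0, 800.0),
       "active-uptake inhibitor time constant"),
    _p("k_ABA", "carbon", 1.6, "dimensionless", "calibrated", (0.1, 5.0),
       "scaling factor of the ABA sugar-uptake factor"),
    _p("STP_m", "carbon", 0.05, "dimensionless", "calibrated", (0.0, 0.6),
       "lower ABA_norm threshold for sugar uptake"),
    _p("STP_e", "carbon", 0.5, "dimensionless", "calibrated", (0.2, 1.0),
       "upper ABA_norm threshold (uptake-factor peak)"),
    _p("q_g", "carbon", 0.084, "dimensionless", "literature", (0.0, 0.5),
       "growth respiration coefficient"),
    _p("q_m_ref", "carbon", 2.0e-4, "h^-1", "literature", (1e-5, 5e-3),
       "maintenance respiration coefficient at T_ref"),
    _p("T_ref", "carbon", 293.15, "K", "literature", (283.15, 303.15),
       "reference temperature of the Q10 law"),
    _p("Q10", "carbon", 1.9, "dimensionless", "literature", (1.0, 3.0),
       "respiration temperature quotient"),
    _p("q_r", "carbon", 0.01, "mg h^-1", "calibrated", (0.0, 2.0),
       "ripening respiration coefficient (ABA-driven)"),
    _p("p_s", "carbon", 0.06, "cm h^-1", "placeholder", (0.0, 1.0),
       "membrane solute permeability for passive diffusion"),
    _p("ssr", "carbon", 0.6, "dimensionless", "placeholder", (0.1, 0.9),
       "soluble-sugar fraction of dry mass"),
    # --- water flux ---
    _p("L_max", "water", 120.0, "mg cm^-2 MPa^-1 h^-1", "placeholder",
       (1.0, 2000.0), "maximal composite-membrane hydraulic conductivity"),
    _p("k_L", "water", 1.0, "dimensionless", "calibrated", (0.0, 5.0),
       "ABA sensitivity of hydraulic conductivity"),
    _p("a_mem", "water", 0.03, "dimensionless", "calibrated", (0.001, 0.5),
       "fruit surface to composite membrane area coefficient"),
    _p("sigma_p", "water", 0.95, "dimensionless", "literature", (0.0, 1.0),
       "phloem reflection coefficient"),
    _p("sigma_x", "water", 0.95, "dimensionless", "literature", (0.0, 1.0),
       "xylem reflection coefficient"),
    _p("rho_min", "water", 2.0, "cm h^-1", "calibrated", (0.0, 50.0),
       "minimum skin permeability"),
    _p("rho_0", "water", 22.0, "cm h^-1", "calibrated", (1.0, 500.0),
       "skin permeability scaling factor"),
    _p("k_p", "water", 3.0, "dimensionless", "calibrated", (0.0, 10.0),
       "exponential decay rate of permeability vs ABA"),
    _p("H_f", "water", 0.996, "fraction", "literature", (0.9, 1.0),
       "relative humidity of the internal air space"),
    _p("Y", "water", 0.20, "MPa", "calibrated", (0.0, 1.5),
       "Lockhart yield-threshold turgor"),
    _p("phi_max", "water", 0.012, "MPa^-1 h^-1", "placeholder", (1e-4, 0.2),
       "maximal cell-wall extensibility"),
    _p("t_phi", "water", 1200.0, "h", "placeholder", (100.0, 2400.0),
       "extensibility decay midpoint"),
    _p("s_phi", "water", 300.0, "h", "placeholder", (10.0, 1000.0),
       "extensibility decay scale"),
    _p("c_area", "water", 4.84, "cm^2 g^-2/3", "literature", (3.0, 8.0),
       "surface-area allometry coefficient (sphere: 4.84)"),
    _p("osm_other", "water", 1.0, "MPa", "placeholder", (0.0, 2.0),
       "non-sugar osmotic contribution (acids, ions)"),
    _p("rho_water", "water", 1000.0, "mg cm^-3", "literature", (900.0, 1100.0),
       "density of water"),
    _p("rho_dry", "water", 1600.0, "mg cm^-3", "literature", (1000.0, 2000.0),
       "density of dry matter"),
    # --- initial state ---
    _p("s_0", "init", 1.5, "mg", "placeholder", (0.1, 50.0),
       "initial dry mass at anthesis"),
    _p("w_0", "init", 8.5, "mg", "placeholder", (0.5, 200.0),
       "initial water mass at anthesis"),
]

REGISTRY: dict[str, ParamSpec] = {s.name: s for s in _SPECS}
assert len(REGISTRY) == len(_SPECS), "duplicate parameter names in registry"
assert all(name in REGISTRY for name in CALIBRATED)

_SECTIONS = ("aba", "carbon", "water", "init")


class ParameterSet:
    """A complete, validated set of model parameter values.

    Behaves like an immutable mapping ``name -> value`` with attribute
    access; ``.aba``, ``.carbon``, ``.water`` build the typed sub-parameter
    objects the flux modules consume (validating their invariants).
    """

    __slots__ = ("_values",)

    def __init__(self, values: dict[str, float] | None = None):
        vals = {name: spec.default for name, spec in REGISTRY.items()}
        for key, val in (values or {}).items():
            if key not in REGISTRY:
                raise ParameterError(f"unknown parameter: {key!r}")
            vals[key] = float(val)
        object.__setattr__(self, "_values", vals)
        self.validate()

    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __repr__(self) -> str:
        return f"ParameterSet({len(self._values)} parameters, hash={self.hash()[:8]})"

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def hash(self) -> str:
        payload = ",".join(f"{k}={self._values[k]!r}" for k in sorted(self._values))
        return hashlib.sha256(payload.encode()).hexdigest()

    # -- typed views ---------------------------------------------------
    @property
    def aba(self) -> ABAParams:
        v = self._values
        return ABAParams(ABA_0=v["ABA_0"], ABA_f=v["ABA_f"], ABA_m=v["ABA_m"],
                         ABA_e=v["ABA_e"], T_b=v["T_b"], T_o=v["T_o"])

    @property
    def carbon(self) -> CarbonParams:
        v = self._values
        return CarbonParams(v_m=v["v_m"], K_m=v["K_m"], t_star=v["t_star"],
                            tau=v["tau"], k_ABA=v["k_ABA"], STP_m=v["STP_m"],
                            STP_e=v["STP_e"], q_g=v["q_g"],
                            q_m_ref=v["q_m_ref"], T_ref=v["T_ref"],
                            Q10=v["Q10"], q_r=v["q_r"], p_s=v["p_s"],
                            ssr=v["ssr"])

    @property
    def water(self) -> WaterParams:
        v = self._values
        return WaterParams(L_max=v["L_max"], k_L=v["k_L"], a_mem=v["a_mem"],
                           sigma_p=v["sigma_p"], sigma_x=v["sigma_x"],
                           rho_min=v["rho_min"], rho_0=v["rho_0"],
                           k_p=v["k_p"], H_f=v["H_f"], Y=v["Y"],
                           phi_max=v["phi_max"], t_phi=v["t_phi"],
                           s_phi=v["s_phi"], c_area=v["c_area"],
                           osm_other=v["osm_other"],
                           rho_water=v["rho_water"], rho_dry=v["rho_dry"])

    def validate(self) -> None:
        """Check every typed sub-parameter invariant; raise ParameterError."""
        if self._values["s_0"] <= 0 or self._values["w_0"] <= 0:
            raise ParameterError("initial masses s_0 and w_0 must be > 0")
        _ = self.aba, self.carbon, self.water

    # -- transformations ----------------------------------------------
    def with_values(self, **updates: float) -> "ParameterSet":
        vals = dict(self._values)
        for key, val in updates.items():
            if key not in REGISTRY:
                raise ParameterError(f"unknown parameter: {key!r}")
            vals[key] = float(val)
        return ParameterSet(vals)

    def perturb(self, name: str, rel_change: float) -> "ParameterSet":
        """Return a copy with ``name`` scaled by (1 + rel_change); all else equal."""
        if name not in REGISTRY:
            raise ParameterError(f"unknown parameter: {name!r}")
        return self.with_values(**{name: self._values[name] * (1.0 + rel_change)})

    # -- provenance ----------------------------------------------------
    def describe(self) -> str:
        """Human-readable provenance table (name, value, units, source)."""
        lines = [f"{'name':<10} {'section':<7} {'value':>12} {'units':<20} "
                 f"{'source':<11} description"]
        for name, spec in REGISTRY.items():
            lines.append(f"{name:<10} {spec.section:<7} "
                         f"{self._values[name]:>12.6g} {spec.units:<20} "
                         f"{spec.source:<11} {spec.description}")
        return "\n".join(lines)


def default_parameters() -> ParameterSet:
    """The packaged default parameter set."""
    return ParameterSet()


def load_parameters(path) -> ParameterSet:
    """Load a ``[aba]/[carbon]/[water]/[init]`` TOML parameter file.

    Unknown keys are rejected; keys absent from the file keep the packaged
    defaults.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    values: dict[str, float] = {}
    for section, entries in doc.items():
        if section not in _SECTIONS:
            raise ParameterError(f"unknown parameter section: [{section}]")
        if not isinstance(entries, dict):
            raise ParameterError(f"section [{section}] must hold key = value pairs")
        for key, val in entries.items():
            if key not in REGISTRY or REGISTRY[key].section != section:
                raise ParameterError(f"unknown parameter {key!r} in [{section}]")
            values[key] = float(val)
    return ParameterSet(values)


def save_parameters(params: ParameterSet, path) -> None:
    """Write the canonical flat TOML parameter file (values only)."""
    lines = []
    for section in _SECTIONS:
        lines.append(f"[{section}]")
        for name, spec in REGISTRY.items():
            if spec.section == section:
                lines.append(f"{name} = {params[name]!r}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
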