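"""Thermal time and abscisic-acid accumulation.

Blueberry is a non-climacteric fruit: ripening is signalled by abscisic acid
(ABA) rather than an ethylene burst.  Observed ABA concentrations rise
slowly, surge to a peak and then decline late in ripening.  Lacking a
process-based biosynthesis/degradation model, ABA is described empirically
as a beta-growth function of cumulative growing degree hours (cGDH), the
hourly thermal-time clock

    cGDH(t) = sum over hours of max(0, min(T, T_o) - T_b),

so that warmer seasons reach the ABA surge earlier but the initial and final
concentrations themselves are fixed constants of the cultivar.

The beta-growth form (Yin et al. style) with baseline ``ABA_m`` and
equilibrium point ``ABA_e`` (both in K h of cGDH):

    g(x)  = max(0, (1 + (ABA_e - x)/(ABA_e - ABA_m)) * (x/ABA_e)^(ABA_e/(ABA_e - ABA_m)))
    ABA(x) = ABA_0 + (ABA_f - ABA_0) * g(x)

peaks exactly at ``x = ABA_e`` with value ``ABA_f`` and declines beyond it.
The normalised signal ABA_norm = (ABA - ABA_0)/(ABA_f - ABA_0), clamped to
[0, 1], is what the carbon- and water-flux closures consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ABAParams",
    "gdh_increment",
    "cumulate_gdh",
    "aba_concentration",
    "aba_normalize",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class ABAParams:
    """Parameters of the thermal-time ABA accumulation curve.

    Units: concentrations in ug per g dry mass; cGDH quantities in K h;
    temperatures in Kelvin.
    """

    ABA_0: float   # initial ABA concentration, ug g^-1
    ABA_f: float   # peak/final ABA concentration, ug g^-1
    ABA_m: float   # cGDH baseline triggering accumulation, K h
    ABA_e: float   # cGDH equilibrium point (peak abscissa), K h
    T_b: float     # base temperature, K
    T_o: float     # optimal (capping) temperature, K

    def __post_init__(self) -> None:
        if not 0 <= self.ABA_0 < self.ABA_f:
            raise ParameterError("require 0 <= ABA_0 < ABA_f")
        if not 0 <= self.ABA_m < self.ABA_e:
            raise ParameterError("require 0 <= ABA_m < ABA_e")
        if not self.T_b < self.T_o:
            raise ParameterError("require T_b < T_o")


def gdh_increment(T_air, T_b: float, T_o: float):
    """Growing-degree-hour gain for one hour at air temperature ``T_air`` (K).

    The effective temperature is the ambient temperature capped at the
    optimum ``T_o``; accumulation is clamped at zero below the base ``T_b``.
    """
    if not T_b < T_o:
        raise ParameterError("require T_b < T_o")
    T = np.asarray(T_air, dtype=float)
    out = np.maximum(0.0, np.minimum(T, T_o) - T_b)
    return out if out.ndim else float(out)


def cumulate_gdh(tair_K: np.ndarray, hours: np.ndarray, params: ABAParams) -> np.ndarray:
    """Running cGDH (K h) over an hourly temperature series.

    ``hours`` gives each record's time since anthesis; records before
    anthesis contribute nothing.  Non-decreasing by construction.
    """
    inc = gdh_increment(tair_K, params.T_b, params.T_o)
    inc = np.where(np.asarray(hours, dtype=float) >= 0.0, inc, 0.0)
    # cGDH at a timestamp counts the hours already elapsed, not the hour
    # about to run: cGDH = 0 at anthesis itself
    out = np.empty_like(inc)
    out[0] = 0.0
    np.cumsum(inc[:-1], out=out[1:])
    return out


def aba_concentration(cGDH, params: ABAParams):
    """ABA concentration (ug g^-1 dry mass) at thermal time ``cGDH`` (K h).

    Beta-growth curve: 0 at cGDH = 0 (returns ABA_0), unimodal peak ABA_f at
    cGDH = ABA_e, declining after the peak, clamped so the raw form never
    goes below ABA_0 at very large thermal times.
    """
    x = np.asarray(cGDH, dtype=float)
    e, m = params.ABA_e, params.ABA_m
    expo = e / (e - m)
    base = np.maximum(x, 0.0) / e
    g = (1.0 + (e - x) / (e - m)) * base ** expo
    g = np.maximum(g, 0.0)
    out = params.ABA_0 + (params.ABA_f - params.ABA_0) * g
    return out if out.ndim else float(out)


def aba_normalize(ABA_conc, params: ABAParams):
    """Normalised ABA signal in [0, 1]: (ABA - ABA_0)/(ABA_f - ABA_0), clamped."""
    if params.ABA_f == params.ABA_0:
        raise ParameterError("ABA_f must differ from ABA_0 for normalisation")
    a = np.asarray(ABA_conc, dtype=float)
    out = np.clip((a - params.ABA_0) / (params.ABA_f - params.ABA_0), 0.0, 1.0)
    return out if out.ndim else float(out)
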