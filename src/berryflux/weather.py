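"""Hourly environmental drivers for the fruit growth model.

The model is forced by an hourly weather series (air temperature, relative
humidity) together with two boundary conditions that a fruiting shoot imposes
on the fruit: the stem water potential seen by the xylem/phloem, and the
sucrose concentration of the phloem sap.  Internally everything is SI-adjacent
and fixed: Kelvin, RH as a fraction, MPa, mol m^-3 (numerically equal to mM),
hours.  Unit conversion happens once, at the I/O boundary.

Time convention: t = 0 at anthesis (0 DAA, days after anthesis); the series
is strictly hourly with no gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeatherSeries",
    "SyntheticWeatherSpec",
    "EnvironmentDrivers",
    "read_weather_csv",
    "write_weather_csv",
    "generate_synthetic_weather",
    "stem_water_potential",
    "phloem_sucrose",
    "vapor_concentration",
]

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314
#: Molar mass of water, g mol^-1.
M_WATER = 18.015

# Diurnal phases (hour of day) used by the synthetic generator and the
# stem-water-potential driver.  Standard micrometeorology: air temperature
# peaks mid-afternoon (14:00) with its minimum shortly before dawn; stem
# water potential recovers to its (least negative) maximum pre-dawn (04:00)
# and is most negative twelve hours later (16:00), tracking transpiration.
T_PEAK_HOUR = 14.0
PSI_MAX_HOUR = 4.0


class WeatherDataError(ValueError):
    """Raised for malformed or out-of-range weather input."""


class WeatherConfigError(ValueError):
    """Raised for unresolvable column mappings or bad generator specs."""


@dataclass(frozen=True)
class WeatherSeries:
    """Validated hourly weather record aligned to anthesis.

    Attributes
    ----------
    frame:
        DataFrame indexed by hourly timestamps with columns ``tair_K``
        (air temperature, Kelvin) and ``rh_frac`` (relative humidity,
        fraction in [0, 1]).
    anthesis:
        Timestamp of anthesis; defines t = 0 for the simulation clock.
    """

    frame: pd.DataFrame
    anthesis: pd.Timestamp

    def __post_init__(self) -> None:
        f = self.frame
        if len(f) < 1:
            raise WeatherDataError("weather series must contain at least one record")
        if not {"tair_K", "rh_frac"} <= set(f.columns):
            raise WeatherConfigError("weather frame needs tair_K and rh_frac columns")
        dt = f.index.to_series().diff().dropna()
        if len(dt) and not (dt == pd.Timedelta(hours=1)).all():
            bad = int(np.argmax((dt != pd.Timedelta(hours=1)).to_numpy())) + 1
            raise WeatherDataError(
                f"timestamps must be strictly increasing at a fixed 1 h step; "
                f"first offending row: {bad} ({f.index[bad]})"
            )
        if (f["rh_frac"] < 0).any() or (f["rh_frac"] > 1).any():
            rows = [int(i) for i in np.flatnonzero((f["rh_frac"] < 0) | (f["rh_frac"] > 1))]
            raise WeatherDataError(f"relative humidity outside [0, 1] at rows {rows}")
        if (f["tair_K"] <= 150.0).any():
            rows = [int(i) for i in np.flatnonzero(f["tair_K"] <= 150.0)]
            raise WeatherDataError(f"implausible temperature (<=150 K) at rows {rows}")
        if self.anthesis > f.index[-1]:
            raise WeatherDataError("anthesis lies after the end of the weather record")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def start(self) -> pd.Timestamp:
        return self.frame.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.frame.index[-1]

    def hours_since_anthesis(self) -> np.ndarray:
        """Hours elapsed since anthesis for each record (may be negative)."""
        delta = self.frame.index - self.anthesis
        return (delta / pd.Timedelta(hours=1)).to_numpy(dtype=float)

    def hour_of_day(self) -> np.ndarray:
        idx = self.frame.index
        return idx.hour.to_numpy(dtype=float) + idx.minute.to_numpy(dtype=float) / 60.0

    def with_temperature_offset(self, offset_K: float) -> "WeatherSeries":
        """Uniform warming/cooling scenario: T + offset, RH untouched."""
        f = self.frame.copy()
        f["tair_K"] = f["tair_K"] + float(offset_K)
        return WeatherSeries(frame=f, anthesis=self.anthesis)

    def with_anthesis(self, anthesis) -> "WeatherSeries":
        return WeatherSeries(frame=self.frame, anthesis=pd.Timestamp(anthesis))

    def window(self, start, end) -> "WeatherSeries":
        f = self.frame.loc[pd.Timestamp(start):pd.Timestamp(end)]
        return WeatherSeries(frame=f, anthesis=self.anthesis)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

#: Canonical writer dialect.
_CANON_COLS = ("timestamp", "tair_C", "rh_pct")


def read_weather_csv(path, anthesis, dialect: dict | None = None) -> WeatherSeries:
    """Read an hourly weather CSV and return a validated :class:`WeatherSeries`.

    The canonical dialect has columns ``timestamp`` (ISO 8601) plus either
    ``tair_C`` or ``tair_K`` and either ``rh_pct`` or ``rh_frac``; units are
    declared by the column name.  ``dialect`` maps canonical names to the
    file's actual column names, e.g. ``{"tair_C": "TempC"}``.

    Raises
    ------
    WeatherConfigError
        If a required column cannot be resolved.
    WeatherDataError
        For out-of-range values (with offending row numbers) or gapped or
        non-monotone timestamps.
    """
    dialect = dict(dialect or {})
    raw = pd.read_csv(path)

    def pick(*names):
        for name in names:
            col = dialect.get(name, name)
            if col in raw.columns:
                return name, raw[col]
        return None, None

    _, ts = pick("timestamp")
    if ts is None:
        raise WeatherConfigError(f"no timestamp column resolvable in {path}")
    uname_t, tair = pick("tair_K", "tair_C")
    if tair is None:
        raise WeatherConfigError(f"no temperature column (tair_C/tair_K) in {path}")
    uname_h, rh = pick("rh_frac", "rh_pct")
    if rh is None:
        raise WeatherConfigError(f"no humidity column (rh_pct/rh_frac) in {path}")

    tair = tair.astype(float)
    rh = rh.astype(float)
    if uname_t == "tair_C":
        tair = tair + 273.15
    if uname_h == "rh_pct":
        rh = rh / 100.0

    bad = np.flatnonzero((rh < 0) | (rh > 1))
    if len(bad):
        raise WeatherDataError(
            f"relative humidity out of range in {path} at data rows {[int(i) for i in bad]}"
        )

    frame = pd.DataFrame(
        {"tair_K": tair.to_numpy(), "rh_frac": rh.to_numpy()},
        index=pd.DatetimeIndex(pd.to_datetime(ts), name="timestamp"),
    )
    return WeatherSeries(frame=frame, anthesis=pd.Timestamp(anthesis))


def write_weather_csv(series: WeatherSeries, path) -> None:
    """Write the canonical dialect: timestamp (ISO 8601), tair_C, rh_pct."""
    out = pd.DataFrame(
        {
            "timestamp": series.frame.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "tair_C": np.round(series.frame["tair_K"].to_numpy() - 273.15, 6),
            "rh_pct": np.round(series.frame["rh_frac"].to_numpy() * 100.0, 6),
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic weather
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticWeatherSpec:
    """Parameters of the synthetic temperate-season weather generator.

    Defaults emulate a mid-latitude (Suwon-like) blueberry season running
    from early May through late July: daily means warming from spring into
    summer, a 5-6 K diurnal cycle peaking at 14:00, and relative humidity in
    anti-phase with temperature.
    """

    season_start: str | pd.Timestamp = "2015-05-05"
    season_end: str | pd.Timestamp = "2015-08-31"
    T_mean_day: float = 294.15          # season-mean daily temperature, K
    T_amplitude_diurnal: float = 5.0    # K
    T_amplitude_seasonal: float = 4.0   # K, swing from season start to mid-summer
    RH_mean: float = 0.70               # fraction
    RH_amplitude: float = 0.18          # fraction, diurnal anti-phase swing
    noise_sd_T: float = 0.8             # K
    noise_sd_RH: float = 0.03           # fraction
    random_seed: int = 0

    def __post_init__(self) -> None:
        if pd.Timestamp(self.season_end) <= pd.Timestamp(self.season_start):
            raise WeatherConfigError("season_end must be after season_start")
        for name in ("T_amplitude_diurnal", "T_amplitude_seasonal", "RH_amplitude",
                     "noise_sd_T", "noise_sd_RH"):
            if getattr(self, name) < 0:
                raise WeatherConfigError(f"{name} must be >= 0")


def generate_synthetic_weather(spec: SyntheticWeatherSpec,
                               anthesis=None) -> WeatherSeries:
    """Generate an hourly synthetic weather series, reproducible from the seed.

    Temperature = seasonal half-sine trend + diurnal cosine (maximum at
    14:00, minimum at 02:00) + Gaussian noise; relative humidity is in exact
    anti-phase with the diurnal temperature cycle, clipped to [0.02, 1.0].
    """
    start = pd.Timestamp(spec.season_start)
    end = pd.Timestamp(spec.season_end)
    idx = pd.date_range(start, end, freq="h", name="timestamp")
    n = len(idx)
    hours = np.arange(n, dtype=float)
    hod = idx.hour.to_numpy(dtype=float)

    season_len = max(hours[-1], 1.0)
    # warms from start, peaks ~70% through the season, eases off after
    seasonal = spec.T_amplitude_seasonal * np.sin(np.pi * hours / (1.4 * season_len))
    diurnal = np.cos(2.0 * np.pi * (hod - T_PEAK_HOUR) / 24.0)

    rng = np.random.default_rng(spec.random_seed)
    tair = (spec.T_mean_day + seasonal + spec.T_amplitude_diurnal * diurnal
            + rng.normal(0.0, spec.noise_sd_T, n))
    rh = (spec.RH_mean - spec.RH_amplitude * diurnal
          + rng.normal(0.0, spec.noise_sd_RH, n))
    rh = np.clip(rh, 0.02, 1.0)

    frame = pd.DataFrame({"tair_K": np.asarray(tair, dtype=float),
                          "rh_frac": rh}, index=idx)
    return WeatherSeries(frame=frame,
                         anthesis=pd.Timestamp(anthesis) if anthesis is not None
                         else start)


# ---------------------------------------------------------------------------
# Boundary-condition drivers
# ---------------------------------------------------------------------------


def stem_water_potential(hour_of_day, bounds: tuple[float, float] = (-1.8, -0.10)):
    """Diurnally oscillating stem water potential (MPa).

    Sinusoid attaining the high (least negative) bound pre-dawn at 04:00 and
    the low bound twelve hours later at 16:00; the range is exactly
    ``[low, high]``.

    Parameters
    ----------
    hour_of_day:
        Hour in [0, 24) (scalar or array); fractional hours allowed.
    bounds:
        ``(low, high)`` in MPa with ``low < high <= 0`` (equal bounds give a
        constant).
    """
    low, high = bounds
    if low > high:
        raise WeatherConfigError("psi bounds must satisfy low <= high")
    if high > 0:
        raise WeatherConfigError("stem water potential bounds must be <= 0 MPa")
    h = np.asarray(hour_of_day, dtype=float)
    mid = 0.5 * (high + low)
    amp = 0.5 * (high - low)
    out = mid + amp * np.cos(2.0 * np.pi * (h - PSI_MAX_HOUR) / 24.0)
    return out if out.ndim else float(out)


def phloem_sucrose(t_hours, season_hours: float,
                   bounds: tuple[float, float] = (15.0, 100.0)):
    """Phloem sap sucrose concentration (mol m^-3 == mM) over the season.

    Default profile: a raised-cosine seasonal wave starting at the low bound
    at anthesis, peaking at the high bound at mid-season and relaxing back --
    a smooth stand-in for the source-strength build-up and late-season
    decline of a fruiting shoot.  Values never leave ``[low, high]``.
    """
    low, high = bounds
    if low > high:
        raise WeatherConfigError("sucrose bounds must satisfy low <= high")
    t = np.asarray(t_hours, dtype=float)
    span = max(float(season_hours), 1.0)
    phase = np.clip(t / span, 0.0, 1.0)
    out = low + (high - low) * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return out if out.ndim else float(out)


def vapor_concentration(T_air: float) -> float:
    """Saturated water-vapour density alpha(T) in g cm^-3.

    alpha = M_w * P_sat(T) / (R * T) with the Magnus saturation-pressure
    formula over liquid water, P_sat = 610.94 * exp(17.625*Tc/(Tc+243.04)) Pa
    (Alduchov & Eskridge constants), Tc in deg C.  Strictly increasing with
    temperature over the physiological range.
    """
    T = float(T_air)
    if not 250.0 <= T <= 330.0:
        raise WeatherConfigError(f"temperature {T} K outside physiological range")
    Tc = T - 273.15
    p_sat = 610.94 * math.exp(17.625 * Tc / (Tc + 243.04))  # Pa
    rho_kg_m3 = (M_WATER / 1000.0) * p_sat / (R_GAS * T)    # kg m^-3
    return rho_kg_m3 / 1000.0  # g cm^-3


@dataclass(frozen=True)
class EnvironmentDrivers:
    """Boundary conditions the shoot imposes on the fruit, as functions of time.

    ``psi_stem`` oscillates diurnally between ``psi_bounds`` (MPa); the
    phloem sucrose concentration follows a seasonal profile within
    ``cp_bounds`` (mM).  Evaluation is aligned to a :class:`WeatherSeries`.
    """

    psi_bounds: tuple[float, float] = (-1.8, -0.10)
    cp_bounds: tuple[float, float] = (15.0, 100.0)
    season_hours: float = 80.0 * 24.0

    def psi_stem(self, hour_of_day):
        return stem_water_potential(hour_of_day, self.psi_bounds)

    def c_phloem(self, t_hours):
        return phloem_sucrose(t_hours, self.season_hours, self.cp_bounds)
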