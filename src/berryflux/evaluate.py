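"""Model evaluation: goodness-of-fit, local sensitivity, and calibration.

Goodness-of-fit between observed y and predicted yhat uses five metrics:
MAE, RMSE, range-normalised RMSE, the Nash-Sutcliffe efficiency
EF = 1 - SSE/SST, and Willmott's refined index of agreement

    d_r = 1 - A/(2B)        if A <= 2B
        = 2B/A - 1          otherwise,

with A = sum|y - yhat| and B = sum|y - ybar|; both EF and d_r are 1 for a
perfect fit and 0/negative for a mean-predictor-level fit.

Local sensitivity follows the one-at-a-time convention: each parameter is
raised 10% with all others fixed, and the coefficient

    S = 10 * (dW/W) / (dP/P)   [percent]

reports the percent change in the final mass per standardised 10% parameter
increase.

Calibration is two-stage: the ABA thermal-time parameters (ABA_m, ABA_e) are
fitted to ABA observations first (cheap — ABA depends only on weather), then
frozen while the remaining free parameters are fitted to fresh-mass
observations through full simulations.  The optimiser is seeded differential
evolution with an L-BFGS-B polish, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .params import CALIBRATED, REGISTRY, ParameterSet
from .phenology import aba_concentration, cumulate_gdh
from .simulate import SimulationConfig, SimulationResult, simulate

__all__ = [
    "ObservationSeries",
    "FitMetrics",
    "CalibrationSpec",
    "ABA_DETECTION_THRESHOLD",
    "SENSITIVITY_CATEGORIES",
    "fit_metrics",
    "match_predictions",
    "sensitivity_coefficient",
    "sensitivity_analysis",
    "calibrate",
]

#: LC-MS detection floor for ABA, ug per mg dry mass; observations below it
#: are censored and excluded from ABA metrics.
ABA_DETECTION_THRESHOLD_UG_PER_MG = 0.01
ABA_DETECTION_THRESHOLD = ABA_DETECTION_THRESHOLD_UG_PER_MG * 1000.0  # ug g^-1

#: Category of each calibrated parameter in the sensitivity analysis.
SENSITIVITY_CATEGORIES = {
    "ABA_m": "ABA accumulation", "ABA_e": "ABA accumulation",
    "a_mem": "composite membrane area",
    "rho_0": "fruit surface transpiration",
    "rho_min": "fruit surface transpiration",
    "k_p": "fruit surface transpiration",
    "k_L": "hydraulic conductance", "Y": "hydraulic conductance",
    "q_r": "respiration",
    "v_m": "sugar uptake", "k_ABA": "sugar uptake",
    "STP_m": "sugar uptake", "STP_e": "sugar uptake",
}


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ObservationSeries:
    """Destructively sampled fruit observations on the DAA axis.

    ``aba_ug_per_g`` may contain NaN for missing values; values at or below
    the detection threshold are treated as censored.
    """

    daa: np.ndarray
    dry_mg: np.ndarray | None = None
    water_mg: np.ndarray | None = None
    fresh_mg: np.ndarray | None = None
    aba_ug_per_g: np.ndarray | None = None

    def __post_init__(self) -> None:
        daa = np.asarray(self.daa, dtype=float)
        object.__setattr__(self, "daa", daa)
        if np.any(np.diff(daa) <= 0):
            raise EvaluationError("observation DAA must be strictly increasing")
        for name in ("dry_mg", "water_mg", "fresh_mg", "aba_ug_per_g"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=float)
                if len(arr) != len(daa):
                    raise EvaluationError(f"{name} length mismatch with daa")
                if name != "aba_ug_per_g" and np.nanmin(arr) < 0:
                    raise EvaluationError(f"{name} must be >= 0")
                object.__setattr__(self, name, arr)

    @property
    def aba_censored(self) -> np.ndarray:
        """True where the ABA value is missing or below the detection floor."""
        if self.aba_ug_per_g is None:
            return np.ones(len(self.daa), dtype=bool)
        a = self.aba_ug_per_g
        return ~np.isfinite(a) | (a <= ABA_DETECTION_THRESHOLD)

    @classmethod
    def from_csv(cls, path) -> "ObservationSeries":
        """Read columns daa, dry_mg, water_mg, fresh_mg, aba_ug_per_g."""
        raw = pd.read_csv(path)
        if "daa" not in raw.columns:
            raise EvaluationError(f"observations CSV {path} needs a 'daa' column")
        kw = {}
        for name in ("dry_mg", "water_mg", "fresh_mg", "aba_ug_per_g"):
            if name in raw.columns:
                kw[name] = raw[name].to_numpy(dtype=float)
        return cls(daa=raw["daa"].to_numpy(dtype=float), **kw)

    def to_csv(self, path) -> None:
        cols = {"daa": self.daa}
        for name in ("dry_mg", "water_mg", "fresh_mg", "aba_ug_per_g"):
            val = getattr(self, name)
            if val is not None:
                cols[name] = val
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass(frozen=True)
class FitMetrics:
    MAE: float
    RMSE: float
    NRMSE: float
    d_r: float
    EF: float

    def as_dict(self) -> dict[str, float]:
        return {"MAE": self.MAE, "RMSE": self.RMSE, "NRMSE": self.NRMSE,
                "d_r": self.d_r, "EF": self.EF}


def fit_metrics(observed, predicted) -> FitMetrics:
    """Compute MAE, RMSE, NRMSE, refined index of agreement d_r, and EF."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise EvaluationError("need two equal-length 1-d series of length >= 2")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    y_range = float(np.max(y) - np.min(y))
    if y_range == 0.0:
        raise EvaluationError("NRMSE undefined: observations have zero range")
    sst = float(np.sum((y - np.mean(y)) ** 2))
    if sst == 0.0:
        raise EvaluationError("EF/d_r undefined: observations have zero variance")
    ef = 1.0 - float(np.sum(err ** 2)) / sst
    a = float(np.sum(np.abs(err)))
    b = float(np.sum(np.abs(y - np.mean(y))))
    d_r = 1.0 - a / (2.0 * b) if a <= 2.0 * b else 2.0 * b / a - 1.0
    return FitMetrics(MAE=mae, RMSE=rmse, NRMSE=rmse / y_range, d_r=d_r, EF=ef)


def match_predictions(result: SimulationResult, obs: ObservationSeries,
                      observable: str) -> tuple[np.ndarray, np.ndarray]:
    """Pair observations with predictions at the nearest simulated hour.

    ``observable`` is one of ``dry``, ``water``, ``fresh``, ``aba``.  Each
    observation at d DAA is matched to the output hour closest to d*24.
    Censored ABA observations are excluded from the ABA pairing.
    """
    col = {"dry": "s_mg", "water": "w_mg", "fresh": "fresh_mg",
           "aba": "ABA_conc"}.get(observable)
    attr = {"dry": "dry_mg", "water": "water_mg", "fresh": "fresh_mg",
            "aba": "aba_ug_per_g"}[observable]
    values = getattr(obs, attr)
    if values is None:
        raise EvaluationError(f"observations carry no {observable} values")
    t_sim = result.table["t_h"].to_numpy()
    keep = np.ones(len(obs.daa), dtype=bool)
    if observable == "aba":
        keep &= ~obs.aba_censored
    else:
        keep &= np.isfinite(values)
    target_hours = obs.daa * 24.0
    if np.any(target_hours[keep] > t_sim[-1]) or np.any(target_hours[keep] < t_sim[0]):
        raise EvaluationError("observation DAA outside the simulated span")
    idx = np.abs(t_sim[None, :] - target_hours[keep, None]).argmin(axis=1)
    return values[keep], result.table[col].to_numpy()[idx]


def synthetic_observations(result: SimulationResult,
                           daa=(10, 20, 30, 40, 50, 60, 70, 80),
                           noise_cv: float = 0.0,
                           rng: np.random.Generator | None = None
                           ) -> ObservationSeries:
    """Sample a simulated trajectory at destructive-harvest intervals.

    Emulates the field protocol: eight harvests every 10 DAA with dry, water
    and fresh mass and ABA concentration per harvest.  ``noise_cv`` adds
    multiplicative Gaussian noise (coefficient of variation) to every
    observable; ABA values below the detection threshold remain as sampled
    and are censored downstream.
    """
    daa = np.asarray(daa, dtype=float)
    rows = [result.at_hour(d * 24.0) for d in daa]
    cols = {"dry_mg": np.array([r["s_mg"] for r in rows]),
            "water_mg": np.array([r["w_mg"] for r in rows]),
            "fresh_mg": np.array([r["fresh_mg"] for r in rows]),
            "aba_ug_per_g": np.array([r["ABA_conc"] for r in rows])}
    if noise_cv > 0.0:
        if rng is None:
            rng = np.random.default_rng(0)
        for key in cols:
            cols[key] = cols[key] * (1.0 + noise_cv * rng.standard_normal(len(daa)))
    return ObservationSeries(daa=daa, **cols)


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------


def sensitivity_coefficient(W_base: float, W_pert: float,
                            rel_change: float = 0.10) -> float:
    """Percent change in W per standardised 10% parameter increase.

    S = 10 * (dW/W_base) / rel_change; for rel_change = 0.10 this is simply
    100 * (W_pert - W_base) / W_base.
    """
    if W_base <= 0:
        raise EvaluationError("baseline output must be > 0")
    if rel_change == 0:
        raise EvaluationError("rel_change must be nonzero")
    return 10.0 * ((W_pert - W_base) / W_base) / rel_change


def sensitivity_analysis(config: SimulationConfig,
                         parameters: list[str] | None = None,
                         rel_change: float = 0.10) -> pd.DataFrame:
    """One-at-a-time +10% sensitivity of the final masses to each parameter.

    Runs the baseline once and one perturbed simulation per parameter
    (n + 1 runs); returns a table with the coefficient (percent) for final
    dry, water and fresh mass, plus the parameter's category.  A perturbed
    run that fails is recorded as NaN with the diagnostic, not fatal.
    """
    names = list(CALIBRATED) if parameters is None else list(parameters)
    base = simulate(config)
    W0 = {"dry": float(base.final["s_mg"]), "water": float(base.final["w_mg"]),
          "fresh": float(base.final["fresh_mg"])}
    records = []
    for name in names:
        rec = {"parameter": name,
               "category": SENSITIVITY_CATEGORIES.get(name, "other")}
        try:
            pert = simulate(config.replace(
                params=config.params.perturb(name, rel_change)))
            for out, key in (("dry", "s_mg"), ("water", "w_mg"),
                             ("fresh", "fresh_mg")):
                rec[f"S_{out}"] = sensitivity_coefficient(
                    W0[out], float(pert.final[key]), rel_change)
            rec["error"] = ""
        except Exception as exc:  # record, keep going
            for out in ("dry", "water", "fresh"):
                rec[f"S_{out}"] = np.nan
            rec["error"] = f"{type(exc).__name__}: {exc}"
        records.append(rec)
    cols = ["parameter", "category", "S_dry", "S_water", "S_fresh", "error"]
    return pd.DataFrame.from_records(records, columns=cols)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationSpec:
    """What to fit: the stage, the free parameters, and the search budget."""

    stage: str = "aba"                    # "aba" | "full"
    free_parameters: tuple[str, ...] = () # default per stage
    objective: str = ""                   # default per stage: "aba" / "fresh"
    seed: int = 0
    max_evaluations: int = 4000
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in ("aba", "full"):
            raise EvaluationError("stage must be 'aba' or 'full'")

    def resolved_free(self) -> tuple[str, ...]:
        if self.free_parameters:
            return self.free_parameters
        if self.stage == "aba":
            return ("ABA_m", "ABA_e")
        return tuple(n for n in CALIBRATED if n not in ("ABA_m", "ABA_e"))

    def resolved_objective(self) -> str:
        return self.objective or ("aba" if self.stage == "aba" else "fresh")

    def resolved_bounds(self, names) -> list[tuple[float, float]]:
        return [self.bounds.get(n, REGISTRY[n].bounds) for n in names]


@dataclass(frozen=True)
class CalibrationResult:
    params: ParameterSet
    objective_value: float
    metrics: FitMetrics
    free_parameters: tuple[str, ...]
    fitted_values: dict[str, float]
    at_bounds: dict[str, bool]
    n_evaluations: int
    converged: bool
    trace: list[float]


def _aba_predictor(config: SimulationConfig, obs: ObservationSeries):
    """Fast ABA objective: cGDH from weather once, then curve evaluation.

    ABA concentration depends on weather only (not on the mass state), so
    stage-1 candidates need no full simulation.
    """
    weather = config.resolved_weather()
    hours = weather.hours_since_anthesis()
    keep = ~obs.aba_censored
    if keep.sum() < 4:
        raise EvaluationError("need >= 4 uncensored ABA observations")
    target = obs.daa[keep] * 24.0
    y = obs.aba_ug_per_g[keep]

    def predict(params: ParameterSet):
        cgdh = cumulate_gdh(weather.frame["tair_K"].to_numpy(), hours,
                            params.aba)
        idx = np.abs(hours[None, :] - target[:, None]).argmin(axis=1)
        return y, aba_concentration(cgdh[idx], params.aba)

    return predict


def calibrate(spec: CalibrationSpec, obs: ObservationSeries,
              config: SimulationConfig) -> CalibrationResult:
    """Fit the stage's free parameters to observations by RMSE minimisation.

    Stage ``aba`` fits the thermal-time ABA parameters to uncensored ABA
    observations; stage ``full`` fits the remaining free parameters to the
    chosen mass observable (fresh by default) with the ABA parameters left
    as given in ``config.params``.  Seeded differential evolution over the
    registry (or user) bounds, polished with L-BFGS-B; deterministic given
    the seed.
    """
    names = spec.resolved_free()
    observable = spec.resolved_objective()
    bounds = spec.resolved_bounds(names)
    base = config.params

    obs_attr = {"aba": "aba_ug_per_g", "dry": "dry_mg", "water": "water_mg",
                "fresh": "fresh_mg"}[observable]
    if getattr(obs, obs_attr) is None:
        raise EvaluationError(f"observations carry no {observable} values")
    n_obs = (np.sum(~obs.aba_censored) if observable == "aba"
             else np.sum(np.isfinite(getattr(obs, obs_attr))))
    if n_obs < 4:
        raise EvaluationError(
            f"need >= 4 observation points for stage {spec.stage!r}")

    if spec.stage == "aba" and observable == "aba":
        predictor = _aba_predictor(config, obs)

        def mse_for(p: ParameterSet) -> float:
            y, yhat = predictor(p)
            return float(np.mean((y - yhat) ** 2))
    else:
        def mse_for(p: ParameterSet) -> float:
            y, yhat = match_predictions(simulate(config.replace(params=p)),
                                        obs, observable)
            return float(np.mean((y - yhat) ** 2))

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # rate-like parameters spanning over a decade are searched on a log
    # scale, otherwise the feasible basin occupies a sliver of the cube
    log_scale = (lo > 0.0) & (hi / np.maximum(lo, 1e-300) >= 20.0)

    def to_native(z):
        z = np.asarray(z)
        x = lo + z * (hi - lo)
        with np.errstate(invalid="ignore"):
            x_log = lo * np.exp(z * np.log(hi / np.maximum(lo, 1e-300)))
        return np.where(log_scale, x_log, x)

    # search on the unit cube so the polish step is well conditioned; the
    # internal objective is the MSE (smooth at the optimum), reported as RMSE
    def objective(z):
        x = to_native(z)
        try:
            with np.errstate(over="ignore"):
                value = mse_for(base.with_values(**dict(zip(names, x))))
        except Exception:
            return 1e12
        return value if np.isfinite(value) and value < 1e12 else 1e12

    trace: list[float] = []
    popsize = 12
    maxiter = max(1, spec.max_evaluations // (popsize * len(names)) - 1)
    result = optimize.differential_evolution(
        objective, bounds=[(0.0, 1.0)] * len(names), seed=spec.seed,
        popsize=popsize, maxiter=maxiter, tol=0.01, polish=False,
        init="sobol", updating="deferred",
        callback=lambda xk, convergence=0.0: trace.append(
            float(np.sqrt(max(objective(xk), 0.0)))))
    if not np.isfinite(result.fun) or result.fun >= 1e12:
        raise EvaluationError("objective non-finite over the whole search space")
    polished = optimize.minimize(
        objective, result.x, method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * len(names),
        options={"ftol": 1e-18, "gtol": 1e-14, "maxfun": 100 * len(names)})
    best = polished if polished.fun <= result.fun else result
    n_evals = int(result.nfev + polished.nfev)
    converged = bool(result.success or polished.success)

    x_fit = to_native(best.x)
    fitted = dict(zip(names, [float(v) for v in x_fit]))
    params = base.with_values(**fitted)
    at_bounds = {n: bool(np.isclose(fitted[n], lo, rtol=1e-3) or
                         np.isclose(fitted[n], hi, rtol=1e-3))
                 for n, (lo, hi) in zip(names, bounds)}
    if spec.stage == "aba" and observable == "aba":
        y, yhat = predictor(params)
    else:
        y, yhat = match_predictions(simulate(config.replace(params=params)),
                                    obs, observable)
    metrics = fit_metrics(y, yhat)
    return CalibrationResult(
        params=params, objective_value=float(np.sqrt(max(best.fun, 0.0))),
        metrics=metrics, free_parameters=tuple(names), fitted_values=fitted,
        at_bounds=at_bounds, n_evaluations=n_evals,
        converged=converged, trace=trace)
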