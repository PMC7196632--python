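"""Enzyme-rate and dose-response models for glutamine-dependent NAD synthetase.

NadE2 (the dimeric glutamine-dependent NAD synthetase) is feedback-inhibited
by its product NAD+; the trimeric PII signal protein GlnZ binds NadE2 and
reshapes that inhibition from a hyperbola into a cooperative sigmoid.  This
module defines the closed-form rate laws used to quantify those behaviours,
reduces raw assay traces to initial velocities, and fits the models to
dose-response and substrate-saturation data by seeded multi-start nonlinear
least squares.

Closed forms
------------
michaelis_menten        v = Vmax*S/(Km+S)
noncompetitive_mm       v = [Vmax/(1+I/Ki)]*S/(Km+S)
hyperbolic_inhibition   v = v0*(1 - Imax*I/(Ki+I))
hill_inhibition         v = v0*(1 - Imax*I^n/(IC50^n+I^n))
hyperbolic_activation   v = v_floor + (v_ceil-v_floor)*A/(Kact+A)
effector_inhibition     f = B + (T-B)*E/(K_E+E)      (percent inhibition vs 2-OG)

Ki and IC50 are empirical half-effect constants of the respective curve, not
mechanistic dissociation constants.  Concentration conventions follow the
assays: enzyme per monomer, PII per trimer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from ._fitting import DomainError, FitResult, ParameterError, multistart_least_squares

__all__ = [
    "RateModelSpec", "MODEL_SPECS", "DoseResponseDataset", "TimeCourse",
    "AssayConfig", "InitialVelocity", "FitResult", "DomainError",
    "ParameterError", "InsufficientDataError", "evaluate_model",
    "initial_velocity", "DoseResponseModel", "SaturationModel", "fit_model",
    "compare_models", "ModelComparison", "classify_inhibition",
]


class InsufficientDataError(ValueError):
    """Fewer observations than the operation requires."""


@dataclass(frozen=True)
class RateModelSpec:
    """A named closed-form rate law with its parameters and default bounds."""

    model_id: str
    parameter_names: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    predictor_names: tuple[str, ...]

    def __post_init__(self):
        for name in self.parameter_names:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ParameterError(f"bounds for {name!r} must be finite with lo < hi")


MODEL_SPECS: dict[str, RateModelSpec] = {
    "michaelis_menten": RateModelSpec(
        "michaelis_menten", ("Vmax", "Km"),
        {"Vmax": (1e-6, 1e3), "Km": (1e-6, 1e3)}, ("S",)),
    "noncompetitive_mm": RateModelSpec(
        "noncompetitive_mm", ("Vmax", "Km", "Ki"),
        {"Vmax": (1e-6, 1e3), "Km": (1e-6, 1e3), "Ki": (1e-6, 1e3)}, ("S", "I")),
    "hyperbolic_inhibition": RateModelSpec(
        "hyperbolic_inhibition", ("v0", "Imax", "Ki"),
        {"v0": (1e-6, 1e4), "Imax": (0.0, 1.0), "Ki": (1e-6, 1e3)}, ("I",)),
    "hill_inhibition": RateModelSpec(
        "hill_inhibition", ("v0", "Imax", "IC50", "n"),
        {"v0": (1e-6, 1e4), "Imax": (0.0, 1.0), "IC50": (1e-6, 1e3),
         "n": (0.1, 10.0)}, ("I",)),
    "hyperbolic_activation": RateModelSpec(
        "hyperbolic_activation", ("v_floor", "v_ceil", "Kact"),
        {"v_floor": (0.0, 1e4), "v_ceil": (0.0, 1e4), "Kact": (1e-6, 1e4)}, ("A",)),
    "effector_inhibition": RateModelSpec(
        "effector_inhibition", ("B", "T", "K_E"),
        {"B": (0.0, 200.0), "T": (0.0, 200.0), "K_E": (1e-6, 1e5)}, ("E",)),
}


def _get_spec(spec: RateModelSpec | str) -> RateModelSpec:
    if isinstance(spec, str):
        try:
            return MODEL_SPECS[spec]
        except KeyError:
            raise ParameterError(f"unknown model {spec!r}") from None
    return spec


def evaluate_model(
    spec: RateModelSpec | str,
    params: Mapping[str, float],
    predictors: Mapping[str, float | np.ndarray],
) -> float | np.ndarray:
    """Evaluate a rate law at given parameters and predictor concentrations.

    Inhibition models return v0 at I=0 and activation returns v_floor at A=0.
    Raises :class:`ParameterError` for missing parameters and
    :class:`DomainError` for negative concentrations.
    """
    spec = _get_spec(spec)
    missing = [p for p in spec.parameter_names if p not in params]
    if missing:
        raise ParameterError(f"missing parameter(s) {missing} for {spec.model_id}")
    for name in spec.predictor_names:
        if name not in predictors:
            raise ParameterError(f"missing predictor {name!r} for {spec.model_id}")
        if np.any(np.asarray(predictors[name], float) < 0):
            raise DomainError(f"negative concentration for predictor {name!r}")

    p = params
    mid = spec.model_id
    if mid == "michaelis_menten":
        S = np.asarray(predictors["S"], float)
        return p["Vmax"] * S / (p["Km"] + S)
    if mid == "noncompetitive_mm":
        S = np.asarray(predictors["S"], float)
        I = np.asarray(predictors["I"], float)
        return (p["Vmax"] / (1.0 + I / p["Ki"])) * S / (p["Km"] + S)
    if mid == "hyperbolic_inhibition":
        I = np.asarray(predictors["I"], float)
        return p["v0"] * (1.0 - p["Imax"] * I / (p["Ki"] + I))
    if mid == "hill_inhibition":
        I = np.asarray(predictors["I"], float)
        with np.errstate(divide="ignore"):
            In = np.where(I > 0, I, np.nan) ** p["n"]
        frac = np.where(I > 0, In / (p["IC50"] ** p["n"] + In), 0.0)
        return p["v0"] * (1.0 - p["Imax"] * frac)
    if mid == "hyperbolic_activation":
        A = np.asarray(predictors["A"], float)
        return p["v_floor"] + (p["v_ceil"] - p["v_floor"]) * A / (p["Kact"] + A)
    if mid == "effector_inhibition":
        E = np.asarray(predictors["E"], float)
        return p["B"] + (p["T"] - p["B"]) * E / (p["K_E"] + E)
    raise ParameterError(f"unknown model {mid!r}")


# ---------------------------------------------------------------------------
# assay traces -> initial velocities
# ---------------------------------------------------------------------------

@dataclass
class TimeCourse:
    """A raw assay trace: product (PPi, uM) or absorbance (A340) versus time (s)."""

    times: np.ndarray
    signal: np.ndarray
    assay_kind: str = "discontinuous_ppi"  # or "coupled_A340"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.signal = np.asarray(self.signal, float)
        if self.times.size != self.signal.size:
            raise ValueError("times and signal must have equal length")
        if self.times.size < 3:
            raise InsufficientDataError("time course needs at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if self.assay_kind not in ("discontinuous_ppi", "coupled_A340"):
            raise ValueError(f"unknown assay_kind {self.assay_kind!r}")


@dataclass(frozen=True)
class AssayConfig:
    """Photometric conversion constants for the coupled A340 assay.

    epsilon_NADH in M^-1 cm^-1, path_length in cm; linearity_tolerance is the
    fractional slope drift allowed while extending the linear phase.
    """

    epsilon_NADH: float = 6220.0
    path_length: float = 1.0
    linearity_tolerance: float = 0.05

    def __post_init__(self):
        if min(self.epsilon_NADH, self.path_length, self.linearity_tolerance) <= 0:
            raise ValueError("AssayConfig fields must be strictly positive")


@dataclass(frozen=True)
class InitialVelocity:
    rate: float
    n_points: int
    slope: float  # raw slope in signal units per second


def _ls_slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def initial_velocity(trace: TimeCourse, config: AssayConfig = AssayConfig()) -> InitialVelocity:
    """Slope of the detected linear phase of an assay trace.

    The linear phase is grown point by point from the first 3 points: the
    prefix is extended while appending the next point changes the fitted slope
    by less than ``linearity_tolerance`` (relative).  Coupled-assay slopes
    (AU/s) are converted to M/s via Beer-Lambert, ``slope/(epsilon*l)``;
    discontinuous PPi slopes are returned in uM/s (numerically umol/s for a
    1-ml reaction).
    """
    t, y = trace.times, trace.signal
    k = 3
    prev = _ls_slope(t[:3], y[:3])
    while k < t.size:
        nxt = _ls_slope(t[: k + 1], y[: k + 1])
        denom = abs(prev) if prev != 0 else np.finfo(float).tiny
        if abs(nxt - prev) / denom >= config.linearity_tolerance:
            break
        prev, k = nxt, k + 1
    slope = _ls_slope(t[:k], y[:k])
    if trace.assay_kind == "coupled_A340":
        rate = slope / (config.epsilon_NADH * config.path_length)
    else:
        rate = slope
    return InitialVelocity(rate=rate, n_points=k, slope=slope)


# ---------------------------------------------------------------------------
# datasets and model objects
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseDataset:
    """Replicated responses versus effector concentration (single unit)."""

    concentrations: np.ndarray
    responses: np.ndarray
    replicate_ids: np.ndarray | None = None
    effector_name: str = ""
    conc_unit: str = "mM"
    response_unit: str = "%"
    normalization_reference: str = ""

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, float)
        self.responses = np.asarray(self.responses, float)
        if self.concentrations.size != self.responses.size:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations < 0):
            raise DomainError("concentrations must be non-negative")
        if np.unique(self.concentrations).size < 2:
            raise InsufficientDataError("need at least 2 distinct concentrations")
        if self.replicate_ids is None:
            self.replicate_ids = np.zeros(self.concentrations.size, int)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "DoseResponseDataset":
        return cls(
            concentrations=df["concentration"].to_numpy(float),
            responses=df["response"].to_numpy(float),
            replicate_ids=df["replicate"].to_numpy() if "replicate" in df else None,
            conc_unit=str(df["conc_unit"].iloc[0]) if "conc_unit" in df else kw.pop("conc_unit", "mM"),
            response_unit=str(df["response_unit"].iloc[0]) if "response_unit" in df else kw.pop("response_unit", "%"),
            **kw,
        )

    @classmethod
    def from_csv(cls, path, **kw) -> "DoseResponseDataset":
        return cls.from_dataframe(pd.read_csv(path), **kw)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "concentration": self.concentrations,
            "conc_unit": self.conc_unit,
            "replicate": self.replicate_ids,
            "response": self.responses,
            "response_unit": self.response_unit,
        })


class DoseResponseModel:
    """A dose-response rate law bound to a dataset; ``fit()`` estimates it.

    Mirrors the Model/Results idiom: construct from data, call :meth:`fit`
    with the multi-start options, receive a :class:`FitResult`.

    Parameters
    ----------
    data : DoseResponseDataset
    model : str
        One of the keys of :data:`MODEL_SPECS` with a single predictor
        (all but the Michaelis-Menten family).
    fixed : mapping, optional
        Parameters pinned during fitting.  By default inhibition fits pin
        ``Imax`` = 1 (full inhibition at saturation); pass ``fixed={}`` to
        free it.
    bounds : mapping, optional
        Per-parameter ``(lo, hi)`` overrides.
    """

    _DEFAULT_FIXED = {
        "hyperbolic_inhibition": {"Imax": 1.0},
        "hill_inhibition": {"Imax": 1.0},
    }

    def __init__(self, data: DoseResponseDataset, model: str = "hyperbolic_inhibition",
                 fixed: Mapping[str, float] | None = None,
                 bounds: Mapping[str, tuple[float, float]] | None = None):
        self.data = data
        self.spec = _get_spec(model)
        if len(self.spec.predictor_names) != 1:
            raise ParameterError(
                f"{self.spec.model_id} needs a saturation design; use SaturationModel")
        self.fixed = dict(self._DEFAULT_FIXED.get(self.spec.model_id, {})
                          if fixed is None else fixed)
        self.bounds = {**self.spec.bounds, **(bounds or {})}
        n_free = len(self.spec.parameter_names) - len(self.fixed)
        if np.unique(data.concentrations).size < n_free + 1:
            raise InsufficientDataError(
                f"need at least {n_free + 1} distinct concentrations for "
                f"{n_free} free parameters")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str = "hyperbolic_inhibition", **kw):
        return cls(DoseResponseDataset.from_dataframe(df), model=model, **kw)

    def _heuristic_start(self) -> dict:
        c, y = self.data.concentrations, self.data.responses
        y0 = float(np.mean(y[c == c.min()])) or 1.0
        chalf = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
        mid = self.spec.model_id
        if mid == "hyperbolic_inhibition":
            return {"v0": abs(y0), "Imax": 1.0, "Ki": chalf}
        if mid == "hill_inhibition":
            return {"v0": abs(y0), "Imax": 1.0, "IC50": chalf, "n": 1.5}
        if mid == "hyperbolic_activation":
            return {"v_floor": abs(y0), "v_ceil": float(np.max(y)), "Kact": chalf}
        if mid == "effector_inhibition":
            return {"B": abs(y0), "T": float(np.max(y)), "K_E": chalf}
        return {}

    def fit(self, n_starts: int = 20, seed: int | None = 0) -> FitResult:
        pred = self.spec.predictor_names[0]
        conc, resp = self.data.concentrations, self.data.responses

        def residual(params):
            return evaluate_model(self.spec, params, {pred: conc}) - resp

        start = self._heuristic_start()
        return multistart_least_squares(
            residual, self.spec.parameter_names, self.bounds,
            n_starts=n_starts, seed=seed, fixed=self.fixed,
            extra_starts=[start] if start else None,
            model_id=self.spec.model_id, n_obs=resp.size,
        )


class SaturationModel:
    """Michaelis-Menten-family fit of rate versus substrate (optionally with a
    fixed inhibitor concentration for the noncompetitive form)."""

    def __init__(self, substrate: Sequence[float], rates: Sequence[float],
                 model: str = "michaelis_menten", inhibitor_conc: float = 0.0,
                 fixed: Mapping[str, float] | None = None,
                 bounds: Mapping[str, tuple[float, float]] | None = None):
        self.S = np.asarray(substrate, float)
        self.v = np.asarray(rates, float)
        if np.any(self.S < 0):
            raise DomainError("substrate concentrations must be non-negative")
        self.spec = _get_spec(model)
        if "S" not in self.spec.predictor_names:
            raise ParameterError(f"{self.spec.model_id} is not a saturation model")
        self.I = float(inhibitor_conc)
        self.fixed = dict(fixed or {})
        self.bounds = {**self.spec.bounds, **(bounds or {})}
        n_free = len(self.spec.parameter_names) - len(self.fixed)
        if np.unique(self.S).size < n_free + 1:
            raise InsufficientDataError("too few distinct substrate levels")

    def fit(self, n_starts: int = 20, seed: int | None = 0) -> FitResult:
        preds = {"S": self.S}
        if "I" in self.spec.predictor_names:
            preds["I"] = np.full_like(self.S, self.I)

        def residual(params):
            return evaluate_model(self.spec, params, preds) - self.v

        start = {"Vmax": float(np.max(self.v)) or 1.0,
                 "Km": float(np.median(self.S[self.S > 0]))}
        if "Ki" in self.spec.parameter_names:
            start["Ki"] = max(self.I, 1e-3)
        return multistart_least_squares(
            residual, self.spec.parameter_names, self.bounds,
            n_starts=n_starts, seed=seed, fixed=self.fixed,
            extra_starts=[start], model_id=self.spec.model_id, n_obs=self.v.size,
        )


def fit_model(data: DoseResponseDataset, spec: RateModelSpec | str,
              n_starts: int = 20, seed: int | None = 0,
              fixed: Mapping[str, float] | None = None,
              bounds: Mapping[str, tuple[float, float]] | None = None) -> FitResult:
    """Functional wrapper around :class:`DoseResponseModel`."""
    return DoseResponseModel(data, model=_get_spec(spec).model_id,
                             fixed=fixed, bounds=bounds).fit(n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# model comparison and inhibition-mode classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelComparison:
    preferred: str | None
    criterion: str
    statistic: float
    p_value: float | None
    detail: str = ""


def compare_models(fitA: FitResult, fitB: FitResult,
                   criterion: str = "aicc", alpha: float = 0.05) -> ModelComparison:
    """Select between two fits of the same data.

    ``f_test`` requires nested models (the simpler one a restriction of the
    richer one) and uses the extra-sum-of-squares F statistic; ``aicc``
    compares small-sample AIC.  Identical fits yield no preference.
    """
    if fitA.n_obs != fitB.n_obs:
        raise ValueError("fits have different n_obs; not the same data")
    simple, rich = (fitA, fitB) if fitA.n_free <= fitB.n_free else (fitB, fitA)
    if criterion == "f_test":
        df1 = rich.n_free - simple.n_free
        df2 = rich.n_obs - rich.n_free
        if df1 == 0 or np.isclose(simple.rss, rich.rss, rtol=0, atol=1e-12):
            return ModelComparison(None, "f_test", 0.0, 1.0, "indistinguishable fits")
        F = max(0.0, (simple.rss - rich.rss) / df1 / (rich.rss / df2))
        p = float(f_dist.sf(F, df1, df2))
        preferred = rich.model_id if p < alpha else simple.model_id
        return ModelComparison(preferred, "f_test", F, p)
    if criterion == "aicc":
        d = fitA.aicc() - fitB.aicc()
        if abs(d) < 1e-9:
            return ModelComparison(None, "aicc", 0.0, None, "equal AICc")
        preferred = fitB.model_id if d > 0 else fitA.model_id
        return ModelComparison(preferred, "aicc", abs(d), None)
    raise ValueError(f"unknown criterion {criterion!r}")


def classify_inhibition(fit_noI: FitResult, fit_withI: FitResult,
                        alpha: float = 0.05) -> tuple[str, str]:
    """Classify inhibition mode from paired saturation fits (+/- inhibitor).

    Noncompetitive/allosteric inhibition leaves Km unchanged while lowering
    Vmax (the NAD+ case for NadE2); competitive inhibition raises Km at
    constant Vmax.  Decided by normal-approximation confidence intervals:
    overlap = unchanged, separation = shifted.  Returns (label, reason).
    """
    if not (fit_noI.converged and fit_withI.converged):
        return "indeterminate", "one or both fits did not converge"
    for name in ("Vmax", "Km"):
        if name not in fit_noI.estimates or name not in fit_withI.estimates:
            return "indeterminate", f"missing {name} in fits"

    def separated(name):
        lo1, hi1 = fit_noI.conf_int(name, alpha)
        lo2, hi2 = fit_withI.conf_int(name, alpha)
        return hi1 < lo2 or hi2 < lo1

    km_shifted = separated("Km")
    vmax_shifted = separated("Vmax")
    km_up = fit_withI.estimates["Km"] > fit_noI.estimates["Km"]
    vmax_down = fit_withI.estimates["Vmax"] < fit_noI.estimates["Vmax"]
    if vmax_shifted and vmax_down and not km_shifted:
        return "noncompetitive_allosteric", "Vmax reduced, Km unchanged"
    if km_shifted and km_up and not vmax_shifted:
        return "competitive", "Km increased, Vmax unchanged"
    if km_shifted and vmax_shifted:
        return "mixed", "both Km and Vmax shifted"
    return "indeterminate", "no clear CI separation pattern"
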