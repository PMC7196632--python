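"""Biolayer-interferometry sensorgram simulation, preprocessing and global fits.

BLI reports the optical-thickness shift (nm) at a sensor tip as an analyte
(here NadE2, concentration per dimer) associates with and dissociates from an
immobilised ligand (His-GlnZ).  Under simple Langmuir 1:1 kinetics the
association phase follows

    R(t) = Req * (1 - exp(-(kON*C + kOFF) * t)),   Req = Rmax * C / (C + Kd)

and the dissociation phase decays exponentially at kOFF from the association
end-point, with Kd = kOFF/kON.  The "2:1 heterogeneous ligand" model is two
independent 1:1 sites sharing the analyte concentration, each with its own
Rmax.  Mass-transport limitation is deliberately not modelled.

Global fitting shares (kON, kOFF, Rmax) across all analyte concentrations
(per site for 2:1) by seeded multi-start least squares; the 2-OG inhibition
constant of complex formation is derived from plateau responses versus 2-OG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from ._fitting import DomainError, FitResult, multistart_least_squares

__all__ = [
    "PHASES", "Sensorgram", "BindingParams", "PreprocessConfig",
    "simulate_sensorgram", "preprocess", "BindingModel", "fit_binding_global",
    "kd_from_rates", "og_inhibition_constant",
]

PHASES = ("baseline", "loading", "association", "dissociation")


@dataclass
class Sensorgram:
    """Phased BLI time series at one analyte concentration.

    time in s (strictly increasing), response in nm spectral shift, phase a
    per-point label drawn from :data:`PHASES` in contiguous order,
    analyte_conc in nM.
    """

    time: np.ndarray
    response: np.ndarray
    phase: np.ndarray
    analyte_conc: float

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.response = np.asarray(self.response, float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.time.size == self.response.size == self.phase.size):
            raise ValueError("time, response and phase must align")
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("time must be strictly increasing")
        order = [PHASES.index(p) for p in dict.fromkeys(self.phase)]
        if order != sorted(order):
            raise ValueError("phases must be contiguous in baseline/loading/"
                             "association/dissociation order")
        if self.analyte_conc < 0:
            raise DomainError("analyte concentration must be non-negative")

    def mask(self, phase: str) -> np.ndarray:
        return self.phase == phase

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time, "response_nm": self.response,
            "phase": self.phase, "analyte_conc_nM": self.analyte_conc,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Sensorgram":
        return cls(df["time_s"].to_numpy(float), df["response_nm"].to_numpy(float),
                   df["phase"].to_numpy(object), float(df["analyte_conc_nM"].iloc[0]))

    @classmethod
    def from_csv(cls, path) -> "Sensorgram":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass(frozen=True)
class BindingParams:
    """Langmuir rate constants; optionally a second independent site (2:1).

    kON in M^-1 s^-1, kOFF in s^-1, Rmax in nm.  Kd is derived, kOFF/kON.
    """

    kON: float
    kOFF: float
    Rmax: float
    kON2: float | None = None
    kOFF2: float | None = None
    Rmax2: float | None = None

    def __post_init__(self):
        if min(self.kON, self.kOFF, self.Rmax) <= 0:
            raise DomainError("kON, kOFF, Rmax must be strictly positive")
        site2 = (self.kON2, self.kOFF2, self.Rmax2)
        if any(v is not None for v in site2) and any(v is None or v <= 0 for v in site2):
            raise DomainError("second site requires positive kON2, kOFF2, Rmax2")

    @property
    def Kd(self) -> float:
        return self.kOFF / self.kON

    @property
    def Kd2(self) -> float | None:
        return None if self.kON2 is None else self.kOFF2 / self.kON2

    @property
    def heterogeneous(self) -> bool:
        return self.kON2 is not None

    def sites(self) -> list[tuple[float, float, float]]:
        out = [(self.kON, self.kOFF, self.Rmax)]
        if self.heterogeneous:
            out.append((self.kON2, self.kOFF2, self.Rmax2))
        return out


@dataclass(frozen=True)
class PreprocessConfig:
    """Reference subtraction + Savitzky-Golay smoothing configuration."""

    sg_window: int = 11
    sg_polyorder: int = 3
    reference_id: str = ""

    def __post_init__(self):
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be smaller than sg_window")


def _site_curve(kON: float, kOFF: float, Rmax: float, C_M: float,
                t_assoc: np.ndarray, t_dissoc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free association/dissociation responses for one Langmuir site."""
    Kd = kOFF / kON
    Req = Rmax * C_M / (C_M + Kd) if C_M > 0 else 0.0
    kobs = kON * C_M + kOFF
    assoc = Req * (1.0 - np.exp(-kobs * t_assoc))
    r_end = assoc[-1] if assoc.size else 0.0
    dissoc = r_end * np.exp(-kOFF * t_dissoc)
    return assoc, dissoc


def simulate_sensorgram(params: BindingParams, conc_nM: float,
                        phase_times: Mapping[str, float] | None = None,
                        noise_sd: float = 0.0, drift: float = 0.0,
                        seed: int | None = None, dt: float = 1.0) -> Sensorgram:
    """Simulate a phased sensorgram at one analyte concentration.

    ``phase_times`` maps phase name to duration in s (defaults: baseline 30,
    loading 60, association 150, dissociation 300).  Gaussian noise of SD
    ``noise_sd`` nm and a linear drift (nm/s over the whole record) are added
    after the deterministic curve; deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    if conc_nM < 0:
        raise DomainError("analyte concentration must be non-negative")
    durations = {"baseline": 30.0, "loading": 60.0, "association": 150.0,
                 "dissociation": 300.0}
    durations.update(phase_times or {})

    t_parts, labels = [], []
    t0 = 0.0
    for ph in PHASES:
        n = max(int(round(durations[ph] / dt)), 1)
        seg = t0 + dt * np.arange(1, n + 1)
        t_parts.append(seg)
        labels.extend([ph] * n)
        t0 = seg[-1]
    time = np.concatenate(t_parts)
    phase = np.array(labels, dtype=object)

    C_M = conc_nM * 1e-9
    am = phase == "association"
    dm = phase == "dissociation"
    t_assoc = time[am] - time[am][0] + dt if am.any() else np.array([])
    t_dissoc = time[dm] - time[dm][0] + dt if dm.any() else np.array([])
    response = np.zeros_like(time)
    for kON, kOFF, Rmax in params.sites():
        assoc, dissoc = _site_curve(kON, kOFF, Rmax, C_M, t_assoc, t_dissoc)
        response[am] += assoc
        response[dm] += dissoc

    if noise_sd > 0 or drift != 0:
        rng = np.random.default_rng(seed)
        response = response + drift * time
        if noise_sd > 0:
            response = response + rng.normal(0.0, noise_sd, time.size)
    return Sensorgram(time, response, phase, conc_nM)


def preprocess(raw: Sensorgram, reference: Sensorgram,
               cfg: PreprocessConfig = PreprocessConfig()) -> Sensorgram:
    """Reference-subtract then Savitzky-Golay smooth a sensorgram.

    The reference sensor (same procedure, no analyte) is subtracted pointwise;
    smoothing runs per phase segment so phase boundaries are not smeared.
    Phases are preserved.
    """
    if raw.time.size != reference.time.size or not np.allclose(raw.time, reference.time):
        raise ValueError("raw and reference sensorgrams must share the time grid")
    resp = raw.response - reference.response
    out = resp.copy()
    for ph in PHASES:
        m = raw.mask(ph)
        n = int(m.sum())
        if n >= cfg.sg_window:
            out[m] = savgol_filter(resp[m], cfg.sg_window, cfg.sg_polyorder)
    return Sensorgram(raw.time.copy(), out, raw.phase.copy(), raw.analyte_conc)


def kd_from_rates(kON: float, kOFF: float) -> float:
    """Equilibrium dissociation constant Kd = kOFF/kON (M)."""
    if kON <= 0 or kOFF <= 0:
        raise DomainError("rate constants must be strictly positive")
    return kOFF / kON


class BindingModel:
    """Global Langmuir fit across a set of sensorgrams.

    Shares (kON, kOFF, Rmax) — per site for the heterogeneous 2:1 model —
    across all analyte concentrations.  Association responses are zeroed to
    their first point; baseline and loading phases are carried through but not
    modelled.
    """

    _BOUNDS_1TO1 = {"kON": (1e2, 1e8), "kOFF": (1e-5, 10.0), "Rmax": (1e-3, 100.0)}

    def __init__(self, sensorgrams: Sequence[Sensorgram],
                 model: str = "one_to_one"):
        if model not in ("one_to_one", "heterogeneous_2to1"):
            raise ValueError(f"unknown binding model {model!r}")
        if not sensorgrams:
            raise ValueError("need at least one sensorgram")
        for sg in sensorgrams:
            if not (sg.mask("association").any() and sg.mask("dissociation").any()):
                raise ValueError("each sensorgram needs association and "
                                 "dissociation phases")
        self.sensorgrams = list(sensorgrams)
        self.model = model
        self.flags: list[str] = []
        if len({sg.analyte_conc for sg in sensorgrams}) < 2:
            # Kd and Rmax trade off at a single concentration
            self.flags.append("kd_rmax_confounded")

    @staticmethod
    def _elapsed(sg: Sensorgram, mask: np.ndarray) -> np.ndarray:
        """Time since the phase boundary for the masked points.

        The boundary is the last sample of the preceding phase; if the phase
        opens the record, the sampling interval is extrapolated backwards.
        """
        i0 = int(np.flatnonzero(mask)[0])
        if i0 > 0:
            t0 = sg.time[i0 - 1]
        else:
            t0 = sg.time[0] - (sg.time[1] - sg.time[0])
        return sg.time[mask] - t0

    def _observed(self):
        """Per-sensorgram (conc_M, t_assoc, y_assoc_zeroed, t_dissoc, y_dissoc)."""
        obs = []
        for sg in self.sensorgrams:
            am, dm = sg.mask("association"), sg.mask("dissociation")
            ta = self._elapsed(sg, am)
            ya = sg.response[am] - sg.response[am][0]
            td = self._elapsed(sg, dm)
            yd = sg.response[dm]
            obs.append((sg.analyte_conc * 1e-9, ta, ya, td, yd))
        return obs

    def _residual_factory(self, obs):
        two = self.model == "heterogeneous_2to1"

        def residual(p):
            parts = []
            sites = [(p["kON"], p["kOFF"], p["Rmax"])]
            if two:
                sites.append((p["kON2"], p["kOFF2"], p["Rmax2"]))
            for C, ta, ya, td, yd in obs:
                pa = np.zeros_like(ta)
                pred_d = np.zeros_like(td)
                for kON, kOFF, Rmax in sites:
                    a, d = _site_curve(kON, kOFF, Rmax, C, ta, td)
                    pa += a
                    pred_d += d
                pa = pa - pa[0]  # match the zeroed association observation
                parts.append(pa - ya)
                parts.append(pred_d - yd)
            return np.concatenate(parts)

        return residual

    def fit(self, n_starts: int = 10, seed: int | None = 0) -> tuple[BindingParams, FitResult]:
        obs = self._observed()
        n_obs = sum(ta.size + td.size for _, ta, ya, td, yd in obs)
        residual = self._residual_factory(obs)

        # heuristic start: kobs from the largest response amplitude
        rmax_guess = max(float(np.max(np.abs(ya))) for _, _, ya, _, _ in obs) or 1.0
        start = {"kON": 1e5, "kOFF": 1e-2, "Rmax": rmax_guess}
        names = ["kON", "kOFF", "Rmax"]
        bounds = dict(self._BOUNDS_1TO1)
        if self.model == "heterogeneous_2to1":
            names += ["kON2", "kOFF2", "Rmax2"]
            bounds.update({"kON2": bounds["kON"], "kOFF2": bounds["kOFF"],
                           "Rmax2": bounds["Rmax"]})
            start.update({"kON2": 3e5, "kOFF2": 3e-3,
                          "Rmax2": rmax_guess / 2})
            start["Rmax"] = rmax_guess / 2

        fit = multistart_least_squares(
            residual, names, bounds, n_starts=n_starts, seed=seed,
            extra_starts=[start], model_id=self.model, n_obs=n_obs)
        fit.flags.extend(self.flags)

        e = fit.estimates
        if self.model == "heterogeneous_2to1" and fit.converged:
            # canonical site order: slower-dissociating site first
            s = sorted([(e["kOFF"], e["kON"], e["Rmax"]),
                        (e["kOFF2"], e["kON2"], e["Rmax2"])])
            e = {"kON": s[0][1], "kOFF": s[0][0], "Rmax": s[0][2],
                 "kON2": s[1][1], "kOFF2": s[1][0], "Rmax2": s[1][2]}
            fit.estimates.update(e)
        if fit.converged:
            params = BindingParams(**{k: e[k] for k in names})
            fit.estimates["Kd"] = params.Kd
        else:
            params = BindingParams(1.0, 1.0, 1.0)
        return params, fit


def fit_binding_global(sensorgrams: Sequence[Sensorgram], model: str = "one_to_one",
                       n_starts: int = 10, seed: int | None = 0,
                       ) -> tuple[BindingParams, FitResult]:
    """Functional wrapper around :class:`BindingModel`."""
    return BindingModel(sensorgrams, model=model).fit(n_starts=n_starts, seed=seed)


def og_inhibition_constant(equilibrium_responses: Sequence[tuple[float, float]],
                          floor: bool = False, n_starts: int = 10,
                          seed: int | None = 0) -> tuple[float, FitResult]:
    """Half-effect constant of 2-OG on complex formation from plateau responses.

    Fits the hyperbolic decay ``R(OG) = R0 * K/(K + OG)`` (plus an optional
    floor) to (2-OG concentration in uM, plateau response in nm) pairs and
    returns the half-effect constant K (uM).  Requires >= 4 2-OG levels
    including 0.
    """
    arr = np.asarray(equilibrium_responses, float)
    if arr.ndim != 2 or arr.shape[0] < 4:
        raise ValueError("need at least 4 (OG, response) pairs")
    og, resp = arr[:, 0], arr[:, 1]
    if np.any(og < 0):
        raise DomainError("2-OG concentrations must be non-negative")
    if 0.0 not in og:
        raise ValueError("a 0 2-OG level is required to anchor R0")

    names = ["R0", "K", "Rfloor"] if floor else ["R0", "K"]
    bounds = {"R0": (1e-6, 1e3), "K": (1e-3, 1e6), "Rfloor": (0.0, 1e3)}

    def residual(p):
        pred = p["R0"] * p["K"] / (p["K"] + og)
        if floor:
            pred = pred + p["Rfloor"]
        return pred - resp

    start = {"R0": float(resp[og == 0].mean()), "K": float(np.median(og[og > 0])),
             "Rfloor": 0.0}
    fit = multistart_least_squares(residual, names, bounds, n_starts=n_starts,
                                   seed=seed, extra_starts=[start],
                                   model_id="og_plateau_decay", n_obs=og.size)
    if np.ptp(resp) < 1e-12:
        fit.flags.append("non_identifiable_flat_responses")
    return fit.estimates.get("K", float("nan")), fit
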