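"""Integrated regulatory-switch model of NadE2 activity control by PII.

Combines the measured constants — the PII-NadE2 complex Kd, the two 2-OG
half-effect constants (complex formation vs pre-formed complex), and the two
NAD+ inhibition regimes (hyperbolic for free enzyme, cooperative sigmoid for
the complex) — into a predictive model of NadE2 activity as a function of
NAD+, available PII, 2-OG, uridylylation state and complex history.  The
model equations are this package's synthesis; the constants are measured.

Model structure
---------------
* Uridylylated PII does not bind NadE2: available PII = PII_total * (1 - u).
* 2-OG weakens binding as a competitive multiplier on the complex Kd,
  Kd_eff = Kd * (1 + OG/K_OG), with K_OG switched by complex history —
  the "memory effect": a pre-formed complex resists 2-OG concentrations that
  abolish de novo formation (K_OG 15.5 uM forming vs 1 mM pre-formed).
* The bound fraction of NadE2 follows the exact tight-binding quadratic for
  1 trimer : 1 dimer binding.
* Activity is the f-weighted mixture of the complexed (Hill) and free
  (hyperbolic) NAD+ inhibition curves, in percent of the NAD+-free rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import kinetics
from ._fitting import DomainError

__all__ = ["HubState", "SwitchParams", "available_pii", "effective_kd",
           "complex_fraction", "predicted_activity", "hysteresis_scan",
           "loop_area", "SwitchScan"]

HISTORIES = ("forming", "preformed")


@dataclass(frozen=True)
class HubState:
    """Metabolite/protein state fed to the switch model.

    NAD in mM; PII_total in uM trimer; NadE_total in uM dimer; OG in uM;
    urid_fraction u in [0, 1]; history 'forming' or 'preformed'.
    """

    NAD: float = 0.0
    PII_total: float = 0.0
    NadE_total: float = 0.1
    OG: float = 0.0
    urid_fraction: float = 0.0
    history: str = "forming"

    def __post_init__(self):
        if min(self.NAD, self.PII_total, self.NadE_total, self.OG) < 0:
            raise DomainError("concentrations must be non-negative")
        if not 0.0 <= self.urid_fraction <= 1.0:
            raise DomainError("urid_fraction must lie in [0, 1]")
        if self.history not in HISTORIES:
            raise ValueError(f"history must be one of {HISTORIES}")


@dataclass(frozen=True)
class SwitchParams:
    """Measured constants wired into the switch model (defaults as measured).

    Kd_complex 0.3 uM with ATP (0.15 with ADP); K_OG_forming 15.5 uM;
    K_OG_preformed 1 mM; free-enzyme NAD+ inhibition Ki 1 mM (Imax 1);
    complexed-enzyme IC50 2.5 mM, Hill n 2.2.  relief_ceiling caps the
    complexed-enzyme curve's 100% reference if partial relief is wanted.
    """

    Kd_complex: float = 0.3        # uM trimer/dimer
    K_OG_forming: float = 15.5     # uM
    K_OG_preformed: float = 1000.0  # uM (1 mM)
    Ki_free: float = 1.0           # mM NAD+
    Imax_free: float = 1.0
    IC50_complex: float = 2.5      # mM NAD+
    hill_n: float = 2.2
    Imax_complex: float = 1.0
    relief_ceiling: float = 100.0  # % activity of the complexed enzyme at NAD=0

    def __post_init__(self):
        vals = (self.Kd_complex, self.K_OG_forming, self.K_OG_preformed,
                self.Ki_free, self.IC50_complex, self.hill_n)
        if min(vals) <= 0:
            raise DomainError("switch constants must be strictly positive")
        if self.K_OG_forming >= self.K_OG_preformed:
            raise ValueError("K_OG_forming must be below K_OG_preformed")


def available_pii(state: HubState) -> float:
    """PII competent to bind NadE2 (uM trimer): the non-uridylylated pool."""
    return state.PII_total * (1.0 - state.urid_fraction)


def effective_kd(params: SwitchParams, OG: float, history: str) -> float:
    """History-dependent effective complex Kd under 2-OG (uM).

    Competitive-effector form Kd * (1 + OG/K_OG); forming complexes feel 2-OG
    at 15.5 uM, pre-formed ones only at 1 mM.
    """
    if OG < 0:
        raise DomainError("OG must be non-negative")
    if history not in HISTORIES:
        raise ValueError(f"history must be one of {HISTORIES}")
    K = params.K_OG_forming if history == "forming" else params.K_OG_preformed
    return params.Kd_complex * (1.0 + OG / K)


def complex_fraction(PII_avail: float, NadE_total: float, Kd_eff: float) -> float:
    """Fraction of NadE2 dimer in complex: exact tight-binding quadratic.

    For 1 trimer : 1 dimer binding with total concentrations P and N,
    f = [(P+N+Kd) - sqrt((P+N+Kd)^2 - 4PN)] / (2N); f = 0 when N = 0.
    """
    P, N, Kd = float(PII_avail), float(NadE_total), float(Kd_eff)
    if min(P, N, Kd) < 0:
        raise DomainError("inputs must be non-negative")
    if N == 0:
        return 0.0
    b = P + N + Kd
    disc = max(b * b - 4.0 * P * N, 0.0)
    f = (b - np.sqrt(disc)) / (2.0 * N)
    return float(min(max(f, 0.0), 1.0))


def predicted_activity(state: HubState, params: SwitchParams = SwitchParams()) -> float:
    """NadE2 activity (% of the NAD+-free rate) for a hub state.

    Linear mixture of the two enzyme populations: the complexed fraction f
    follows the cooperative sigmoid (IC50, n), the free fraction the
    hyperbola (Ki); both evaluated through the kinetics module's rate laws.
    """
    f = complex_fraction(available_pii(state), state.NadE_total,
                         effective_kd(params, state.OG, state.history))
    complexed = kinetics.evaluate_model(
        "hill_inhibition",
        {"v0": params.relief_ceiling, "Imax": params.Imax_complex,
         "IC50": params.IC50_complex, "n": params.hill_n},
        {"I": state.NAD})
    free = kinetics.evaluate_model(
        "hyperbolic_inhibition",
        {"v0": 100.0, "Imax": params.Imax_free, "Ki": params.Ki_free},
        {"I": state.NAD})
    act = f * float(complexed) + (1.0 - f) * float(free)
    return float(min(max(act, 0.0), 100.0))


@dataclass
class SwitchScan:
    """Hysteresis scan output: one branch per complex history."""

    ascending: pd.DataFrame   # history='preformed', OG raised on a formed complex
    descending: pd.DataFrame  # history='forming', complex formed de novo per OG

    def to_dataframe(self) -> pd.DataFrame:
        up = self.ascending.assign(branch="preformed_ascending")
        dn = self.descending.assign(branch="forming_descending")
        return pd.concat([up, dn], ignore_index=True)


def hysteresis_scan(state: HubState, params: SwitchParams,
                    og_grid: Sequence[float]) -> SwitchScan:
    """Activity along an ascending-then-descending 2-OG sweep.

    The ascending branch models a complex formed at low 2-OG and then
    challenged (history='preformed'); the descending branch models de novo
    complex formation at each 2-OG level (history='forming').  The gap
    between branches over 2-OG in (K_OG_forming, K_OG_preformed) is the
    memory effect.
    """
    og = np.asarray(list(og_grid), float)
    if og.size == 0:
        raise ValueError("og_grid must be non-empty")
    if np.any(og < 0):
        raise DomainError("OG values must be non-negative")

    def branch(history, grid):
        acts = [predicted_activity(replace(state, OG=float(g), history=history),
                                   params) for g in grid]
        return pd.DataFrame({"OG": grid, "activity": acts})

    asc = np.sort(og)
    desc = asc[::-1].copy()
    return SwitchScan(ascending=branch("preformed", asc),
                      descending=branch("forming", desc))


def loop_area(scan: SwitchScan) -> float:
    """Area enclosed between the two hysteresis branches (trapezoidal)."""
    up = scan.ascending.sort_values("OG")
    dn = scan.descending.sort_values("OG")
    if not np.allclose(up["OG"].to_numpy(), dn["OG"].to_numpy()):
        raise ValueError("branches must share the OG grid")
    gap = up["activity"].to_numpy() - dn["activity"].to_numpy()
    return float(np.trapezoid(gap, up["OG"].to_numpy()))
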