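"""Shared multi-start nonlinear least-squares engine.

All model fits in the package go through :func:`multistart_least_squares`:
seeded uniform draws within the parameter bounds, a trust-region-reflective
least-squares solve from each start (scipy), the lowest-RSS solution kept,
and standard errors from the Gauss-Newton curvature at the optimum.  The
procedure is a pure function of (data, bounds, n_starts, seed) and therefore
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitResult", "multistart_least_squares", "DomainError", "ParameterError"]


class DomainError(ValueError):
    """An input lies outside the physical domain (e.g. negative concentration)."""


class ParameterError(KeyError):
    """A required model parameter is missing or malformed."""


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    Attributes
    ----------
    model_id : str
        Identifier of the fitted closed form.
    estimates : dict
        Parameter name -> point estimate (fixed parameters included).
    standard_errors : dict
        Parameter name -> asymptotic standard error from the Gauss-Newton
        approximation ``rss/(n-p) * inv(J'J)``; 0.0 for fixed parameters.
    rss : float
        Residual sum of squares at the optimum.
    n_obs : int
        Number of observations.
    converged : bool
        True if at least one start converged.
    seed, n_starts : int
        The multi-start configuration used.
    """

    model_id: str
    estimates: dict
    standard_errors: dict
    rss: float
    n_obs: int
    converged: bool
    seed: int | None
    n_starts: int
    fixed: dict = field(default_factory=dict)
    message: str = ""
    flags: list = field(default_factory=list)

    @property
    def n_free(self) -> int:
        return len(self.estimates) - len(self.fixed)

    def aicc(self) -> float:
        """Small-sample corrected Akaike information criterion.

        Uses the Gaussian log-likelihood up to a constant,
        ``n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1)`` with ``k`` = free parameters + 1
        (the error variance).
        """
        n, k = self.n_obs, self.n_free + 1
        if n - k - 1 <= 0:
            return np.inf
        return n * np.log(self.rss / n if self.rss > 0 else np.finfo(float).tiny) \
            + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-approximation confidence interval for one parameter."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        e, se = self.estimates[name], self.standard_errors[name]
        return (e - z * se, e + z * se)

    def summary(self) -> str:
        lines = [
            f"Model: {self.model_id}",
            f"Observations: {self.n_obs}   RSS: {self.rss:.6g}   "
            f"converged: {self.converged}   starts: {self.n_starts}   seed: {self.seed}",
            f"{'parameter':<12}{'estimate':>14}{'std err':>14}",
        ]
        for name, val in self.estimates.items():
            se = self.standard_errors.get(name, float("nan"))
            tag = "  (fixed)" if name in self.fixed else ""
            lines.append(f"{name:<12}{val:>14.6g}{se:>14.6g}{tag}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "estimates": dict(self.estimates),
            "standard_errors": dict(self.standard_errors),
            "rss": self.rss,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "fixed": dict(self.fixed),
            "flags": list(self.flags),
        }


def _draw_starts(
    rng: np.random.Generator,
    lo: np.ndarray,
    hi: np.ndarray,
    n_starts: int,
) -> np.ndarray:
    """Seeded starting points within bounds.

    Parameters spanning more than two decades on a strictly positive range are
    drawn log-uniformly (rate constants, affinities); the rest uniformly.
    """
    out = np.empty((n_starts, lo.size))
    for j in range(lo.size):
        if lo[j] > 0 and hi[j] / lo[j] > 100:
            out[:, j] = np.exp(rng.uniform(np.log(lo[j]), np.log(hi[j]), n_starts))
        else:
            out[:, j] = rng.uniform(lo[j], hi[j], n_starts)
    return out


def multistart_least_squares(
    residual: Callable[[Mapping[str, float]], np.ndarray],
    names: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    *,
    n_starts: int = 20,
    seed: int | None = 0,
    fixed: Mapping[str, float] | None = None,
    extra_starts: Sequence[Mapping[str, float]] | None = None,
    model_id: str = "custom",
    n_obs: int | None = None,
) -> FitResult:
    """Fit ``residual(params) -> vector`` by seeded multi-start least squares.

    ``fixed`` pins parameters at given values (excluded from optimisation).
    ``extra_starts`` adds deterministic heuristic starting points ahead of the
    random draws.  Non-convergence of every start yields a flagged result,
    never an exception.
    """
    fixed = dict(fixed or {})
    free = [n for n in names if n not in fixed]
    if not free:
        raise ParameterError("no free parameters to fit")
    lo = np.array([bounds[n][0] for n in free], float)
    hi = np.array([bounds[n][1] for n in free], float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(lo < hi)):
        raise ParameterError("bounds must be finite with lo < hi")

    def vec_residual(x: np.ndarray) -> np.ndarray:
        params = dict(zip(free, x))
        params.update(fixed)
        return np.asarray(residual(params), float)

    rng = np.random.default_rng(seed)
    starts = list(_draw_starts(rng, lo, hi, n_starts))
    for s in extra_starts or []:
        x0 = np.clip(np.array([s[n] for n in free], float), lo, hi)
        starts.insert(0, x0)

    best = None
    for x0 in starts:
        try:
            sol = least_squares(vec_residual, x0, bounds=(lo, hi), method="trf")
        except Exception:  # singular model evaluation at a start: skip it
            continue
        if not np.all(np.isfinite(sol.fun)):
            continue
        rss = float(np.sum(sol.fun**2))
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol)

    n = n_obs if n_obs is not None else (len(vec_residual(np.clip((lo + hi) / 2, lo, hi))))

    if best is None:
        return FitResult(
            model_id=model_id,
            estimates={**{k: np.nan for k in free}, **fixed},
            standard_errors={k: np.nan for k in names},
            rss=np.inf, n_obs=n, converged=False, seed=seed,
            n_starts=len(starts), fixed=fixed, message="no start converged",
            flags=["non_converged"],
        )

    rss, sol = best
    p = len(free)
    ses = dict.fromkeys(free, np.nan)
    flags: list[str] = []
    dof = n - p
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.pinv(jtj) * (rss / dof)
            diag = np.clip(np.diag(cov), 0, None)
            ses = dict(zip(free, np.sqrt(diag)))
            if np.linalg.matrix_rank(jtj) < p:
                flags.append("rank_deficient")
        except np.linalg.LinAlgError:
            flags.append("rank_deficient")
    else:
        flags.append("zero_dof")

    estimates = dict(zip(free, sol.x))
    estimates.update(fixed)
    ses.update(dict.fromkeys(fixed, 0.0))
    # report in the caller's declared parameter order
    estimates = {k: estimates[k] for k in names}
    ses = {k: ses[k] for k in names}
    return FitResult(
        model_id=model_id, estimates=estimates, standard_errors=ses,
        rss=rss, n_obs=n, converged=True, seed=seed, n_starts=len(starts),
        fixed=fixed, flags=flags,
    )
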