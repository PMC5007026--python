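"""30-day survival curves and probit dose-lethality estimation.

The dose-lethality model is the classic probit: the probability that an
animal dies within 30 days of a total-body dose ``d`` is

    P(death | d) = Phi((d - mu) / sigma),

with ``mu`` the dose of 50% mortality (LD50/30) and ``sigma`` the tolerance
spread.  The model is fit to *grouped* 30-day mortality counts (dose, n,
deaths) by maximizing the binomial log-likelihood; euthanasia at a humane
endpoint counts as death, since the score system is an explicit surrogate for
death as the endpoint.  The dose lethal to a fraction ``p`` is
``mu + sigma * Phi^{-1}(p)``, with delta-method confidence limits from the
observed information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .cohort import CohortStudy

__all__ = [
    "ProbitFit",
    "LDEstimate",
    "SurvivalCurve",
    "as_dose_mortality",
    "dose_mortality_from_study",
    "fit_probit",
    "ld_estimate",
    "survival_curve",
]

DoseMortalityLike = Union[pd.DataFrame, Iterable[tuple]]


def as_dose_mortality(data: DoseMortalityLike) -> pd.DataFrame:
    """Coerce to a validated (dose, n, deaths) frame."""
    if isinstance(data, pd.DataFrame):
        df = data[["dose", "n", "deaths"]].copy()
    else:
        df = pd.DataFrame(list(data), columns=["dose", "n", "deaths"])
    df = df.astype({"dose": float, "n": int, "deaths": int})
    if (df["deaths"] < 0).any() or (df["deaths"] > df["n"]).any():
        raise ValueError("deaths must satisfy 0 <= deaths <= n")
    if df["dose"].duplicated().any():
        raise ValueError("doses must be distinct")
    return df


def dose_mortality_from_study(study: CohortStudy) -> pd.DataFrame:
    """Grouped 30-day mortality from an adjudicated cohort (irradiated groups)."""
    rows = []
    for group in sorted({a.group for a in study.animals if a.dose_Gy is not None}, key=float):
        recs = study.group(group)
        if any(r.fate is None for r in recs):
            raise ValueError(f"group {group!r}: fates not assigned")
        rows.append(
            {"dose": float(group), "n": len(recs), "deaths": sum(r.died() for r in recs)}
        )
    return as_dose_mortality(rows)


@dataclass(frozen=True)
class ProbitFit:
    mu: float
    sigma: float
    loglik: float
    converged: bool
    cov: Optional[np.ndarray] = None  # 2x2 covariance of (mu, sigma)
    diagnostic: str = ""
    n_total: int = 0


@dataclass(frozen=True)
class LDEstimate:
    p: float
    dose: float
    ci_low: float
    ci_high: float
    method: str = "probit-mle-delta"


def _loglik(mu: float, sigma: float, dose, n, deaths) -> float:
    z = (dose - mu) / sigma
    return float(np.sum(deaths * norm.logcdf(z) + (n - deaths) * norm.logsf(z)))


def _nll_and_grad(theta, dose, n, deaths):
    mu, log_s = theta
    s = math.exp(log_s)
    z = (dose - mu) / s
    logcdf = norm.logcdf(z)
    logsf = norm.logsf(z)
    logpdf = norm.logpdf(z)
    ll = float(np.sum(deaths * logcdf + (n - deaths) * logsf))
    # dl/dz per dose level, with stable Mills-ratio terms.
    g = deaths * np.exp(logpdf - logcdf) - (n - deaths) * np.exp(logpdf - logsf)
    d_mu = float(np.sum(g) * (-1.0 / s))
    d_logs = float(np.sum(g * (-z)))
    return -ll, np.array([-d_mu, -d_logs])


def _separation(df: pd.DataFrame) -> Optional[tuple[float, float]]:
    """Detect a perfect dose step (complete separation); return its bracket."""
    boundary = df[(df["deaths"] > 0) & (df["deaths"] < df["n"])]
    if len(boundary) > 0:
        return None
    zero = df[df["deaths"] == 0]["dose"]
    full = df[df["deaths"] == df["n"]]["dose"]
    if len(zero) == 0 or len(full) == 0:
        return None
    if zero.max() < full.min():
        return float(zero.max()), float(full.min())
    return None


def _moment_start(df: pd.DataFrame) -> tuple[float, float]:
    # Probit-transform regression on shrunk proportions.
    p_adj = (df["deaths"] + 0.5) / (df["n"] + 1.0)
    y = norm.ppf(p_adj)
    b, a = np.polyfit(df["dose"], y, 1)
    if b <= 1e-6:
        return float(np.average(df["dose"], weights=df["n"])), 1.0
    return float(-a / b), float(1.0 / b)


def _observed_cov(mu, sigma, dose, n, deaths) -> Optional[np.ndarray]:
    # Observed information in (mu, sigma) by central finite differences.
    h = np.array([1e-4 * max(1.0, abs(mu)), 1e-4 * max(1e-3, sigma)])

    def nll(v):
        return -_loglik(v[0], v[1], dose, n, deaths)

    x0 = np.array([mu, sigma])
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            H[i, j] = (
                nll(x0 + ei + ej) - nll(x0 + ei - ej) - nll(x0 - ei + ej) + nll(x0 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or cov[0, 0] <= 0 or cov[1, 1] <= 0:
        return None
    return cov


def fit_probit(data: DoseMortalityLike) -> ProbitFit:
    """Maximum-likelihood probit fit to grouped mortality counts.

    Newton iterations with line search (on (mu, log sigma), so sigma stays
    positive) from a probit-transform moment start.  All-0 and all-n dose
    levels are tolerated; a *perfect* dose step (complete separation) has no
    finite MLE and is reported honestly with ``converged=False`` and the
    bracketing doses in the diagnostic, rather than as a silently huge slope.
    The result is independent of row order.
    """
    df = as_dose_mortality(data).sort_values("dose").reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("need at least two dose levels")
    dose = df["dose"].to_numpy()
    n = df["n"].to_numpy(dtype=float)
    deaths = df["deaths"].to_numpy(dtype=float)
    n_total = int(df["n"].sum())

    bracket = _separation(df)
    if bracket is not None:
        mu = 0.5 * (bracket[0] + bracket[1])
        return ProbitFit(
            mu=mu,
            sigma=float("nan"),
            loglik=0.0,
            converged=False,
            diagnostic=(
                f"complete separation: mortality steps from 0 to 1 between "
                f"{bracket[0]} and {bracket[1]} Gy; mu is bracketed but sigma "
                f"has no finite MLE"
            ),
            n_total=n_total,
        )

    mu0, s0 = _moment_start(df)
    s0 = min(max(s0, 1e-2), 50.0)
    theta0 = np.array([mu0, math.log(s0)])
    res = minimize(
        _nll_and_grad,
        theta0,
        args=(dose, n, deaths),
        jac=True,
        method="Newton-CG",
        options={"xtol": 1e-12, "maxiter": 200},
    )
    # Quasi-Newton polish: Newton-CG can stall within float tolerance of the
    # optimum when the curvature is nearly flat along log(sigma).
    res = minimize(
        _nll_and_grad,
        res.x,
        args=(dose, n, deaths),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 200},
    )
    mu, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    ll = _loglik(mu, sigma, dose, n, deaths)
    grad_norm = float(np.linalg.norm(res.jac)) if res.jac is not None else math.inf
    converged = bool(grad_norm < 1e-4 and 1e-3 < sigma < 1e3 and np.isfinite(ll))
    cov = _observed_cov(mu, sigma, dose, n, deaths) if converged else None
    diagnostic = "" if converged else f"optimizer: {res.message} (|grad|={grad_norm:.2e})"
    return ProbitFit(
        mu=mu, sigma=sigma, loglik=ll, converged=converged, cov=cov,
        diagnostic=diagnostic, n_total=n_total,
    )


def ld_estimate(fit: ProbitFit, p: float) -> LDEstimate:
    """Dose lethal to fraction ``p`` with delta-method confidence limits."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p={p} outside (0, 1)")
    if not fit.converged:
        raise ValueError(f"probit fit did not converge: {fit.diagnostic}")
    z = float(norm.ppf(p))
    dose = fit.mu + fit.sigma * z
    if fit.cov is not None:
        grad = np.array([1.0, z])
        var = float(grad @ fit.cov @ grad)
        half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    else:
        half = math.nan
    return LDEstimate(p=p, dose=dose, ci_low=dose - half, ci_high=dose + half)


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous 30-day surviving-fraction step function for one group."""

    group: str
    n: int
    event_days: tuple[float, ...]  # sorted fate days of deaths

    def at(self, day: float) -> float:
        deaths = sum(1 for d in self.event_days if d <= day)
        return 1.0 - deaths / self.n

    def to_frame(self) -> pd.DataFrame:
        days = [0.0] + sorted(set(self.event_days)) + [30.0]
        days = sorted(set(days))
        return pd.DataFrame(
            {"day": days, "surviving_fraction": [self.at(d) for d in days]}
        )


def survival_curve(study: CohortStudy, group: str) -> SurvivalCurve:
    """Step function of surviving fraction vs day for one group.

    Starts at 1.0; drops by 1/n at each fate day (euthanized and found dead
    both count as deaths); 30-day survivors are censored at day 30 with no
    drop.  Fates must be assigned.
    """
    recs = study.group(str(group))
    if any(r.fate is None for r in recs):
        raise ValueError(f"group {group!r}: fates not assigned; replay or adjudicate first")
    events = tuple(sorted(r.fate_day for r in recs if r.died()))
    return SurvivalCurve(group=str(group), n=len(recs), event_days=events)
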