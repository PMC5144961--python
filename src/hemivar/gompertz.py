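"""Gompertz mortality: interval-censored maximum likelihood per vial.

The demographic model is the Gompertz hazard μ(t) = α·exp(βt), with α the
initial (baseline) mortality rate and β the demographic rate of aging, both
per day.  Mortality in the assay is scored at each 48-h transfer, so each
vial yields an interval-censored death schedule; the two parameters are
estimated per vial by maximizing the multinomial interval likelihood

    ℓ(α, β) = Σ_j d_j · log[S(t_{j−1}) − S(t_j)] + c · log S(t_J),

where S(t) = exp(−(α/β)(exp(βt) − 1)) is the Gompertz survivor function,
d_j the deaths in interval (t_{j−1}, t_j] and c the flies surviving past the
last census.  Optimization is over (log α, β) from a small multi-start grid,
with standard errors from the observed information at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

_BETA_SWITCH = 1e-8  # below this |β| the exponential-limit series is used


def _validate_alpha(alpha: float) -> None:
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")


def gompertz_hazard(alpha: float, beta: float, t):
    """Mortality rate μ(t) = α·exp(βt) (per day)."""
    _validate_alpha(alpha)
    return alpha * np.exp(beta * np.asarray(t, dtype=float))


def log_gompertz_survival(alpha: float, beta: float, t):
    """log S(t); series form exp(−αt) is used for |β| below 1e−8."""
    _validate_alpha(alpha)
    t = np.asarray(t, dtype=float)
    if abs(beta) < _BETA_SWITCH:
        # expm1(βt)/β → t(1 + βt/2) as β → 0
        return -alpha * t * (1.0 + 0.5 * beta * t)
    return -(alpha / beta) * np.expm1(beta * t)


def gompertz_survival(alpha: float, beta: float, t):
    """Survivor function S(t) = exp(−(α/β)(exp(βt) − 1))."""
    return np.exp(log_gompertz_survival(alpha, beta, t))


def gompertz_mean(alpha: float, beta: float) -> float:
    """Expected age at death: (1/β)·exp(α/β)·E1(α/β), or 1/α when β = 0."""
    _validate_alpha(alpha)
    if abs(beta) < _BETA_SWITCH:
        return 1.0 / alpha
    if beta < 0:
        raise ValueError("mean lifespan undefined for beta < 0 "
                         "(defective distribution)")
    x = alpha / beta
    # exp(x)·E1(x) computed stably via scipy for moderate x
    if x < 700.0:
        val = np.exp(x) * special.exp1(x)
    else:  # asymptotic expansion
        val = (1.0 - 1.0 / x + 2.0 / x**2) / x
    return val / beta


def alpha_for_mean_lifespan(beta: float, mean_days: float) -> float:
    """Baseline mortality α giving the requested mean lifespan at aging rate β."""
    if mean_days <= 0:
        raise ValueError("mean_days must be positive")
    if abs(beta) < _BETA_SWITCH:
        return 1.0 / mean_days
    f = lambda la: gompertz_mean(np.exp(la), beta) - mean_days
    return float(np.exp(optimize.brentq(f, -60.0, 10.0, xtol=1e-12)))


@dataclass
class MortalitySchedule:
    """Per-vial census boundaries, deaths per interval, and survivors.

    ``boundaries`` are the J+1 census times t_0 < t_1 < … < t_J (days);
    ``deaths[j]`` counts deaths in (t_j, t_{j+1}]; ``censored`` counts flies
    alive past t_J.
    """

    vial_id: str
    boundaries: np.ndarray
    deaths: np.ndarray
    censored: int = 0

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.deaths = np.asarray(self.deaths, dtype=int)
        if self.boundaries.ndim != 1 or np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.boundaries.size and self.boundaries[0] < 0:
            raise ValueError("census times must be non-negative")
        if self.deaths.size != max(self.boundaries.size - 1, 0):
            raise ValueError("need one death count per census interval")
        if np.any(self.deaths < 0) or self.censored < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.deaths.sum()) + self.censored


@dataclass
class GompertzFit:
    vial_id: str
    alpha: float
    beta: float
    loglik: float
    converged: bool
    n_deaths: int
    se_alpha: float | None = None
    se_beta: float | None = None
    se_log_alpha: float | None = None
    message: str = ""
    log_alpha: float = field(init=False)
    beta_x100: float = field(init=False)

    def __post_init__(self) -> None:
        self.log_alpha = float(np.log(self.alpha))
        self.beta_x100 = 100.0 * self.beta


def _interval_loglik(log_alpha: float, beta: float,
                     bounds: np.ndarray, deaths: np.ndarray,
                     censored: int) -> float:
    alpha = np.exp(log_alpha)
    logS = log_gompertz_survival(alpha, beta, bounds)
    a, b = logS[:-1], logS[1:]
    # log[S(t_{j-1}) - S(t_j)] = logS(t_{j-1}) + log(1 - exp(b - a))
    with np.errstate(divide="ignore"):
        logp = a + np.log(-np.expm1(np.minimum(b - a, -1e-300)))
    mask = deaths > 0
    ll = float(np.dot(deaths[mask], logp[mask]))
    if censored:
        ll += censored * float(logS[-1])
    return ll


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    hs = h * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = hs[i]
            ej = np.zeros(n); ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return H


def fit_gompertz(schedule: MortalitySchedule,
                 beta_grid: tuple[float, ...] = (0.02, 0.08, 0.2),
                 log_alpha_offsets: tuple[float, ...] = (-1.0, 0.0, 1.0),
                 ) -> GompertzFit:
    """Maximum-likelihood (α, β) for one vial's interval-censored schedule.

    Runs a 3×3 multi-start (β guesses crossed with log-α offsets around a
    moment-matched baseline) because the likelihood can be flat in β for
    small cohorts.  Standard errors come from the observed information on the
    (log α, β) scale; ``se_alpha`` is delta-method transformed.
    """
    if schedule.deaths.size == 0:
        raise ValueError("empty schedule: no census intervals")
    n_deaths = int(schedule.deaths.sum())
    if n_deaths == 0:
        raise ValueError("no deaths observed; Gompertz parameters unidentifiable")
    bounds = schedule.boundaries
    deaths = schedule.deaths
    if np.count_nonzero(deaths) < 2:
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        j = int(np.flatnonzero(deaths)[0])
        return GompertzFit(schedule.vial_id, alpha=1.0 / max(mids[j], 1e-6),
                           beta=0.0, loglik=np.nan, converged=False,
                           n_deaths=n_deaths, message="beta_unidentifiable")

    mids = 0.5 * (bounds[:-1] + bounds[1:])
    mean_death = float(np.dot(deaths, mids) / n_deaths)

    def nll(x):
        return -_interval_loglik(x[0], x[1], bounds, deaths, schedule.censored)

    best = None
    for b0 in beta_grid:
        la_center = np.log(alpha_for_mean_lifespan(b0, mean_death))
        for off in log_alpha_offsets:
            x0 = np.array([la_center + off, b0])
            res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10,
                                             "maxiter": 600})
            if best is None or res.fun < best.fun:
                best = res
    # polish with gradient-based step
    res = optimize.minimize(nll, best.x, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 200})
    if res.fun <= best.fun:
        best = res
    x_hat = best.x
    ll = -float(best.fun)
    grad_ok = True
    if hasattr(best, "jac") and best.jac is not None:
        grad_ok = float(np.linalg.norm(best.jac)) < 1e-3 * max(1.0, abs(ll))

    H = _numeric_hessian(nll, x_hat)
    se_la = se_b = None
    hess_pd = False
    try:
        cov = np.linalg.inv(H)
        if cov[0, 0] > 0 and cov[1, 1] > 0:
            hess_pd = True
            se_la = float(np.sqrt(cov[0, 0]))
            se_b = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        pass

    alpha_hat = float(np.exp(x_hat[0]))
    return GompertzFit(
        schedule.vial_id, alpha=alpha_hat, beta=float(x_hat[1]), loglik=ll,
        converged=bool(grad_ok and hess_pd and np.isfinite(ll)),
        n_deaths=n_deaths,
        se_alpha=alpha_hat * se_la if se_la is not None else None,
        se_beta=se_b, se_log_alpha=se_la,
        message="" if grad_ok else "large_gradient",
    )


def fit_gompertz_many(schedules) -> list[GompertzFit]:
    return [fit_gompertz(s) for s in schedules]


def log_alpha_beta_correlation(fits, confidence: float = 0.95) -> dict:
    """Pearson correlation of log α̂ with β̂ across converged vial fits.

    Returns r with a Fisher-z confidence interval and two-sided p-value; at
    least three converged fits with non-degenerate spread are required.
    """
    fits = [f for f in fits if f.converged]
    if len(fits) < 3:
        raise ValueError("need at least 3 converged fits")
    la = np.array([f.log_alpha for f in fits])
    b = np.array([f.beta for f in fits])
    if np.ptp(la) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate input: zero variance in log(alpha) or beta")
    res = stats.pearsonr(la, b)
    ci = res.confidence_interval(confidence_level=confidence)
    return {"r": float(res.statistic), "p": float(res.pvalue),
            "ci_low": float(ci.low), "ci_high": float(ci.high),
            "n": len(fits)}


# ---------------------------------------------------------------- CSV I/O

SCHEDULE_COLUMNS = ["vial_id", "interval_start_day", "interval_end_day",
                    "deaths", "censored"]


def schedules_to_frame(schedules) -> pd.DataFrame:
    rows = []
    for s in schedules:
        for j in range(s.deaths.size):
            rows.append((s.vial_id, s.boundaries[j], s.boundaries[j + 1],
                         int(s.deaths[j]), int(s.censored) if j == s.deaths.size - 1 else 0))
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def frame_to_schedules(df: pd.DataFrame) -> list[MortalitySchedule]:
    out = []
    for vial_id, grp in df.groupby("vial_id", sort=False):
        grp = grp.sort_values("interval_start_day")
        bounds = np.concatenate([grp["interval_start_day"].to_numpy()[:1],
                                 grp["interval_end_day"].to_numpy()])
        out.append(MortalitySchedule(
            vial_id=str(vial_id), boundaries=bounds,
            deaths=grp["deaths"].to_numpy(),
            censored=int(grp["censored"].iloc[-1])))
    return out


def fits_to_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([{
        "vial_id": f.vial_id, "alpha": f.alpha, "beta": f.beta,
        "beta_x100": f.beta_x100, "log_alpha": f.log_alpha,
        "loglik": f.loglik, "se_alpha": f.se_alpha, "se_beta": f.se_beta,
        "converged": f.converged,
    } for f in fits])
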