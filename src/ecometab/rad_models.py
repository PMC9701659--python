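"""Rank-abundance distribution (RAD) models with Poisson ML fitting.

Five classical models are fitted to a descending-sorted abundance vector
and compared by AIC: the broken stick (null, no free parameters),
geometric-series niche preemption (alpha), the quantile-parameterized
lognormal (mu, sigma), Zipf (p1, gamma) and Zipf-Mandelbrot (c, beta,
gamma).  Counts are modelled with a Poisson error family, the standard
choice for ion-count abundances; parameters maximize the Poisson
likelihood of the observed counts given the model's expected abundance
at each rank.  The Zipf-Mandelbrot likelihood is multimodal, so every
free-parameter fit is restarted from several seeded random
perturbations of a heuristic initial guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, ndtri

MODELS = ("brokenstick", "preemption", "lognormal", "zipf", "zipf_mandelbrot")
N_PARAMS = {
    "brokenstick": 0,
    "preemption": 1,
    "lognormal": 2,
    "zipf": 2,
    "zipf_mandelbrot": 3,
}

_EPS = 1e-10


@dataclass
class RADFit:
    model: str
    params: dict[str, float]
    expected: np.ndarray
    deviance: float
    aic: float
    loglik: float
    n_params: int
    converged: bool
    message: str = ""
    residual_sd: float = float("nan")


def rad_expected(
    model: str, params: dict[str, float], S: int, N: float
) -> np.ndarray:
    """Expected abundance at ranks 1..S under a named RAD model."""
    if S < 1:
        raise ValueError("S must be >= 1")
    if N <= 0:
        raise ValueError("N must be positive")
    r = np.arange(1, S + 1, dtype=float)
    if model == "brokenstick":
        return (N / S) * np.cumsum((1.0 / r)[::-1])[::-1]
    if model == "preemption":
        a = params["alpha"]
        if not (0 < a < 1):
            raise ValueError("preemption alpha must be in (0, 1)")
        geo = a * (1 - a) ** (r - 1)
        return N * geo / (1 - (1 - a) ** S)
    if model == "lognormal":
        mu, sigma = params["mu"], params["sigma"]
        if sigma < 0:
            raise ValueError("lognormal sigma must be non-negative")
        q = (S - r + 0.5) / S
        return np.exp(mu + sigma * ndtri(q))
    if model == "zipf":
        p1, gamma = params["p1"], params["gamma"]
        if gamma >= 0:
            raise ValueError("zipf gamma must be negative")
        return N * p1 * r**gamma
    if model == "zipf_mandelbrot":
        c, beta, gamma = params["c"], params["beta"], params["gamma"]
        if beta < 0:
            raise ValueError("zipf_mandelbrot beta must be non-negative")
        return N * c * (r + beta) ** gamma
    raise ValueError(f"unknown RAD model {model!r}")


def _poisson_loglik(y: np.ndarray, lam: np.ndarray) -> float:
    lam = np.clip(lam, _EPS, None)
    return float(np.sum(y * np.log(lam) - lam - gammaln(y + 1)))


def _poisson_deviance(y: np.ndarray, lam: np.ndarray) -> float:
    lam = np.clip(lam, _EPS, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / lam), 0.0)
    return float(2.0 * np.sum(term - (y - lam)))


# parameter transforms: optimizer works on unconstrained theta
def _pack(model: str, params: dict[str, float]) -> np.ndarray:
    if model == "preemption":
        a = params["alpha"]
        return np.array([np.log(a / (1 - a))])
    if model == "lognormal":
        return np.array([params["mu"], np.log(max(params["sigma"], _EPS))])
    if model == "zipf":
        return np.array([np.log(max(params["p1"], _EPS)), np.log(-params["gamma"])])
    if model == "zipf_mandelbrot":
        return np.array(
            [
                np.log(max(params["c"], _EPS)),
                np.log(max(params["beta"], _EPS)),
                np.log(-params["gamma"]),
            ]
        )
    return np.array([])


def _exp(t: float) -> float:
    return float(np.exp(np.clip(t, -700.0, 700.0)))


def _unpack(model: str, theta: np.ndarray) -> dict[str, float]:
    if model == "preemption":
        return {"alpha": 1.0 / (1.0 + _exp(-theta[0]))}
    if model == "lognormal":
        return {"mu": theta[0], "sigma": _exp(theta[1])}
    if model == "zipf":
        return {"p1": _exp(theta[0]), "gamma": -_exp(theta[1])}
    if model == "zipf_mandelbrot":
        return {"c": _exp(theta[0]), "beta": _exp(theta[1]), "gamma": -_exp(theta[2])}
    return {}


def _initial_guess(model: str, y: np.ndarray, N: float) -> dict[str, float]:
    S = y.size
    r = np.arange(1, S + 1, dtype=float)
    logy = np.log(np.clip(y, _EPS, None))
    if model == "preemption":
        a0 = min(max(y[0] / N, 0.01), 0.95)
        return {"alpha": a0}
    if model == "lognormal":
        return {"mu": float(logy.mean()), "sigma": float(max(logy.std(), 0.1))}
    slope, intercept = np.polyfit(np.log(r), logy, 1)
    gamma0 = min(slope, -0.05)
    if model == "zipf":
        return {"p1": float(np.exp(intercept) / N), "gamma": float(gamma0)}
    return {
        "c": float(np.exp(intercept) / N),
        "beta": 0.1,
        "gamma": float(gamma0),
    }


def fit_rad(
    abundances: Sequence[float],
    model: str,
    n_restarts: int = 5,
    seed: int | None = 0,
) -> RADFit:
    """Fit one RAD model to an abundance vector by Poisson ML.

    Input is sorted descending internally.  Non-convergence is reported
    on the returned fit (``converged=False``), never raised, so model
    selection can still tabulate the attempt.
    """
    if model not in MODELS:
        raise ValueError(f"unknown RAD model {model!r}")
    y = np.sort(np.asarray(abundances, dtype=float))[::-1]
    if (y <= 0).any():
        raise ValueError("abundances must be strictly positive")
    S, N = y.size, float(y.sum())
    k = N_PARAMS[model]

    if model == "brokenstick":
        lam = rad_expected(model, {}, S, N)
        ll = _poisson_loglik(y, lam)
        return RADFit(
            model=model,
            params={},
            expected=lam,
            deviance=_poisson_deviance(y, lam),
            aic=-2 * ll,
            loglik=ll,
            n_params=0,
            converged=True,
            residual_sd=float(np.std(y - lam, ddof=0)),
        )

    if S < k:
        return RADFit(
            model=model, params={}, expected=np.full(S, np.nan),
            deviance=float("inf"), aic=float("inf"), loglik=-float("inf"),
            n_params=k, converged=False,
            message=f"S={S} too small for {k} parameters",
        )

    def objective(theta: np.ndarray) -> float:
        params = _unpack(model, theta)
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                lam = rad_expected(model, params, S, N)
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.all(np.isfinite(lam)):
            return 1e12
        return -_poisson_loglik(y, lam)

    rng = np.random.default_rng(seed)
    theta0 = _pack(model, _initial_guess(model, y, N))
    starts = [theta0] + [
        theta0 + rng.normal(0.0, 0.5, size=theta0.size) for _ in range(n_restarts - 1)
    ]
    best = None
    for t0 in starts:
        res = optimize.minimize(objective, t0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    params = _unpack(model, best.x)
    try:
        lam = rad_expected(model, params, S, N)
        ok = bool(best.success) and np.all(np.isfinite(lam))
    except ValueError:
        lam, ok = np.full(S, np.nan), False
    ll = _poisson_loglik(y, lam) if ok else -float("inf")
    return RADFit(
        model=model,
        params={kk: float(v) for kk, v in params.items()},
        expected=lam,
        deviance=_poisson_deviance(y, lam) if ok else float("inf"),
        aic=-2 * ll + 2 * k if ok else float("inf"),
        loglik=ll,
        n_params=k,
        converged=ok,
        message=str(best.message),
        residual_sd=float(np.std(y - lam, ddof=0)) if ok else float("nan"),
    )


@dataclass
class RADSelection:
    fits: dict[str, RADFit]
    table: pd.DataFrame
    best: RADFit


def select_rad(
    abundances: Sequence[float], n_restarts: int = 5, seed: int | None = 0
) -> RADSelection:
    """Fit all five models and rank them by AIC (ties: fewer parameters)."""
    fits = {m: fit_rad(abundances, m, n_restarts=n_restarts, seed=seed) for m in MODELS}
    rows = [
        {
            "model": m,
            "n_params": f.n_params,
            "deviance": f.deviance,
            "aic": f.aic,
            "residual_sd": f.residual_sd,
            "converged": f.converged,
        }
        for m, f in fits.items()
    ]
    table = (
        pd.DataFrame(rows)
        .sort_values(["aic", "n_params"], kind="stable")
        .reset_index(drop=True)
    )
    usable = [f for f in fits.values() if np.isfinite(f.aic)]
    if not usable:
        raise RuntimeError("all RAD fits failed")
    best = min(usable, key=lambda f: (f.aic, f.n_params))
    return RADSelection(fits=fits, table=table, best=best)
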