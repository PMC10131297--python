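"""Phenomenological (logistic-growth) model fits to abundance time series.

Four discrete-time models of the per-capita growth rate
r_t = ln(N_{t+1}/N_t) are compared:

    random walk   r = 0                      (k = 1: sigma)
    exponential   r = alpha                  (k = 2)
    Ricker        r = alpha + beta N_t       (k = 3)
    Gompertz      r = alpha + beta ln N_t    (k = 3)

All are Gaussian regressions fitted by least squares (the maximum-likelihood
solution), with sigma^2 estimated as RSS/n and counted as a parameter.
Small-sample AICc weights give each model's probability; the evidence for an
ensemble density feedback is the summed weight of the Ricker and Gompertz
models, and its strength is the negated Gompertz slope (positive =
compensation, negative = depensation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MODELS",
    "MIN_TRANSITIONS",
    "ModelFit",
    "EnsembleResult",
    "growth_rates",
    "fit_model",
    "aicc",
    "akaike_weights",
    "fit_all_models",
    "ensemble_result",
    "fit_series",
]

MODELS = ("random_walk", "exponential", "ricker", "gompertz")
K_PARAMS = {"random_walk": 1, "exponential": 2, "ricker": 3, "gompertz": 3}

#: Series with fewer usable transitions than this are not fitted.
MIN_TRANSITIONS = 30


@dataclass
class ModelFit:
    model: str
    k: int
    n_obs: int
    alpha_hat: float
    beta_hat: float
    sigma2_hat: float
    logL: float
    AICc: float
    wAICc: float = float("nan")


@dataclass
class EnsembleResult:
    pr_density_feedback: float
    strength: float        # -beta_hat of the Gompertz model
    ricker_beta: float
    n_transitions: int


def growth_rates(N_t: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-capita growth rates and their aligned predictors.

    Returns (r, N_used, n_dropped) where r_t = ln(N_{t+1}/N_t) for every
    transition with both endpoints positive, N_used are the matching N_t
    values, and n_dropped counts transitions lost to non-positive abundances.
    """
    N = np.asarray(N_t, dtype=float)
    if len(N) < 2:
        raise ValueError("need at least two census values")
    ok = (N[:-1] > 0) & (N[1:] > 0)
    r = np.log(N[1:][ok] / N[:-1][ok])
    return r, N[:-1][ok], int(np.sum(~ok))


def _least_squares(y: np.ndarray, x: np.ndarray | None):
    """(alpha, beta, RSS) for y = alpha + beta x (x None -> intercept only)."""
    n = len(y)
    if x is None:
        alpha = float(y.mean())
        resid = y - alpha
        return alpha, 0.0, float(resid @ resid)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate predictor: no variation in abundance")
    beta = float(((x - xm) * (y - ym)).sum()) / sxx
    alpha = ym - beta * xm
    resid = y - alpha - beta * x
    return alpha, beta, float(resid @ resid)


def _gaussian_logL(rss: float, n: int) -> tuple[float, float]:
    sigma2 = max(rss / n, 1e-300)
    return sigma2, -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def fit_model(r_t: np.ndarray, N_t: np.ndarray, model: str) -> ModelFit:
    """Fit one of the four phenomenological models by least squares."""
    r = np.asarray(r_t, dtype=float)
    N = np.asarray(N_t, dtype=float)
    n = len(r)
    k = K_PARAMS[model]
    if n < k + 2:
        raise ValueError(f"{model}: need n >= k + 2 transitions (got {n})")
    if model == "random_walk":
        alpha = beta = 0.0
        rss = float(r @ r)
    elif model == "exponential":
        alpha, beta, rss = _least_squares(r, None)
    elif model == "ricker":
        alpha, beta, rss = _least_squares(r, N)
    elif model == "gompertz":
        alpha, beta, rss = _least_squares(r, np.log(N))
    else:
        raise ValueError(f"unknown model {model!r}")
    sigma2, logL = _gaussian_logL(rss, n)
    return ModelFit(
        model=model, k=k, n_obs=n, alpha_hat=alpha, beta_hat=beta,
        sigma2_hat=sigma2, logL=logL, AICc=aicc(logL, k, n),
    )


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc undefined: n must exceed k + 1")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Relative model probabilities from a set of AICc values."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def fit_all_models(N_t: np.ndarray) -> dict[str, ModelFit]:
    """Fit all four models to one census and attach AICc weights."""
    r, N, _ = growth_rates(N_t)
    fits = {m: fit_model(r, N, m) for m in MODELS}
    w = akaike_weights([fits[m].AICc for m in MODELS])
    for m, wi in zip(MODELS, w):
        fits[m].wAICc = float(wi)
    return fits


def ensemble_result(fits: dict[str, ModelFit]) -> EnsembleResult:
    """Evidence and strength of the ensemble density feedback."""
    return EnsembleResult(
        pr_density_feedback=fits["ricker"].wAICc + fits["gompertz"].wAICc,
        strength=-fits["gompertz"].beta_hat,
        ricker_beta=fits["ricker"].beta_hat,
        n_transitions=fits["gompertz"].n_obs,
    )


def fit_series(N_t: np.ndarray, min_transitions: int = MIN_TRANSITIONS):
    """Full per-series analysis: four fits plus the ensemble summary.

    Returns (fits, EnsembleResult) or (None, None) when too few usable
    transitions remain (short or extinct series).
    """
    r, N, _ = growth_rates(np.asarray(N_t, dtype=float))
    if len(r) < min_transitions:
        return None, None
    fits = fit_all_models(N_t)
    return fits, ensemble_result(fits)
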