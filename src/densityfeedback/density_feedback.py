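"""Component (vital-rate level) compensatory density feedback on survival.

The feedback multiplies the whole survival vector by a sigmoid reduction
modifier of total population size,

    S_red(N) = a / (1 + (N / b)^c),

so survival is undepressed at very low density (S_red -> a, with a = 1 by
default), halves its headroom at N = b, and falls off with steepness c.  The
constants are calibrated per species so that the deterministic matrix is
exactly stationary (lambda = 1) at the species' carrying capacity K, which is
what makes long-run stochastic dynamics hover around K with mean growth rate
near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FeedbackParams",
    "CalibrationRecord",
    "SplitFeedback",
    "s_red",
    "apply_feedback",
    "equilibrium_survival_multiplier",
    "solve_b_for_equilibrium",
    "calibrate_feedback",
    "component_strength",
    "split_feedback_with_fertility",
    "survival_fertility_elasticities",
]


@dataclass
class FeedbackParams:
    """Constants of the survival reduction modifier."""

    a: float = 1.0
    b: float = 1.0
    c: float = 2.0
    applies_to: str = "survival"  # survival | survival+fertility | none

    def __post_init__(self) -> None:
        if not (0 < self.a <= 1):
            raise ValueError("a must lie in (0, 1]")
        if self.b <= 0 or self.c <= 0:
            raise ValueError("b and c must be positive")
        if self.applies_to not in ("survival", "survival+fertility", "none"):
            raise ValueError(f"unknown applies_to {self.applies_to!r}")


@dataclass
class CalibrationRecord:
    achieved_mean_r: float
    equilibrium_ratio: float  # long-run mean abundance / K
    replicates_used: int
    iterations: int
    converged: bool


def s_red(total_n, p: FeedbackParams):
    """Survival reduction modifier at total abundance ``total_n``.

    Accepts scalars or arrays; ``b`` may also be an array (fluctuating
    carrying capacity).  Values lie in (0, a].
    """
    n = np.asarray(total_n, dtype=float)
    if np.any(n < 0):
        raise ValueError("total abundance must be non-negative")
    out = p.a / (1.0 + (n / p.b) ** p.c)
    return out if out.ndim else float(out)


def apply_feedback(S: np.ndarray, total_n: float, p: FeedbackParams) -> np.ndarray:
    """Survival vector scaled by the reduction modifier, clipped to [0, 1]."""
    if p.applies_to == "none":
        return np.asarray(S, dtype=float).copy()
    mod = s_red(total_n, p)
    return np.clip(np.asarray(S, dtype=float) * mod, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _lambda_scaled(lh, s: float) -> float:
    """Dominant eigenvalue with every survival multiplied by ``s``."""
    n = lh.omega + 1
    M = np.zeros((n, n))
    M[0, :] = lh.m
    M[np.arange(1, n), np.arange(0, n - 1)] = lh.S[:-1] * s
    M[n - 1, n - 1] = lh.S[-1] * s
    return float(np.max(np.linalg.eigvals(M).real))


def equilibrium_survival_multiplier(lh) -> float:
    """Uniform survival multiplier s* with lambda(s* . S) = 1.

    Raises if the population cannot grow even with unreduced survival
    (lambda < 1 at s = 1), in which case no compensatory equilibrium exists.
    """
    if _lambda_scaled(lh, 1.0) < 1.0:
        raise ValueError(
            f"{lh.species.abbr}: lambda < 1 with unreduced survival; "
            "no compensatory equilibrium"
        )
    return brentq(lambda s: _lambda_scaled(lh, s) - 1.0, 1e-6, 1.0, xtol=1e-12)


def solve_b_for_equilibrium(K: float, s_star: float, a: float, c: float) -> float:
    """Half-saturation abundance placing S_red(K) = s*."""
    if not (0 < s_star < a):
        raise ValueError("need 0 < s* < a for a finite b")
    return K / (a / s_star - 1.0) ** (1.0 / c)


def calibrate_feedback(
    lh,
    horizon_generations: float = 40.0,
    target_mean_r: float = 0.0,
    tol: float = 0.005,
    n_reps: int = 50,
    rng_seed: int = 0,
    a: float = 1.0,
    c: float = 2.0,
    validate: bool = True,
) -> tuple[FeedbackParams, CalibrationRecord]:
    """Calibrate (a, b, c) so the population is stable at K on average.

    ``a`` is fixed at 1 (no survival depression at zero density) and ``c``
    sets the steepness; ``b`` is solved analytically so that the deterministic
    matrix is stationary exactly at carrying capacity.  A stochastic
    validation run (survival/fertility resampling only, as in the
    no-catastrophe scenario) then measures the achieved mean yearly growth
    rate and equilibrium abundance over ``horizon_generations`` generations.
    """
    try:
        s_star = equilibrium_survival_multiplier(lh)
    except ValueError:
        p = FeedbackParams(a=a, b=lh.K, c=c)
        rec = CalibrationRecord(
            achieved_mean_r=float("nan"),
            equilibrium_ratio=float("nan"),
            replicates_used=0,
            iterations=0,
            converged=False,
        )
        return p, rec
    b = solve_b_for_equilibrium(lh.K, s_star, a, c)
    p = FeedbackParams(a=a, b=b, c=c)
    if not validate:
        return p, CalibrationRecord(0.0, 1.0, 0, 1, True)

    from . import projection  # deferred: projection imports this module

    scen = projection.get_scenario("i")
    n_years = int(round(horizon_generations * lh.species.gl_target))
    batch = projection.project_batch(
        lh,
        p,
        scen,
        n_reps=n_reps,
        rng=np.random.default_rng(np.random.SeedSequence([rng_seed, 0xFEED])),
        n_years=n_years,
    )
    mean_r = float(np.nanmean(batch.r))
    eq_ratio = float(np.nanmean(batch.N) / lh.K)
    converged = abs(mean_r - target_mean_r) <= tol
    rec = CalibrationRecord(
        achieved_mean_r=mean_r,
        equilibrium_ratio=eq_ratio,
        replicates_used=n_reps,
        iterations=1,
        converged=converged,
    )
    return p, rec


def component_strength(series, summary: str = "mean") -> float:
    """Strength of the component feedback, summarizing 1 - S_red over time.

    ``series`` is anything with an ``s_red_t`` attribute or an array of
    S_red values.  Summaries: "mean" (default), "median", "terminal".
    """
    trace = getattr(series, "s_red_t", series)
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty S_red trace")
    x = 1.0 - trace
    if summary == "mean":
        return float(np.mean(x))
    if summary == "median":
        return float(np.median(x))
    if summary == "terminal":
        return float(x[-1])
    raise ValueError(f"unknown summary {summary!r}")


# ---------------------------------------------------------------------------
# Optional split of the feedback between survival and fertility
# ---------------------------------------------------------------------------

def survival_fertility_elasticities(lh, survival_multiplier: float = 1.0):
    """Elasticities of lambda to uniform scaling of survival vs fertility.

    Evaluated on the matrix with survival scaled by ``survival_multiplier``
    (use the equilibrium multiplier s* to evaluate at carrying capacity).
    They sum to 1 because the matrix is linear in its entries.
    """
    n = lh.omega + 1
    M = np.zeros((n, n))
    M[0, :] = lh.m
    M[np.arange(1, n), np.arange(0, n - 1)] = lh.S[:-1] * survival_multiplier
    M[n - 1, n - 1] = lh.S[-1] * survival_multiplier
    vals, vecs = np.linalg.eig(M)
    i = int(np.argmax(vals.real))
    lam = float(vals[i].real)
    w = np.abs(vecs[:, i].real)
    lvals, lvecs = np.linalg.eig(M.T)
    j = int(np.argmax(lvals.real))
    v = np.abs(lvecs[:, j].real)
    denom = lam * float(v @ w)
    F = np.zeros_like(M)
    F[0, :] = M[0, :]
    T = M - F
    e_f = float(v @ (F @ w)) / denom
    e_s = float(v @ (T @ w)) / denom
    return e_s, e_f


@dataclass
class SplitFeedback:
    """Density feedback split between survival and fertility.

    The survival modifier is S_red^(1-phi) and the fertility modifier is
    S_red^(phi * e_S / e_F), so to first order the density effect on lambda
    matches the survival-only calibration at every abundance (the fertility
    exponent compensates for fertility's smaller elasticity).
    """

    base: FeedbackParams
    split_fraction: float
    fertility_exponent: float

    def survival_modifier(self, total_n):
        return s_red(total_n, self.base) ** (1.0 - self.split_fraction)

    def fertility_modifier(self, total_n):
        return s_red(total_n, self.base) ** (
            self.split_fraction * self.fertility_exponent
        )


def split_feedback_with_fertility(
    p: FeedbackParams, split_fraction: float, lh=None
) -> SplitFeedback:
    """Split the calibrated feedback between survival and fertility.

    ``split_fraction`` = 0 reproduces the survival-only feedback; 1 moves all
    of it onto fertility.  When a life history is supplied the fertility
    exponent is set from the survival/fertility elasticities at the
    calibrated equilibrium (equal-lambda-effect split); otherwise the raw
    modifier is used for both rates.
    """
    if not (0.0 <= split_fraction <= 1.0):
        raise ValueError("split_fraction must lie in [0, 1]")
    if lh is not None:
        s_star = equilibrium_survival_multiplier(lh)
        e_s, e_f = survival_fertility_elasticities(lh, s_star)
        exponent = e_s / e_f if e_f > 0 else 1.0
    else:
        exponent = 1.0
    base = FeedbackParams(p.a, p.b, p.c, applies_to="survival+fertility")
    return SplitFeedback(base=base, split_fraction=split_fraction,
                         fertility_exponent=exponent)


def write_feedback_params(entries, path) -> None:
    """Persist calibrated constants, one species per line (plain text)."""
    with open(path, "w") as fh:
        fh.write("abbr\ta\tb\tc\tseed\tachieved_mean_r\tconverged\n")
        for abbr, p, seed, rec in entries:
            fh.write(
                f"{abbr}\t{p.a!r}\t{p.b!r}\t{p.c!r}\t{seed}\t"
                f"{rec.achieved_mean_r!r}\t{int(rec.converged)}\n"
            )


def read_feedback_params(path) -> dict[str, FeedbackParams]:
    out: dict[str, FeedbackParams] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            abbr, a, b, c, _seed, _r, _conv = line.rstrip("\n").split("\t")
            out[abbr] = FeedbackParams(float(a), float(b), float(c))
    return out
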