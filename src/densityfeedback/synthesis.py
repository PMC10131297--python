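"""Species-level aggregation: percentile summaries, interval-bootstrapped
Spearman correlations, and exponential-plateau fits.

Per-series metrics (ensemble strength, component strength, detection
probability, stationarity index) are summarized per species as the median and
2.5-97.5 percentile interval over replicate series.  Cross-species
correlations are estimated with an interval bootstrap: each iteration draws
one uniform value inside every species' interval for both metrics and
computes Spearman's rho across species; the bootstrap median and 95% interval
quantify how strongly between-species differences in one metric track the
other given within-species uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "SpeciesSummary",
    "CorrelationResult",
    "PlateauFit",
    "METRICS",
    "summarize_species",
    "bootstrap_spearman",
    "fit_plateau",
    "plateau_curve",
    "scenario_report",
]

METRICS = ("strength", "component_strength", "pr_density_feedback", "stat_index")


@dataclass
class SpeciesSummary:
    species: str
    scenario: str
    n_series: int
    n_excluded: int
    median: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    reliable: bool = True


@dataclass
class CorrelationResult:
    scenario: str
    x_metric: str
    y_metric: str
    rho_median: float
    rho_lower: float
    rho_upper: float
    n_boot: int
    n_redrawn: int = 0


@dataclass
class PlateauFit:
    y0: float
    ymax: float
    k_rate: float
    converged: bool


def summarize_species(
    results: pd.DataFrame, scenario: str, metrics=METRICS
) -> list[SpeciesSummary]:
    """Median and 95% percentile interval of each metric, per species.

    ``results`` holds one row per fitted series with columns ``species``,
    ``scenario`` and the metric columns.  Species with fewer than 3 usable
    replicates are flagged unreliable.
    """
    sub = results[results["scenario"] == scenario]
    out: list[SpeciesSummary] = []
    for sp, grp in sub.groupby("species", sort=True):
        med, lo, hi = {}, {}, {}
        for m in metrics:
            vals = grp[m].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                med[m] = lo[m] = hi[m] = float("nan")
                continue
            med[m] = float(np.median(vals))
            lo[m] = float(np.percentile(vals, 2.5))
            hi[m] = float(np.percentile(vals, 97.5))
        n_excl = int(grp["excluded"].sum()) if "excluded" in grp else 0
        out.append(
            SpeciesSummary(
                species=sp,
                scenario=scenario,
                n_series=len(grp),
                n_excluded=n_excl,
                median=med,
                lower=lo,
                upper=hi,
                reliable=len(grp) >= 3,
            )
        )
    return out


def bootstrap_spearman(
    summaries: list[SpeciesSummary],
    x_metric: str,
    y_metric: str,
    n_boot: int = 10_000,
    rng_seed: int = 0,
) -> CorrelationResult:
    """Uniform-within-interval bootstrap of Spearman's rho across species.

    Each iteration draws one value uniformly inside every species' 95%
    interval for x and y and computes rho over species (average ranks for
    ties).  Degenerate iterations (all draws equal) are redrawn and counted.
    """
    usable = [
        s for s in summaries
        if s.reliable
        and np.isfinite(s.lower[x_metric]) and np.isfinite(s.upper[x_metric])
        and np.isfinite(s.lower[y_metric]) and np.isfinite(s.upper[y_metric])
    ]
    n_sp = len(usable)
    if n_sp < 5:
        raise ValueError(f"need >= 5 species with finite intervals, got {n_sp}")
    rng = np.random.default_rng(rng_seed)
    xlo = np.array([s.lower[x_metric] for s in usable])
    xhi = np.array([s.upper[x_metric] for s in usable])
    ylo = np.array([s.lower[y_metric] for s in usable])
    yhi = np.array([s.upper[y_metric] for s in usable])
    scen = usable[0].scenario

    def draw(k: int) -> np.ndarray:
        x = rng.uniform(xlo, xhi, size=(k, n_sp))
        y = rng.uniform(ylo, yhi, size=(k, n_sp))
        rx = stats.rankdata(x, axis=1)
        ry = stats.rankdata(y, axis=1)
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            return (rx * ry).sum(axis=1) / denom

    rhos = draw(n_boot)
    n_redrawn = 0
    for _ in range(100):
        bad = ~np.isfinite(rhos)
        nb = int(bad.sum())
        if nb == 0:
            break
        n_redrawn += nb
        rhos[bad] = draw(nb)
    rhos = rhos[np.isfinite(rhos)]
    return CorrelationResult(
        scenario=scen,
        x_metric=x_metric,
        y_metric=y_metric,
        rho_median=float(np.median(rhos)),
        rho_lower=float(np.percentile(rhos, 2.5)),
        rho_upper=float(np.percentile(rhos, 97.5)),
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )


def plateau_curve(x: np.ndarray, y0: float, ymax: float, k: float) -> np.ndarray:
    """Exponential plateau y = ymax - (ymax - y0) * exp(-k x)."""
    return ymax - (ymax - y0) * np.exp(-k * np.asarray(x, dtype=float))


def fit_plateau(x, y) -> PlateauFit:
    """Nonlinear least squares of the exponential plateau, multi-start in k.

    Flat data leave ymax unidentifiable; the fit is then reported with
    converged=False (the flat curve itself is still returned via y0 = ymax).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit the plateau model")
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        return PlateauFit(y0=float(y.mean()), ymax=float(y.mean()),
                          k_rate=0.0, converged=False)
    xspan = np.ptp(x) if np.ptp(x) > 0 else 1.0
    y0_init = float(y[np.argmin(x)])
    ymax_init = float(y.max())
    best = None
    for k0 in (0.3 / xspan, 1.0 / xspan, 3.0 / xspan, 10.0 / xspan):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    plateau_curve, x, y, p0=(y0_init, ymax_init, k0), maxfev=5000
                )
        except RuntimeError:
            continue
        rss = float(((y - plateau_curve(x, *popt)) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return PlateauFit(y0=y0_init, ymax=ymax_init, k_rate=float("nan"),
                          converged=False)
    y0, ymax, k = best[1]
    return PlateauFit(y0=float(y0), ymax=float(ymax), k_rate=float(k),
                      converged=bool(np.isfinite(k)))


def scenario_report(
    results: pd.DataFrame,
    n_boot: int = 10_000,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-scenario summary tables from the per-series results.

    Returns (scenario_table, correlation_table).  The scenario table carries
    the median detection probability, the share of series supporting a
    feedback (Pr > 0.5; the false-positive rate when the scenario has no
    component feedback), and the bootstrapped across-species mean/IQR of
    ensemble strength.  The correlation table holds the interval-bootstrapped
    Spearman rho of ensemble strength against component strength and against
    the stationarity index.
    """
    scen_rows = []
    corr_rows = []
    for k, scen in enumerate(sorted(results["scenario"].unique())):
        sub = results[results["scenario"] == scen]
        summaries = summarize_species(results, scen)
        pr = sub["pr_density_feedback"].to_numpy(dtype=float)
        pr = pr[np.isfinite(pr)]
        strength_meds = [s.median["strength"] for s in summaries if s.reliable]
        scen_rows.append(
            {
                "scenario": scen,
                "n_series": len(sub),
                "n_species": sub["species"].nunique(),
                "median_pr_density_feedback": float(np.median(pr)),
                "share_pr_above_0.5": float(np.mean(pr > 0.5)),
                "strength_mean": float(np.mean(strength_meds)),
                "strength_q25": float(np.percentile(strength_meds, 25)),
                "strength_q75": float(np.percentile(strength_meds, 75)),
            }
        )
        if sub["species"].nunique() >= 5:
            for y_metric in ("component_strength", "stat_index"):
                try:
                    c = bootstrap_spearman(
                        summaries, "strength", y_metric,
                        n_boot=n_boot, rng_seed=rng_seed + k,
                    )
                except ValueError:
                    continue
                corr_rows.append(
                    {
                        "scenario": scen,
                        "x_metric": c.x_metric,
                        "y_metric": c.y_metric,
                        "rho_median": c.rho_median,
                        "rho_lower": c.rho_lower,
                        "rho_upper": c.rho_upper,
                        "n_boot": c.n_boot,
                    }
                )
    return pd.DataFrame(scen_rows), pd.DataFrame(corr_rows)
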