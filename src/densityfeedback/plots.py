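"""Basic diagnostic plots for the decoupling analyses (optional)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .synthesis import SpeciesSummary, fit_plateau, plateau_curve

__all__ = ["plot_decoupling"]


def plot_decoupling(
    summaries: list[SpeciesSummary],
    path: str | Path,
    x_metric: str = "component_strength",
    y_metric: str = "strength",
) -> None:
    """Scatter of per-species medians with 95% interval bars and the fitted
    exponential-plateau curve, written to ``path`` (format by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    usable = [s for s in summaries if s.reliable]
    x = np.array([s.median[x_metric] for s in usable])
    y = np.array([s.median[y_metric] for s in usable])
    xerr = np.array([
        [s.median[x_metric] - s.lower[x_metric] for s in usable],
        [s.upper[x_metric] - s.median[x_metric] for s in usable],
    ])
    yerr = np.array([
        [s.median[y_metric] - s.lower[y_metric] for s in usable],
        [s.upper[y_metric] - s.median[y_metric] for s in usable],
    ])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(x, y, xerr=xerr, yerr=yerr, fmt="o", ms=4, lw=0.8, alpha=0.8)
    for s, xi, yi in zip(usable, x, y):
        ax.annotate(s.species, (xi, yi), fontsize=6,
                    textcoords="offset points", xytext=(3, 3))
    if len(x) >= 4:
        fit = fit_plateau(x, y)
        if fit.converged:
            grid = np.linspace(x.min(), x.max(), 200)
            ax.plot(grid, plateau_curve(grid, fit.y0, fit.ymax, fit.k_rate),
                    "-", color="crimson", lw=1.2,
                    label=f"plateau fit (k={fit.k_rate:.2f})")
            ax.legend(frameon=False, fontsize=8)
    scen = usable[0].scenario if usable else "?"
    ax.set_xlabel("component feedback strength (1 - S_red)")
    ax.set_ylabel("ensemble feedback strength (-Gompertz beta)")
    ax.set_title(f"scenario {scen}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
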