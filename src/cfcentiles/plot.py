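"""Basic chart plotting: selected percentile curves with an optional
shaded median confidence band."""

from __future__ import annotations

import numpy as np

from .charts import PercentileChart
from .inference import BootstrapBand

DEFAULT_PLOT_TAUS = (0.05, 0.25, 0.50, 0.75, 0.95)


def plot_chart(
    chart: PercentileChart,
    band: BootstrapBand | None = None,
    taus=DEFAULT_PLOT_TAUS,
    n_grid: int = 200,
    ax=None,
):
    """Plot percentile curves against the first covariate; returns the axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    cov = chart.covariates[0]
    lo, hi = chart.training_range(cov)
    grid = np.linspace(lo, hi, n_grid)
    sel = np.isin(np.round(chart.taus, 10), np.round(taus, 10))
    values = chart.curve_values({cov: grid})[sel]
    for tau, curve in zip(chart.taus[sel], values):
        style = "-" if np.isclose(tau, 0.5) else "--"
        ax.plot(grid, curve, style, lw=2 if np.isclose(tau, 0.5) else 1,
                label=f"{int(round(tau * 100))}th")
    if band is not None:
        ax.fill_between(band.grid, band.lower, band.upper, alpha=0.3,
                        color="grey", label=f"{int(band.level * 100)}% CI (median)")
    ax.set_xlabel(f"{cov} ({'years' if cov == 'age' else 'cm'})")
    ax.set_ylabel("FEV1 (L)" if chart.outcome == "fev1" else "BMI (kg/m²)")
    ax.set_title(f"{chart.outcome.upper()} percentiles, sex {chart.sex}")
    ax.legend(fontsize=8)
    return ax
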