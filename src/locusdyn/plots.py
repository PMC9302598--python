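"""Diagnostic plots: MSD curves, D_app histograms with fitted peaks, fraction bars."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .mixture import COMPONENT_ORDER, DappDistribution, MixtureFit, _gauss
from .msd import DiffusionFit, MSDCurve

__all__ = ["plot_msd", "plot_dapp_histogram", "plot_fraction_bars"]

_COMPONENT_COLORS = {"fast": "#d45087", "slow": "#2f4b7c", "fixed": "#333333"}


def plot_msd(curve: MSDCurve, fit: DiffusionFit | None = None, ax=None, label=None):
    """Log-log ensemble MSD with the fitted 4Dt^α power law overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.loglog(curve.lags, curve.msd, ".", ms=3, label=label)
    if fit is not None:
        t = np.linspace(curve.lags[0], curve.lags[-1], 200)
        ax.loglog(
            t, 4 * fit.D * t**fit.alpha, "-",
            label=rf"$4Dt^\alpha$: D={fit.D:.2e}, $\alpha$={fit.alpha:.2f}",
        )
    ax.set_xlabel("lag time (s)")
    ax.set_ylabel(r"MSD ($\mu m^2$)")
    ax.legend(fontsize=8)
    return ax


def plot_dapp_histogram(dist: DappDistribution, fit: MixtureFit | None = None, ax=None):
    """log10(D_app) histogram with the fitted Gaussian components."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    widths = np.diff(dist.bin_edges)
    ax.bar(dist.bin_centers, dist.density, width=widths, color="#cccccc", edgecolor="white")
    if fit is not None and fit.components:
        x = np.linspace(dist.bin_edges[0], dist.bin_edges[-1], 400)
        total = np.zeros_like(x)
        for c in fit.components:
            y = c.weight * _gauss(x, c.mean, c.sd)
            total += y
            ax.plot(x, y, color=_COMPONENT_COLORS.get(c.label, "k"), label=c.label)
        ax.plot(x, total, color="green", lw=1.5, label="sum")
        ax.legend(fontsize=8)
    ax.set_xlabel(r"$\log_{10} D_{app}$ ($\mu m^2/s$)")
    ax.set_ylabel("density")
    return ax


def plot_fraction_bars(table, ax=None):
    """Stacked per-condition component percentages (long-format table in)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 3.5))
    pivot = table.pivot(index="condition", columns="component", values="percent")
    pivot = pivot.reindex(columns=[c for c in COMPONENT_ORDER if c in pivot.columns])
    bottom = np.zeros(len(pivot))
    for comp in pivot.columns:
        vals = pivot[comp].to_numpy()
        ax.bar(pivot.index, vals, bottom=bottom, label=comp,
               color=_COMPONENT_COLORS.get(comp, "gray"))
        bottom += vals
    ax.set_ylabel("percent of trajectories")
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=30)
    return ax
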