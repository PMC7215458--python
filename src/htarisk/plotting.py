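"""Static charts: F-N band with ALARP zones, slope histogram fits, and the
elbow curve.  All functions take an output path and write an image file."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .alarp import CriterionLine, default_lines
from .fitting import FNBand, SlopeDistributionFit, improved_normal_density, normal_density
from .fncurve import FNSeries

__all__ = ["plot_fn_band", "plot_slope_histogram", "plot_elbow"]


def plot_fn_band(
    band: FNBand,
    series: FNSeries | None = None,
    lines: tuple[CriterionLine, CriterionLine] | None = None,
    path=None,
    n_max: float | None = None,
):
    """Log-log F-N plot: data points, central line, 95% envelope and the
    shaded ALARP zones."""
    tolerable, acceptable = lines or default_lines()
    upper = n_max or (float(series.n_deaths.max()) if series is not None else 100.0)
    N = np.geomspace(1, upper, 200)
    vals = band.evaluate(N)
    fig, ax = plt.subplots(figsize=(6, 5))
    tol, acc = tolerable.evaluate(N), acceptable.evaluate(N)
    top = max(2.0, float(np.max(vals["upper"])) * 2)
    ax.fill_between(N, tol, top, color="#f4cccc", alpha=0.6, label="unacceptable")
    ax.fill_between(N, acc, tol, color="#fff2cc", alpha=0.6, label="tolerable if ALARP")
    ax.fill_between(N, 1e-7, acc, color="#d9ead3", alpha=0.6, label="broadly acceptable")
    ax.plot(N, tol, "k--", lw=1)
    ax.plot(N, acc, "k:", lw=1)
    ax.plot(N, vals["central"], "k-", lw=1.5, label="central F-N curve")
    ax.plot(N, vals["lower"], "b-", lw=0.8, label="95% envelope")
    ax.plot(N, vals["upper"], "b-", lw=0.8)
    if series is not None:
        ax.plot(series.n_deaths, series.F, "ro", ms=4, label="observed")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("number of deaths N")
    ax.set_ylabel("cumulative frequency F")
    ax.set_ylim(1e-7, top)
    ax.legend(fontsize=7, loc="lower left")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_slope_histogram(slopes, fits: list[SlopeDistributionFit], bins, path=None):
    """Slope histogram with fitted densities overlaid."""
    arr = np.asarray(slopes, float)
    arr = arr[~np.isnan(arr)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(arr, bins=bins, density=True, color="#9fc5e8", edgecolor="white")
    x = np.linspace(arr.min() - 0.1, arr.max() + 0.1, 300)
    for fit in fits:
        if fit.family == "normal":
            ax.plot(x, normal_density(x, fit.mu, fit.sigma), label=f"normal (R²={fit.r2:.3f})")
        else:
            ax.plot(x, improved_normal_density(x, fit.B, fit.D, fit.mu, fit.sigma), label=f"improved normal (R²={fit.r2:.3f})")
    ax.set_xlabel("per-point slope −a")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_elbow(sse_table: pd.DataFrame, path=None):
    """SSE vs k with elbow candidates highlighted."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(sse_table["k"], sse_table["sse"], "o-")
    cand = sse_table[sse_table["elbow_candidate"]]
    ax.plot(cand["k"], cand["sse"], "rs", ms=9, mfc="none", label="elbow candidates")
    ax.set_xlabel("k")
    ax.set_ylabel("within-cluster SSE")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
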