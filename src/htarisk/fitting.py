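"""Slope-uncertainty and power-law fits for F-N series.

A deterministic F-N curve F = C*N^(-a) summarises societal risk with a
single steepness a, but empirical per-point slopes scatter around any such
line.  The enhanced approach treats the slope as an uncertain quantity and
fits three competing descriptions:

* a normal law for the per-point slopes (mean mu, sd sigma, population
  dispersion interval mu +/- 1.96 sigma),
* an "improved" normal density with a baseline offset B and amplitude D,
  f(x) = B + D/(sigma*sqrt(pi/2)) * exp(-2 (x-mu)^2 / sigma^2), fitted to
  the slope histogram by least squares,
* a direct power law for the curve itself, fitted either by OLS in log-log
  space or by nonlinear least squares in linear F space.

Goodness of fit (R^2 and dof-adjusted RMSE) ranks the candidates; the
winning fit's 95% intervals on (a, C) define a confidence band around the
central F-N line, which downstream ALARP zoning evaluates edge by edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .fncurve import FNSeries, group_fatalities, cumulative_frequency

__all__ = [
    "SlopeDistributionFit",
    "PowerLawFit",
    "FNBand",
    "goodness_of_fit",
    "goodness_of_fit_histogram",
    "normal_density",
    "improved_normal_density",
    "fit_normal",
    "fit_improved_normal",
    "fit_improved_normal_density",
    "fit_powerlaw_loglog",
    "fit_powerlaw_linear",
    "bootstrap_slope_interval",
    "select_model",
    "fn_band",
    "fatality_ratio",
]


def goodness_of_fit(observed: Sequence[float], predicted: Sequence[float], n_params: int = 2) -> tuple[float, float]:
    """R^2 and degree-of-freedom adjusted RMSE of a fit.

    R^2 = 1 - SSE/SST; RMSE = sqrt(SSE / (n - n_params)).
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    if len(o) <= n_params:
        raise ValueError("need more observations than parameters")
    sse = float(np.sum((o - p) ** 2))
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values have zero variance")
    return 1.0 - sse / sst, math.sqrt(sse / (len(o) - n_params))


def normal_density(x, mu: float, sigma: float):
    return np.exp(-((np.asarray(x, float) - mu) ** 2) / (2 * sigma**2)) / (sigma * math.sqrt(2 * math.pi))


def improved_normal_density(x, B: float, D: float, mu: float, sigma: float):
    """Offset normal-shaped density: B + D/(sigma*sqrt(pi/2)) * exp(-2(x-mu)^2/sigma^2)."""
    x = np.asarray(x, float)
    return B + D / (sigma * math.sqrt(math.pi / 2)) * np.exp(-2 * (x - mu) ** 2 / sigma**2)


def _histogram(slopes: np.ndarray, bins) -> tuple[np.ndarray, np.ndarray]:
    density, edges = np.histogram(slopes, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def goodness_of_fit_histogram(
    slopes: Sequence[float], density: Callable[[np.ndarray], np.ndarray], bins, n_params: int = 2
) -> tuple[float, float]:
    """R^2/RMSE of a fitted density against the slope histogram densities.

    ``bins`` follows :func:`numpy.histogram` (an int, edges, or a rule name
    such as ``"sturges"``) and must be given explicitly by callers that
    need reproducible metrics — histogram-space goodness of fit depends on
    the binning.
    """
    arr = np.asarray(slopes, dtype=float)
    if len(arr) < 4:
        raise ValueError("need at least 4 slopes for a histogram fit")
    centers, observed = _histogram(arr, bins)
    if len(centers) <= n_params:
        raise ValueError("too few histogram bins for the parameter count")
    return goodness_of_fit(observed, density(centers), n_params=n_params)


@dataclass(frozen=True)
class SlopeDistributionFit:
    """Fitted distribution of per-point F-N slopes.

    ``interval_95`` is mu +/- 1.96 sigma: the central 95% range of the
    slope *population*, not a standard-error interval on mu.  It is the
    interval that propagates into fatality-ratio bounds and band edges.
    """

    family: str  # "normal" | "improved_normal"
    mu: float
    sigma: float
    r2: float
    rmse: float
    n_slopes: int
    B: float | None = None
    D: float | None = None

    @property
    def interval_95(self) -> tuple[float, float]:
        return (self.mu - 1.96 * self.sigma, self.mu + 1.96 * self.sigma)

    def to_dict(self) -> dict:
        lo, hi = self.interval_95
        d = {
            "family": self.family,
            "mu": self.mu,
            "sigma": self.sigma,
            "interval_95": [lo, hi],
            "r2": self.r2,
            "rmse": self.rmse,
            "n_slopes": self.n_slopes,
        }
        if self.family == "improved_normal":
            d["B"], d["D"] = self.B, self.D
        return d


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted F = C*N^(-a) with 95% intervals on a and C.

    ``fit_space`` records whether the fit minimised squared error on
    (lgN, lgF) pairs (``loglog_ols``) or on F itself (``linear_nls``);
    metrics live in the corresponding space.
    """

    a_hat: float
    C_hat: float
    a_interval_95: tuple[float, float]
    C_interval_95: tuple[float, float]
    r2: float
    rmse: float
    fit_space: str
    n_points: int

    def __post_init__(self) -> None:
        if self.C_hat <= 0:
            raise ValueError("C must be positive")
        if not self.a_interval_95[0] <= self.a_hat <= self.a_interval_95[1]:
            raise ValueError("a interval must contain the estimate")

    def predict(self, N) -> np.ndarray:
        return self.C_hat * np.asarray(N, float) ** (-self.a_hat)

    def to_dict(self) -> dict:
        return {
            "family": "power_law",
            "a": self.a_hat,
            "C": self.C_hat,
            "a_interval_95": list(self.a_interval_95),
            "C_interval_95": list(self.C_interval_95),
            "r2": self.r2,
            "rmse": self.rmse,
            "fit_space": self.fit_space,
            "n_points": self.n_points,
        }


def fit_normal(slopes: Sequence[float], bins="sturges") -> SlopeDistributionFit:
    """Normal fit of the per-point slopes.

    mu is the arithmetic mean and sigma the sample (n-1) standard
    deviation; R^2/RMSE compare the implied density with the slope
    histogram under ``bins``.
    """
    arr = np.asarray(slopes, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        raise ValueError("need at least 2 defined slopes")
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=1))
    if sigma == 0.0 or len(arr) < 4:
        r2, rmse = (1.0, 0.0) if sigma == 0.0 else (float("nan"), float("nan"))
    else:
        r2, rmse = goodness_of_fit_histogram(arr, lambda x: normal_density(x, mu, sigma), bins, n_params=2)
    return SlopeDistributionFit("normal", mu, sigma, r2, rmse, len(arr))


def fit_improved_normal_density(centers: Sequence[float], density: Sequence[float], p0=None) -> tuple[float, float, float, float]:
    """Least-squares (B, D, mu, sigma) of the offset normal density to
    given (center, density) pairs.  Exposed separately so densities from a
    known parameter quadruple can be refitted exactly."""
    centers = np.asarray(centers, float)
    density = np.asarray(density, float)
    if p0 is None:
        mu0 = float(centers[np.argmax(density)])
        p0 = [0.0, 0.5, mu0, float(centers.std() or 0.1)]
    popt, _ = optimize.curve_fit(improved_normal_density, centers, density, p0=p0, maxfev=20000)
    B, D, mu, sigma = (float(v) for v in popt)
    return B, D, mu, abs(sigma)


def fit_improved_normal(slopes: Sequence[float], bins="sturges") -> SlopeDistributionFit:
    """Least-squares fit of the offset normal density to the slope histogram.

    All four parameters (B, D, mu, sigma) are free; mu and sigma are the
    histogram-fitted location and scale, which generally differ from the
    sample moments.  Non-convergence raises with the optimiser diagnostics.
    """
    arr = np.asarray(slopes, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 4:
        raise ValueError("need at least 4 defined slopes")
    centers, density = _histogram(arr, bins)
    if len(centers) < 4:
        raise ValueError("binning yields fewer bins than parameters; use more bins")
    p0 = [0.0, 0.5, float(arr.mean()), float(arr.std(ddof=1)) or 0.1]
    try:
        B, D, mu, sigma = fit_improved_normal_density(centers, density, p0=p0)
    except RuntimeError as exc:  # pragma: no cover - optimiser failure path
        raise RuntimeError(f"improved-normal histogram fit did not converge: {exc}") from exc
    r2, rmse = goodness_of_fit(density, improved_normal_density(centers, B, D, mu, sigma), n_params=4) \
        if len(centers) > 4 else (1.0 - _sse(density, improved_normal_density(centers, B, D, mu, sigma)) / _sst(density), float("nan"))
    return SlopeDistributionFit("improved_normal", mu, sigma, r2, rmse, len(arr), B=B, D=D)


def _sse(o, p):
    return float(np.sum((np.asarray(o) - np.asarray(p)) ** 2))


def _sst(o):
    o = np.asarray(o)
    return float(np.sum((o - o.mean()) ** 2))


def fit_powerlaw_loglog(series: FNSeries) -> PowerLawFit:
    """OLS of lgF on lgN over all series points (the N=1 origin included).

    Intervals are textbook t-based regression CIs with n-2 dof.  Note that
    empirical cumulative frequencies are autocorrelated along N, so these
    iid-error intervals are anti-conservative for raw accident data; use
    :func:`bootstrap_slope_interval` when calibrated coverage matters.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 points")
    x, y = series.lgN, series.lgF
    if np.allclose(x, x[0]):
        raise ValueError("degenerate series: all lgN equal")
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    r2, rmse = goodness_of_fit(y, intercept + slope * x, n_params=2)
    s2 = float(np.sum(resid**2)) / (n - 2)
    t = stats.t.ppf(0.975, n - 2)
    se_slope = math.sqrt(s2 / sxx)
    se_inter = math.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))
    a = -slope
    return PowerLawFit(
        a_hat=a,
        C_hat=10.0**intercept,
        a_interval_95=(a - t * se_slope, a + t * se_slope),
        C_interval_95=(10.0 ** (intercept - t * se_inter), 10.0 ** (intercept + t * se_inter)),
        r2=r2,
        rmse=rmse,
        fit_space="loglog_ols",
        n_points=n,
    )


def fit_powerlaw_linear(series: FNSeries) -> PowerLawFit:
    """Unweighted nonlinear least squares of F = C*N^(-a) in linear F space.

    Initialised from the log-log OLS fit; 95% intervals come from the
    Jacobian linearisation with a t(n-2) quantile, R^2/RMSE are computed
    on F with the RMSE denominator n-2.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 points")
    start = fit_powerlaw_loglog(series)
    N = series.n_deaths.astype(float)
    F = series.F

    def model(n, C, a):
        return C * n ** (-a)

    try:
        popt, pcov = optimize.curve_fit(model, N, F, p0=[start.C_hat, start.a_hat], maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover
        raise RuntimeError(f"power-law fit did not converge: {exc}") from exc
    C_hat, a_hat = (float(v) for v in popt)
    pred = model(N, C_hat, a_hat)
    r2, rmse = goodness_of_fit(F, pred, n_params=2)
    t = stats.t.ppf(0.975, len(N) - 2)
    se = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(se)):  # exact fits have singular covariance
        se = np.zeros(2)
    return PowerLawFit(
        a_hat=a_hat,
        C_hat=C_hat,
        a_interval_95=(a_hat - t * float(se[1]), a_hat + t * float(se[1])),
        C_interval_95=(C_hat - t * float(se[0]), C_hat + t * float(se[0])),
        r2=r2,
        rmse=rmse,
        fit_space="linear_nls",
        n_points=len(N),
    )


def _tail_slope(deaths: np.ndarray) -> float | None:
    """Log-log OLS slope of the empirical F-N relation of raw death counts."""
    values, counts = np.unique(deaths, return_counts=True)
    if len(values) < 3:
        return None
    F = np.cumsum(counts[::-1])[::-1] / counts.sum()
    x, y = np.log10(values.astype(float)), np.log10(F)
    dx = x - x.mean()
    return float(dx @ (y - y.mean()) / (dx @ dx))


def bootstrap_slope_interval(
    deaths: Sequence[int], n_boot: int = 999, seed: int | None = None, level: float = 0.95
) -> tuple[float, float]:
    """Bootstrap percentile interval for the F-N slope magnitude a.

    Resamples whole accidents (death counts) with replacement, regroups,
    and refits the log-log OLS slope per resample.  Unlike the iid-error
    OLS interval — which ignores the autocorrelation of cumulative
    frequencies and badly undercovers — the percentile interval reflects
    the true sampling variability of the slope.
    """
    arr = np.asarray(list(deaths), dtype=int)
    if np.any(arr < 1):
        raise ValueError("death counts must be >= 1")
    rng = np.random.default_rng(seed)
    estimates = []
    while len(estimates) < n_boot:
        s = _tail_slope(rng.choice(arr, size=len(arr), replace=True))
        if s is not None:
            estimates.append(-s)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def select_model(fits: Sequence) -> list:
    """Rank fits by descending R^2, ties broken by ascending RMSE.

    The ranking is stable in the input order; the first element is the
    selected model.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to rank")
    return sorted(fits, key=lambda f: (-f.r2, f.rmse))


@dataclass(frozen=True)
class FNBand:
    """Central F-N line with a nesting 95% envelope, each line (a, C).

    The lower edge pairs the steepest slope with the smallest C and the
    upper edge the shallowest slope with the largest C, so for N >= 1 the
    band brackets the central line everywhere.
    """

    central: tuple[float, float]
    lower: tuple[float, float]
    upper: tuple[float, float]
    source: str

    def evaluate(self, N) -> dict[str, np.ndarray]:
        N = np.asarray(N, dtype=float)
        out = {}
        for name, (a, C) in (("lower", self.lower), ("central", self.central), ("upper", self.upper)):
            out[name] = C * N ** (-a)
        return out

    def to_dict(self) -> dict:
        return {
            "central": {"a": self.central[0], "C": self.central[1]},
            "lower": {"a": self.lower[0], "C": self.lower[1]},
            "upper": {"a": self.upper[0], "C": self.upper[1]},
            "source": self.source,
        }


def fn_band(fit: SlopeDistributionFit | PowerLawFit, series: FNSeries | None = None) -> FNBand:
    """Build the 95% F-N band implied by a fit's intervals.

    For a power-law fit the band uses the (a, C) intervals directly.  For
    a slope-distribution fit, the slope interval is mu +/- 1.96 sigma and
    C is pinned to the series' F at its smallest group (1 for a complete
    fatal-accident sample), since those fits describe steepness only.
    """
    if isinstance(fit, PowerLawFit):
        a_lo, a_hi = fit.a_interval_95
        C_lo, C_hi = max(fit.C_interval_95[0], 1e-300), fit.C_interval_95[1]
        return FNBand(
            central=(fit.a_hat, fit.C_hat),
            lower=(a_hi, C_lo),
            upper=(a_lo, C_hi),
            source=f"power_law/{fit.fit_space}",
        )
    C = float(series.F[0]) if series is not None else 1.0
    lo, hi = fit.interval_95  # slopes are negative: lo is steepest
    return FNBand(central=(-fit.mu, C), lower=(-lo, C), upper=(-hi, C), source=fit.family)


def fatality_ratio(slope_magnitude: float, n1: int, n2: int) -> float:
    """Ratio F(>=n1)/F(>=n2) on a power-law curve: (n2/n1)^a.

    With the slope-population interval endpoints 1.1631 and 1.5217 from
    the China series, the ratio of 10-or-more to 100-or-more fatality
    frequencies ranges over roughly 14.6-33.2.
    """
    if not (n2 > n1 >= 1):
        raise ValueError("need n2 > n1 >= 1")
    if slope_magnitude <= 0:
        raise ValueError("slope magnitude must be positive")
    return (n2 / n1) ** slope_magnitude
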