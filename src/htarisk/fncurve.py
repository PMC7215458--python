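"""F-N series construction: fatality groups, cumulative frequencies, log
pairs and per-point slopes.

The F-N curve relates the number of fatalities N to the cumulative
frequency F of accidents with N or more deaths.  Within a sample of fatal
accidents grouped by exact death count, F at group j is the tail sum of
group counts divided by the total, so F = 1 at the smallest death count and
decreases along the tail.  On log-log axes each point (lgN, lgF) with
lgN > 0 defines a per-point slope lgF/lgN — the local steepness used as the
uncertain quantity in the slope-distribution fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FatalityGroup",
    "FNSeries",
    "group_fatalities",
    "cumulative_frequency",
    "pointwise_slopes",
    "series_from_table",
    "read_fn_table",
]


@dataclass(frozen=True)
class FatalityGroup:
    """Accidents with exactly ``n_deaths`` fatalities."""

    n_deaths: int
    n_accidents: int

    def __post_init__(self) -> None:
        if self.n_deaths < 1:
            raise ValueError("n_deaths must be >= 1 (F-N curves concern fatal accidents)")
        if self.n_accidents < 1:
            raise ValueError("n_accidents must be >= 1")


@dataclass
class FNSeries:
    """An F-N series over strictly increasing death counts.

    ``F`` is the cumulative relative frequency of N-or-more deaths; the
    per-point ``slopes`` are lgF/lgN, NaN at the N = 1 group where lgN = 0.
    ``F`` may be supplied explicitly (e.g. a published table whose printed
    frequencies are not exactly the count ratios); otherwise it is computed
    from the counts at full precision.  Likewise ``lgN``/``lgF``/``slopes``
    default to full-precision derivations but can be overridden with a
    published table's own printed columns, which carry independent rounding.
    """

    n_deaths: np.ndarray
    n_accidents: np.ndarray
    F: np.ndarray
    lgN: np.ndarray | None = None
    lgF: np.ndarray | None = None
    slopes: np.ndarray | None = None
    total_accidents: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_deaths = np.asarray(self.n_deaths, dtype=int)
        self.n_accidents = np.asarray(self.n_accidents, dtype=int)
        self.F = np.asarray(self.F, dtype=float)
        if not (len(self.n_deaths) == len(self.n_accidents) == len(self.F)):
            raise ValueError("n_deaths, n_accidents and F must have equal length")
        if len(self.n_deaths) == 0:
            raise ValueError("series must contain at least one group")
        if np.any(np.diff(self.n_deaths) <= 0):
            raise ValueError("n_deaths must be strictly increasing")
        if np.any(self.F <= 0) or np.any(np.diff(self.F) > 0):
            raise ValueError("F must be positive and non-increasing")
        self.total_accidents = int(self.n_accidents.sum())
        self.lgN = np.log10(self.n_deaths.astype(float)) if self.lgN is None else np.asarray(self.lgN, float)
        self.lgF = np.log10(self.F) if self.lgF is None else np.asarray(self.lgF, float)
        if self.slopes is None:
            self.slopes = pointwise_slopes(self.lgN, self.lgF)
        else:
            self.slopes = np.asarray(self.slopes, dtype=float)

    def __len__(self) -> int:
        return len(self.n_deaths)

    def defined_slopes(self) -> np.ndarray:
        """Per-point slopes excluding the undefined N = 1 entry."""
        return self.slopes[~np.isnan(self.slopes)]

    def to_frame(self, round_digits: int | None = None) -> pd.DataFrame:
        """Tabular report; pass ``round_digits=3`` for published-table style."""
        out = pd.DataFrame(
            {
                "n_deaths": self.n_deaths,
                "n_accidents": self.n_accidents,
                "F": self.F,
                "lg_n": self.lgN,
                "lg_f": self.lgF,
                "slope": self.slopes,
            }
        )
        if round_digits is not None:
            for c in ("F", "lg_n", "lg_f", "slope"):
                out[c] = out[c].round(round_digits)
        return out


def group_fatalities(deaths: Iterable[int]) -> list[FatalityGroup]:
    """Group fatal accidents by exact death count, sorted ascending."""
    arr = np.asarray(list(deaths), dtype=int)
    if arr.size == 0:
        raise ValueError("no fatal accidents to group")
    if np.any(arr < 1):
        raise ValueError("all death counts must be >= 1; filter non-fatal accidents first")
    values, counts = np.unique(arr, return_counts=True)
    return [FatalityGroup(int(n), int(c)) for n, c in zip(values, counts)]


def cumulative_frequency(groups: Sequence[FatalityGroup]) -> FNSeries:
    """Build the F-N series from fatality groups.

    F at group j is the tail count sum over groups j..n divided by the
    total number of accidents, so the first (smallest-N) group has F = 1.
    """
    ordered = sorted(groups, key=lambda g: g.n_deaths)
    n = np.array([g.n_deaths for g in ordered], dtype=int)
    c = np.array([g.n_accidents for g in ordered], dtype=int)
    tail = np.cumsum(c[::-1])[::-1]
    return FNSeries(n, c, tail / c.sum())


def pointwise_slopes(lgN: Sequence[float], lgF: Sequence[float]) -> np.ndarray:
    """Per-point slope lgF/lgN; NaN where lgN = 0 (the N = 1 group)."""
    x = np.asarray(lgN, dtype=float)
    y = np.asarray(lgF, dtype=float)
    if x.shape != y.shape:
        raise ValueError("lgN and lgF must have equal length")
    if np.any(x < 0):
        raise ValueError("lgN must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(x > 0, y / x, np.nan)


def series_from_table(rows: Iterable[tuple[int, int]]) -> FNSeries:
    """Build an F-N series from pre-grouped (n_deaths, n_accidents) rows.

    Row order is irrelevant; duplicate death counts are rejected.
    """
    pairs = list(rows)
    seen = [n for n, _ in pairs]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate n_deaths in table")
    return cumulative_frequency([FatalityGroup(int(n), int(c)) for n, c in pairs])


def read_fn_table(path, use_printed_frequencies: bool = True) -> FNSeries:
    """Read a two-or-more-column delimited fatality-group table.

    Requires ``n_deaths`` and ``n_accidents`` columns.  If an ``F`` column
    is present and ``use_printed_frequencies`` is true, those frequencies
    are used verbatim (published tables sometimes print rounded or
    renormalised F that do not exactly equal the count ratios); otherwise
    F is recomputed from the counts.
    """
    frame = pd.read_csv(path).sort_values("n_deaths")
    if use_printed_frequencies and "F" in frame.columns:
        extra = {
            dst: frame[src].to_numpy(dtype=float)
            for src, dst in (("lg_n", "lgN"), ("lg_f", "lgF"), ("slope", "slopes"))
            if src in frame.columns
        }
        return FNSeries(frame["n_deaths"].to_numpy(), frame["n_accidents"].to_numpy(), frame["F"].to_numpy(), **extra)
    return series_from_table(zip(frame["n_deaths"], frame["n_accidents"]))
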