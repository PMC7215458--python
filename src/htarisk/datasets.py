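"""Packaged reference tables from the 371-accident China survey (2004-2018).

Three small fixtures ship with the package: the 19-row fatality-group F-N
series (printed cumulative frequencies, log pairs and per-point slopes),
the 4x4 severity confusion matrix of the published cause-consequence tree,
and the categorical marginals of the 569 expanded accident cases.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fncurve import FNSeries

__all__ = ["fn_table_china", "fn_series_china", "slopes_china", "confusion_counts_china", "case_marginals"]


def _data(name: str) -> pd.DataFrame:
    with resources.files("htarisk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def fn_table_china() -> pd.DataFrame:
    """The China fatality-group table with its printed derived columns
    (F, lg_n, lg_f, slope)."""
    return _data("fn_china_2004_2018.csv")


def fn_series_china(use_printed_frequencies: bool = True) -> FNSeries:
    """The China F-N series.

    By default the printed cumulative frequencies are used verbatim; they
    are slightly renormalised relative to the raw count ratios (the group
    counts sum to 370 while e.g. F at N = 2 prints as 0.480, not
    177/370 = 0.478), and the published fits are anchored to the printed
    values.  Pass ``use_printed_frequencies=False`` to recompute F from
    the counts.
    """
    t = fn_table_china()
    if use_printed_frequencies:
        return FNSeries(
            t["n_deaths"].to_numpy(),
            t["n_accidents"].to_numpy(),
            t["F"].to_numpy(),
            lgN=t["lg_n"].to_numpy(dtype=float),
            lgF=t["lg_f"].to_numpy(dtype=float),
            slopes=t["slope"].to_numpy(dtype=float),
        )
    from .fncurve import series_from_table

    return series_from_table(zip(t["n_deaths"], t["n_accidents"]))


def slopes_china() -> pd.Series:
    """The 18 printed per-point slopes of the China series (the N = 1 row
    has no slope).  The published slope-distribution parameters are the
    moments of exactly these 3-decimal values, which differ in the fourth
    decimal from slopes recomputed off the printed log columns."""
    return fn_table_china()["slope"].dropna().reset_index(drop=True)


def confusion_counts_china() -> pd.DataFrame:
    """Severity confusion matrix (actual rows x predicted columns) of the
    published cause-consequence tree over the 569 cases."""
    return _data("confusion_china.csv").set_index("actual")


def case_marginals() -> pd.DataFrame:
    """Categorical marginals of the 569 expanded cases (variable, code,
    label, count)."""
    return _data("case_marginals_china.csv")
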