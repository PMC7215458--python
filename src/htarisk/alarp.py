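"""ALARP criterion lines and risk-zone classification of F-N curves.

Two power-law limit lines F = C*N^(-a) partition the F-N plane: above the
tolerable line the societal risk is unacceptable, below the acceptable
line it is broadly acceptable, and in between it is tolerable only if
reduced as low as reasonably practicable (ALARP).  With a neutral risk
attitude both lines have slope a = 1; the defaults put the tolerable
intercept at 0.1 and the acceptable intercept two decades lower at 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fitting import FNBand

__all__ = [
    "CriterionLine",
    "RiskAssessment",
    "default_lines",
    "classify_zone",
    "assess_curve",
    "crossing_fatalities",
    "ZONES",
]

#: Zone labels ordered from worst to best.
ZONES = ("unacceptable", "tolerable_if_alarp", "broadly_acceptable")


@dataclass(frozen=True)
class CriterionLine:
    """A limit line F = C*N^(-a); C is the frequency intercept at N = 1."""

    a: float = 1.0
    C: float = 0.1
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.C <= 0:
            raise ValueError("criterion line requires a > 0 and C > 0")

    def evaluate(self, N) -> np.ndarray:
        return self.C * np.asarray(N, dtype=float) ** (-self.a)


def default_lines() -> tuple[CriterionLine, CriterionLine]:
    """The neutral-attitude limit lines: tolerable (a=1, C=0.1) and
    acceptable (a=1, C=0.001, i.e. 1% of the tolerable intercept)."""
    return CriterionLine(1.0, 0.1, "tolerable"), CriterionLine(1.0, 0.001, "acceptable")


def classify_zone(F: float, N: float, lines: tuple[CriterionLine, CriterionLine] | None = None) -> str:
    """Zone of a single (N, F) point.

    Points exactly on a limit line belong to the less severe zone (limit
    lines are "up to and including").
    """
    if F <= 0 or N < 1:
        raise ValueError("need F > 0 and N >= 1")
    tolerable, acceptable = lines or default_lines()
    if F > tolerable.evaluate(N):
        return "unacceptable"
    if F > acceptable.evaluate(N):
        return "tolerable_if_alarp"
    return "broadly_acceptable"


@dataclass
class RiskAssessment:
    """Per-N zone verdicts for a band's central, lower and upper edges.

    The lower (optimistic) edge is the shallow/low-frequency reading of
    the uncertainty band, the upper (pessimistic) edge the severe one.
    ``verdict`` is the worst zone the central line attains over the
    evaluated N range.
    """

    N: np.ndarray
    zones: dict[str, list[str]]
    verdict: str
    crossings: dict[str, dict[str, float | None]]
    extrapolated: bool = False

    def to_dict(self) -> dict:
        return {
            "N": [float(n) for n in self.N],
            "zones": self.zones,
            "verdict": self.verdict,
            "crossings": {
                edge: {line: (None if v is None else float(v)) for line, v in d.items()}
                for edge, d in self.crossings.items()
            },
            "extrapolated": self.extrapolated,
        }


def crossing_fatalities(curve: tuple[float, float], line: CriterionLine) -> float | None:
    """Fatality count N* where a power-law curve crosses a limit line.

    For curve (a_c, C_c) and line (a_l, C_l) with a_c != a_l the unique
    positive crossing is N* = (C_c/C_l)^(1/(a_c - a_l)); returns None when
    the crossing falls below N = 1 or the lines are parallel and distinct.
    A curve identical to the line is degenerate (crosses everywhere).
    """
    a_c, C_c = curve
    if a_c == line.a:
        if C_c == line.C:
            raise ValueError("curve coincides with the line: crossing everywhere")
        return None
    lg_n_star = (np.log10(C_c) - np.log10(line.C)) / (a_c - line.a)
    if lg_n_star < 0:
        return None
    if lg_n_star > 300:  # near-parallel lines: crossing beyond float range
        return float("inf")
    return float(10.0**lg_n_star)


def assess_curve(
    band: FNBand,
    lines: tuple[CriterionLine, CriterionLine] | None = None,
    N_range: Sequence[float] | None = None,
    max_observed_N: float | None = None,
    allow_extrapolation: bool = False,
) -> RiskAssessment:
    """Classify an F-N band against the ALARP limit lines.

    ``N_range`` defaults to 1..max_observed_N (the data support); asking
    for N beyond the observed maximum is refused unless
    ``allow_extrapolation`` is set, since verdicts out there rest on the
    fitted tail, not on data.
    """
    lines = lines or default_lines()
    if N_range is None:
        upper = max_observed_N if max_observed_N is not None else 100.0
        N = np.unique(np.round(np.geomspace(1, upper, 25)))
    else:
        N = np.asarray(sorted(N_range), dtype=float)
    extrapolated = bool(max_observed_N is not None and N.max() > max_observed_N)
    if extrapolated and not allow_extrapolation:
        raise ValueError(
            f"N range extends to {N.max():g} beyond the observed maximum {max_observed_N:g}; "
            "pass allow_extrapolation=True for fitted-tail verdicts"
        )
    values = band.evaluate(N)
    zones = {edge: [classify_zone(f, n, lines) for f, n in zip(values[edge], N)] for edge in values}
    central = zones["central"]
    verdict = next(z for z in ZONES if z in central)
    crossings = {}
    for edge, params in (("lower", band.lower), ("central", band.central), ("upper", band.upper)):
        crossings[edge] = {}
        for line in lines:
            try:
                crossings[edge][line.label] = crossing_fatalities(params, line)
            except ValueError:
                crossings[edge][line.label] = float("nan")
    return RiskAssessment(N=N, zones=zones, verdict=verdict, crossings=crossings, extrapolated=extrapolated)
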