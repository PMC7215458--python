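"""CHAID cause-consequence decision tree.

Chi-squared automatic interaction detection builds a classification tree
for a categorical target (here the accident severity level) by, at each
node: (1) merging, per predictor, the pair of categories whose target
distributions are least distinguishable (highest chi-square p, adjacent
pairs only for ordinal predictors) until every remaining pair differs at
``alpha_merge``; (2) scoring each predictor's merged table with a Pearson
chi-square whose p-value is Bonferroni-adjusted for the number of ways the
original categories can be reduced to the merged groups (Kass's
correction); and (3) splitting on the most significant predictor when its
adjusted p is at most ``alpha_split`` and the size constraints hold.  The
procedure is fully deterministic.

Accidents carrying several hazmat classes must be expanded into one case
per class first (see :func:`htarisk.records.expand_multiclass`); the tree
then sees ``hazmat_class`` as an ordinary single-valued predictor.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import RecordSet

__all__ = [
    "ContingencyTable",
    "ChaidParams",
    "ChaidNode",
    "ChaidTree",
    "ConfusionMatrix",
    "chi_square",
    "merge_categories",
    "build_tree",
    "cases_frame",
    "evaluate",
    "node_report",
    "SEVERITY_ORDER",
]

#: Severity labels from least to most severe (ties in prediction break
#: toward the more severe level).
SEVERITY_ORDER = ("I", "II", "III", "IV", "V")

#: Predictors treated as ordinal (only adjacent categories may merge).
DEFAULT_ORDINAL = ("period",)

DEFAULT_PREDICTORS = ("hazmat_class", "accident_type", "specific_type", "period", "cause_factor", "road_level")


@dataclass(frozen=True)
class ContingencyTable:
    """An R x C cross-tabulation of predictor categories against levels."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    @classmethod
    def from_series(cls, predictor: Sequence, target: Sequence) -> "ContingencyTable":
        tab = pd.crosstab(pd.Series(predictor), pd.Series(target))
        return cls(tab.to_numpy(dtype=float), tuple(tab.index), tuple(tab.columns))

    def total(self) -> int:
        return int(self.counts.sum())


def chi_square(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Empty rows and columns are dropped first; a table with fewer than two
    non-empty rows or columns is degenerate and rejected.  Returns
    (statistic, dof, p) with dof = (R-1)(C-1), no continuity correction.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("degenerate table: need at least 2 non-empty rows and columns")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def _pair_p(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """p-value of the 2 x C comparison of two category groups; 1.0 when the
    sub-table is degenerate (a single shared target level)."""
    try:
        return chi_square(np.vstack([counts_a, counts_b]))[2]
    except ValueError:
        return 1.0


def merge_categories(
    predictor: Sequence,
    target: Sequence,
    ordinal: bool = False,
    alpha_merge: float = 0.05,
) -> list[tuple]:
    """CHAID merge step: reduce predictor categories to significant groups.

    Iteratively merges the pair of groups (adjacent pair for ordinal
    predictors) with the highest chi-square p-value as long as it exceeds
    ``alpha_merge``.  May reduce to a single group, in which case the
    predictor carries no usable signal at this node.
    """
    tab = ContingencyTable.from_series(predictor, target)
    groups: list[tuple] = [(lbl,) for lbl in tab.row_labels]
    rows = [tab.counts[i].copy() for i in range(len(groups))]
    while len(groups) >= 2:
        if ordinal:
            candidates = [(i, i + 1) for i in range(len(groups) - 1)]
        else:
            candidates = list(itertools.combinations(range(len(groups)), 2))
        pvals = [_pair_p(rows[i], rows[j]) for i, j in candidates]
        best = int(np.argmax(pvals))
        if pvals[best] <= alpha_merge:
            break
        i, j = candidates[best]
        groups[i] = groups[i] + groups[j]
        rows[i] = rows[i] + rows[j]
        del groups[j], rows[j]
    return groups


def _bonferroni_multiplier(n_categories: int, n_groups: int, ordinal: bool) -> float:
    """Kass's multiplier: the number of ways ``n_categories`` can be reduced
    to ``n_groups`` — C(c-1, g-1) for ordinal predictors and the Stirling
    number of the second kind for nominal ones."""
    c, g = n_categories, n_groups
    if ordinal:
        return float(math.comb(c - 1, g - 1))
    return float(sum((-1) ** i * (g - i) ** c / (math.factorial(i) * math.factorial(g - i)) for i in range(g)))


@dataclass(frozen=True)
class ChaidParams:
    """Stopping and significance settings of the tree growth.

    ``bonferroni`` applies Kass's within-predictor correction for the
    category merging; ``adjust_predictors`` additionally divides
    ``alpha_split`` by the number of predictors tested at the node, so the
    node-level probability of a false split is controlled at
    ``alpha_split`` rather than inflating with the predictor count.
    """

    alpha_merge: float = 0.05
    alpha_split: float = 0.05
    bonferroni: bool = True
    adjust_predictors: bool = True
    min_parent: int = 20
    min_child: int = 10
    max_depth: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.alpha_merge <= 1 and 0 < self.alpha_split <= 1):
            raise ValueError("alpha levels must lie in (0, 1]")
        if self.min_child > self.min_parent:
            raise ValueError("min_child must not exceed min_parent")


@dataclass
class ChaidNode:
    """A tree node: class composition plus, if split, the chosen predictor,
    its merged category groups and the split's chi-square evidence."""

    node_id: int
    depth: int
    class_counts: dict
    split_var: str | None = None
    groups: list[tuple] = field(default_factory=list)
    chi2: float | None = None
    dof: int | None = None
    p_adj: float | None = None
    children: list["ChaidNode"] = field(default_factory=list)

    @property
    def size(self) -> int:
        return sum(self.class_counts.values())

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def modal_class(self):
        best = max(self.class_counts.values())
        tied = [k for k, v in self.class_counts.items() if v == best]
        return max(tied, key=lambda k: SEVERITY_ORDER.index(str(k)) if str(k) in SEVERITY_ORDER else -1)

    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "depth": self.depth,
            "size": self.size,
            "class_counts": {str(k): int(v) for k, v in self.class_counts.items()},
        }
        if not self.is_leaf:
            d.update(
                split_var=self.split_var,
                groups=[list(g) for g in self.groups],
                chi2=self.chi2,
                dof=self.dof,
                p_adj=self.p_adj,
                children=[c.to_dict() for c in self.children],
            )
        return d


@dataclass
class ChaidTree:
    root: ChaidNode
    target: str
    predictors: tuple[str, ...]
    ordinal: tuple[str, ...]
    params: ChaidParams

    def n_nodes(self) -> int:
        def count(node: ChaidNode) -> int:
            return 1 + sum(count(c) for c in node.children)

        return count(self.root)

    def predict(self, case: Mapping) -> str:
        """Route one case to a leaf and return its modal class.

        A category unseen at training is routed to the largest sibling
        child.  Ties in the leaf's class counts break toward the more
        severe level.
        """
        node = self.root
        while not node.is_leaf:
            value = case[node.split_var]
            child = None
            for grp, ch in zip(node.groups, node.children):
                if value in grp:
                    child = ch
                    break
            if child is None:  # unseen category
                child = max(node.children, key=lambda c: c.size)
            node = child
        return node.modal_class()

    def predict_frame(self, frame: pd.DataFrame) -> list:
        return [self.predict(row) for row in frame.to_dict("records")]

    def report(self) -> str:
        """Indented text report of the tree."""
        total = self.root.size
        lines: list[str] = []

        def walk(node: ChaidNode, indent: int, label: str) -> None:
            comp = node_report(node, total)
            dist = ", ".join(f"{k}: {v:.1f}%" for k, v in comp["class_percent"].items())
            head = f"{'  ' * indent}node {node.node_id} {label}n={node.size} ({comp['share_percent']:.1f}%) [{dist}]"
            if not node.is_leaf:
                head += f" split on {node.split_var} (chi2={node.chi2:.2f}, dof={node.dof}, adj p={node.p_adj:.3g})"
            lines.append(head)
            for grp, ch in zip(node.groups, node.children):
                walk(ch, indent + 1, f"{node.split_var} in {sorted(grp)} -> ")

        walk(self.root, 0, "")
        return "\n".join(lines)

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "target": self.target,
                "predictors": list(self.predictors),
                "ordinal": list(self.ordinal),
                "params": dataclasses.asdict(self.params),
                "n_nodes": self.n_nodes(),
                "root": self.root.to_dict(),
            },
            **kwargs,
        )


def cases_frame(rs: RecordSet) -> pd.DataFrame:
    """Coded per-case table for tree building from an *expanded* record set."""
    period_code = {"early_morning": 1, "forenoon": 2, "afternoon": 3, "evening": 4}
    rows = []
    for r in rs:
        if len(r.hazmat_classes) != 1:
            raise ValueError("multi-class record: run expand_multiclass first")
        rows.append(
            {
                "hazmat_class": next(iter(r.hazmat_classes)),
                "accident_type": r.accident_type,
                "specific_type": r.specific_type,
                "period": period_code[r.period],
                "cause_factor": r.cause_factor,
                "road_level": r.road_level,
                "severity_level": str(r.severity_level),
            }
        )
    return pd.DataFrame(rows)


def build_tree(
    data: pd.DataFrame | RecordSet,
    target: str = "severity_level",
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    params: ChaidParams | None = None,
    ordinal: Sequence[str] = DEFAULT_ORDINAL,
) -> ChaidTree:
    """Grow a CHAID tree on expanded accident cases.

    ``data`` is either a coded case table or an expanded
    :class:`~htarisk.records.RecordSet`.  A node becomes a leaf when it is
    pure, smaller than ``min_parent``, at ``max_depth``, when no predictor
    reaches ``alpha_split`` after the Bonferroni adjustment, or when the
    best split would produce a child smaller than ``min_child``.
    """
    if isinstance(data, RecordSet):
        data = cases_frame(data)
    params = params or ChaidParams()
    predictors = tuple(p for p in predictors if p in data.columns)
    if not predictors:
        raise ValueError("no usable predictor columns")
    levels = sorted(data[target].unique(), key=lambda v: SEVERITY_ORDER.index(str(v)) if str(v) in SEVERITY_ORDER else str(v))
    counter = itertools.count(1)

    def class_counts(frame: pd.DataFrame) -> dict:
        vc = frame[target].value_counts()
        return {lvl: int(vc.get(lvl, 0)) for lvl in levels}

    def grow(frame: pd.DataFrame, depth: int) -> ChaidNode:
        node = ChaidNode(node_id=next(counter), depth=depth, class_counts=class_counts(frame))
        if depth >= params.max_depth or len(frame) < params.min_parent or frame[target].nunique() < 2:
            return node
        best = None  # (p_adj, order, predictor, groups, chi2, dof)
        for order, pred in enumerate(predictors):
            if frame[pred].nunique() < 2:
                continue
            groups = merge_categories(frame[pred], frame[target], ordinal=pred in ordinal, alpha_merge=params.alpha_merge)
            if len(groups) < 2:
                continue
            member = {cat: gi for gi, grp in enumerate(groups) for cat in grp}
            merged = ContingencyTable.from_series(frame[pred].map(member), frame[target])
            try:
                stat, dof, p = chi_square(merged)
            except ValueError:
                continue
            if params.bonferroni:
                p = min(1.0, p * _bonferroni_multiplier(frame[pred].nunique(), len(groups), pred in ordinal))
            cand = (p, order, pred, groups, stat, dof)
            if best is None or cand[:2] < best[:2]:
                best = cand
        n_tested = sum(1 for p in predictors if frame[p].nunique() >= 2)
        threshold = params.alpha_split / (max(n_tested, 1) if params.adjust_predictors else 1)
        if best is None or best[0] > threshold:
            return node
        p_adj, _, pred, groups, stat, dof = best
        parts = [frame[frame[pred].isin(grp)] for grp in groups]
        if any(len(part) < params.min_child for part in parts):
            return node
        node.split_var, node.groups, node.chi2, node.dof, node.p_adj = pred, groups, stat, dof, p_adj
        node.children = [grow(part, depth + 1) for part in parts]
        return node

    return ChaidTree(root=grow(data, 0), target=target, predictors=predictors, ordinal=tuple(ordinal), params=params)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Actual-by-predicted class counts with per-row correct percentages."""

    counts: pd.DataFrame  # rows = actual, columns = predicted

    @classmethod
    def from_predictions(cls, actual: Sequence, predicted: Sequence, labels: Sequence | None = None) -> "ConfusionMatrix":
        if len(actual) != len(predicted):
            raise ValueError("actual and predicted must have equal length")
        actual = [str(v) for v in actual]
        predicted = [str(v) for v in predicted]
        if labels is None:
            seen = set(actual) | set(predicted)
            labels = [l for l in SEVERITY_ORDER if l in seen] or sorted(seen)
        else:
            labels = [str(l) for l in labels]
            bad = (set(actual) | set(predicted)) - set(labels)
            if bad:
                raise ValueError(f"labels outside the level set: {sorted(bad)}")
        mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for a, p in zip(actual, predicted):
            mat.loc[a, p] += 1
        return cls(mat)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts.to_numpy())) / float(self.counts.to_numpy().sum())

    def row_percent(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts.to_numpy()), index=self.counts.index, dtype=float)
        totals = self.counts.sum(axis=1)
        return (diag / totals.where(totals > 0)).fillna(0.0) * 100.0

    def column_percent(self) -> pd.Series:
        """Share of all predictions falling in each predicted class."""
        return self.counts.sum(axis=0) / self.counts.to_numpy().sum() * 100.0

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy().astype(object)
        out["correct_percent"] = [round(v, 1) for v in self.row_percent()]
        return out


def evaluate(actual: Sequence, predicted: Sequence, labels: Sequence | None = None) -> ConfusionMatrix:
    """Confusion matrix of predicted vs actual severity levels."""
    return ConfusionMatrix.from_predictions(actual, predicted, labels)


def node_report(node: ChaidNode, total_cases: int) -> dict:
    """Composition summary: node share of all cases and per-class percentages."""
    size = node.size
    return {
        "node_id": node.node_id,
        "size": size,
        "share_percent": round(100.0 * size / total_cases, 1),
        "class_percent": {str(k): round(100.0 * v / size, 1) if size else 0.0 for k, v in node.class_counts.items()},
    }
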