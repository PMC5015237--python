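"""Confusion-matrix construction and diagnostic rates.

The crosstab cells follow the conventional naming: a = true-positive,
b = false-positive, c = false-negative, d = true-negative, from which

    sensitivity          = a / (a + c)
    specificity          = d / (b + d)
    false-positive rate  = b / (b + d)
    false-negative rate  = c / (a + c)

d can legitimately be unknown (a region-restricted reading of the finding
lists leaves the negative column unfilled); rates whose denominator is then
unavailable are reported as undefined (None), never coerced to a number.

Report output follows the field's presentation: percentages to one decimal,
proportions to three decimals; full-precision values are always retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "MatchSpec", "rates", "crosstab_from_lists",
           "match_to_truth", "per_unit_rollup", "format_report"]


@dataclass(frozen=True)
class ConfusionCounts:
    a: int  # true-positive
    b: int  # false-positive
    c: int  # false-negative
    d: int | None = None  # true-negative; may be unknown

    def __post_init__(self) -> None:
        for name in "abc":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")
        if self.d is not None and (not isinstance(self.d, (int, np.integer)) or self.d < 0):
            raise ValueError(f"count d must be a non-negative integer or None, got {self.d!r}")

    @property
    def total(self) -> int | None:
        return None if self.d is None else self.a + self.b + self.c + self.d

    @property
    def correction_rate(self) -> float | None:
        """(b + c) / total — the fraction of findings the experts had to move."""
        return None if self.total in (None, 0) else (self.b + self.c) / self.total


@dataclass(frozen=True)
class MatchSpec:
    max_centroid_distance_mm: float = 10.0
    matching: str = "greedy_by_probability"

    def __post_init__(self) -> None:
        if self.max_centroid_distance_mm <= 0:
            raise ValueError("matching distance must be positive")
        if self.matching != "greedy_by_probability":
            raise ValueError(f"unknown matching mode {self.matching!r}")


def rates(cc: ConfusionCounts) -> dict[str, float | None]:
    """The four crosstab estimators; undefined denominators yield None."""
    pos = cc.a + cc.c
    neg = None if cc.d is None else cc.b + cc.d
    return {
        "sensitivity": cc.a / pos if pos > 0 else None,
        "specificity": cc.d / neg if neg not in (None, 0) else None,
        "false_positive_rate": cc.b / neg if neg not in (None, 0) else None,
        "false_negative_rate": cc.c / pos if pos > 0 else None,
    }


def crosstab_from_lists(program_lists: tuple[list, list],
                        corrected_lists: tuple[list, list]) -> ConfusionCounts:
    """Crosstab of the program's lists against the expert-corrected lists.

    Inputs are (true_labels, false_labels) pairs; items may be finding labels
    or objects with a ``label`` attribute.  Both pairs must cover the same
    label set.
    """
    def labels(seq):
        return {x.label if hasattr(x, "label") else x for x in seq}

    pt, pf = labels(program_lists[0]), labels(program_lists[1])
    ct, cf = labels(corrected_lists[0]), labels(corrected_lists[1])
    if pt & pf or ct & cf:
        raise ValueError(f"labels appear in both lists: {sorted((pt & pf) | (ct & cf))}")
    if (pt | pf) != (ct | cf):
        raise ValueError(
            f"label sets differ between program and corrected lists: "
            f"{sorted((pt | pf) ^ (ct | cf))}")
    return ConfusionCounts(a=len(pt & ct), b=len(pt & cf), c=len(pf & ct), d=len(pf & cf))


def match_to_truth(true_findings: list, false_findings: list, truth_nodes,
                   spec: MatchSpec = MatchSpec()) -> ConfusionCounts:
    """Greedy correspondence of findings to planted phantom nodes.

    ``truth_nodes`` is a sequence of objects/mappings with a position in mm
    (``position_mm``).  True findings are visited in descending probability;
    each matches the nearest still-unmatched node within the distance bound.
    a = matched true findings, b = unmatched true findings, c = unmatched
    nodes, d = false findings not within the bound of any node.
    """
    def pos(n):
        return np.asarray(n["position_mm"] if isinstance(n, dict) else n.position_mm, float)

    node_pos = [pos(n) for n in truth_nodes]
    unmatched = set(range(len(node_pos)))
    a = b = 0
    for f in sorted(true_findings, key=lambda f: -f.probability):
        c_mm = np.asarray(f.hotspot.centroid_mm)
        best, best_d = None, spec.max_centroid_distance_mm
        for i in unmatched:
            d = float(np.linalg.norm(node_pos[i] - c_mm))
            if d <= best_d:
                best, best_d = i, d
        if best is None:
            b += 1
        else:
            unmatched.discard(best)
            a += 1
    c = len(unmatched)
    d = 0
    for f in false_findings:
        c_mm = np.asarray(f.hotspot.centroid_mm)
        if all(float(np.linalg.norm(p - c_mm)) > spec.max_centroid_distance_mm
               for p in node_pos):
            d += 1
    return ConfusionCounts(a=a, b=b, c=c, d=d)


def per_unit_rollup(assignments: pd.DataFrame):
    """Per-unit (patient or groin) crosstab plus simple event proportions.

    ``assignments`` needs columns ``unit`` and ``outcome`` (TP/FP/FN/TN); any
    further boolean columns are treated as per-unit event flags whose
    proportions over all units are reported alongside — a distinct quantity
    from the crosstab rates (e.g. procedure failures per groin vs the
    crosstab false-negative rate).
    """
    df = pd.DataFrame(assignments)
    if df["unit"].duplicated().any():
        dupes = sorted(df.loc[df["unit"].duplicated(), "unit"].unique().tolist())
        raise ValueError(f"duplicate unit ids: {dupes}")
    bad = set(df["outcome"]) - {"TP", "FP", "FN", "TN"}
    if bad:
        raise ValueError(f"unknown outcomes: {sorted(bad)}")
    n = len(df)
    counts = df["outcome"].value_counts()
    cc = ConfusionCounts(a=int(counts.get("TP", 0)), b=int(counts.get("FP", 0)),
                         c=int(counts.get("FN", 0)), d=int(counts.get("TN", 0)))
    events = {col: float(df[col].astype(bool).sum()) / n
              for col in df.columns if col not in ("unit", "outcome")}
    return cc, rates(cc), events


def _pct(x: float | None) -> str:
    return "undefined" if x is None else f"{100 * x:.1f} %"


def _prop(x: float | None) -> str:
    return "undefined" if x is None else f"{x:.3f}"


def format_report(cc: ConfusionCounts, title: str = "Crosstab") -> str:
    """Plain-text rendering of a crosstab and its rates."""
    r = rates(cc)
    d = "-" if cc.d is None else str(cc.d)
    tot = "-" if cc.total is None else str(cc.total)
    lines = [
        title,
        "-" * len(title),
        f"  true-positive  (a): {cc.a:>6}",
        f"  false-positive (b): {cc.b:>6}",
        f"  false-negative (c): {cc.c:>6}",
        f"  true-negative  (d): {d:>6}",
        f"  total             : {tot:>6}",
        "",
        f"  Sensitivity         {_pct(r['sensitivity'])}",
        f"  Specificity         {_pct(r['specificity'])}",
        f"  False-positive rate {_prop(r['false_positive_rate'])}",
        f"  False-negative rate {_prop(r['false_negative_rate'])}",
    ]
    return "\n".join(lines)
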