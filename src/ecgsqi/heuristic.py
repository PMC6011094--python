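"""Rule-based fusion of per-index grades into an E/B/U quality label.

Given the three-level grades of k entered indices (k = 2..5), a fixed rule
table counts how many are "optimal", "suspicious" and "unqualified" and maps
the counts to Excellent (E), Barely acceptable (B) or Unacceptable (U).  The
tables are fixed; no threshold optimization is performed.  Also provides the
sensitivity / specificity / accuracy arithmetic used to score classifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

OPTIMAL, SUSPICIOUS, UNQUALIFIED = "optimal", "suspicious", "unqualified"

__all__ = ["GradeCounts", "ConfusionCounts", "count_grades",
           "fuse_heuristic", "confusion_metrics"]


@dataclass(frozen=True)
class GradeCounts:
    n_optimal: int
    n_suspicious: int
    n_unqualified: int

    @property
    def total(self) -> int:
        return self.n_optimal + self.n_suspicious + self.n_unqualified


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def count_grades(grades: Sequence[str]) -> GradeCounts:
    for g in grades:
        if g not in (OPTIMAL, SUSPICIOUS, UNQUALIFIED):
            raise ValueError(f"unknown grade {g!r}")
    return GradeCounts(
        sum(g == OPTIMAL for g in grades),
        sum(g == SUSPICIOUS for g in grades),
        sum(g == UNQUALIFIED for g in grades),
    )


def fuse_heuristic(grades: Sequence[str]) -> str:
    """Map k = 2..5 per-index grades to an E/B/U label via the rule tables.

    Writing o / s / u for the optimal / suspicious / unqualified counts:

    k=2:  E if o == 2;  B if s == 2 or (o == 1 and s == 1);  else U.
    k=3:  E if o >= 2 and u == 0;
          U if u == 2 or (s == 2 and u == 1);  else B.
    k=4:  E if o >= 3 and u == 0;
          U if u >= 3 or (u == 2 and s >= 1) or (u == 1 and s == 3);  else B.
    k=5:  E if o >= 4 and u == 0;
          U if u >= 4 or (u == 3 and s >= 1) or (u == 2 and s >= 2)
                      or (u == 1 and s == 4);  else B.

    For k = 3..5 the catch-all level is B; for k = 2 it is U.
    """
    k = len(grades)
    if not 2 <= k <= 5:
        raise ValueError(f"rule tables are defined for 2-5 entered SQIs, got {k}")
    c = count_grades(grades)
    o, s, u = c.n_optimal, c.n_suspicious, c.n_unqualified

    if k == 2:
        if o == 2:
            return "E"
        if s == 2 or (o == 1 and s == 1):
            return "B"
        return "U"
    if k == 3:
        if o >= 2 and u == 0:
            return "E"
        if u == 2 or (s == 2 and u == 1):
            return "U"
        return "B"
    if k == 4:
        if o >= 3 and u == 0:
            return "E"
        if u >= 3 or (u == 2 and s >= 1) or (u == 1 and s == 3):
            return "U"
        return "B"
    # k == 5
    if o >= 4 and u == 0:
        return "E"
    if u >= 4 or (u == 3 and s >= 1) or (u == 2 and s >= 2) or (u == 1 and s == 4):
        return "U"
    return "B"


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity, accuracy in percent.

    Acceptable segments are the positive class.  A zero denominator yields a
    NaN marker for the affected metric rather than an exception.
    """
    nan = float("nan")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    se = 100.0 * tp / (tp + fn) if tp + fn > 0 else nan
    sp = 100.0 * tn / (tn + fp) if tn + fp > 0 else nan
    total = tp + tn + fp + fn
    acc = 100.0 * (tp + tn) / total if total > 0 else nan
    return se, sp, acc
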