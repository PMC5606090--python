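"""Person-level accounting across item sets: group means, deltas, PSI.

Whether DIF is worth acting on shows up here: the between-group difference in
mean person locations shifts as DIF items are resolved, while the Person
Separation Index (PSI) — the share of person-estimate variance not
attributable to estimation error, analogous to coefficient alpha but usable
with missing data — barely moves under resolution (unlike deletion).
Group means exclude extreme-score persons; this is noted in output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasch_core import PersonEstimates

__all__ = [
    "ComparisonTable",
    "group_means",
    "difference_delta",
    "person_separation_index",
    "comparison_table_from_trace",
]


@dataclass
class ComparisonTable:
    """Group mean locations, their difference, and PSI per item set (column)."""

    group_a: str
    group_b: str
    columns: list[str] = field(default_factory=list)
    mean_a: list[float] = field(default_factory=list)
    mean_b: list[float] = field(default_factory=list)
    difference: list[float] = field(default_factory=list)
    psi: list[float] = field(default_factory=list)
    excludes_extremes: bool = True

    def add_column(self, label, mean_a, mean_b, psi=np.nan):
        self.columns.append(label)
        self.mean_a.append(mean_a)
        self.mean_b.append(mean_b)
        self.difference.append(mean_a - mean_b)
        self.psi.append(psi)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                c: [
                    round(self.mean_a[k], 3),
                    round(self.mean_b[k], 3),
                    round(self.difference[k], 3),
                    round(self.psi[k], 3) if np.isfinite(self.psi[k]) else np.nan,
                ]
                for k, c in enumerate(self.columns)
            },
            index=[
                str(self.group_a),
                str(self.group_b),
                f"Difference {self.group_a}-{self.group_b}",
                "Person Separation Index",
            ],
        )
        frame.attrs["excludes_extremes"] = self.excludes_extremes
        return frame


def group_means(persons: PersonEstimates, group_a, group_b) -> tuple[float, float, float]:
    """Arithmetic mean locations of two groups and their difference.

    Means are over non-extreme persons with finite estimates; an empty group
    is an error.  The difference is group_a mean minus group_b mean.
    """
    usable = np.isfinite(persons.location) & ~persons.extreme
    out = []
    for g in (group_a, group_b):
        sel = usable & (persons.group == g)
        if sel.sum() == 0:
            raise ValueError(f"group {g!r}: no non-extreme persons")
        out.append(float(persons.location[sel].mean()))
    return out[0], out[1], out[0] - out[1]


def difference_delta(
    table: ComparisonTable, set_a: str, set_b: str
) -> tuple[float, float | None]:
    """Change in the between-group difference from item set A to item set B.

    Returns (absolute change in logits, rounded to 2 decimals; relative change
    as an integer percent of set A's difference).  The relative change is None
    when the baseline difference is zero.
    """
    for s in (set_a, set_b):
        if s not in table.columns:
            raise KeyError(f"item set {s!r} not in table")
    da = table.difference[table.columns.index(set_a)]
    db = table.difference[table.columns.index(set_b)]
    absolute = round(da - db, 2)
    if da == 0:
        warnings.warn("zero baseline difference; relative change undefined", stacklevel=2)
        return absolute, None
    relative = round((da - db) / da * 100)
    return absolute, float(relative)


def person_separation_index(persons: PersonEstimates) -> float:
    """PSI = (var(beta) - mean(se^2)) / var(beta), truncated to [0, 1].

    Observed variance of the person estimates minus the mean squared standard
    error, as a share of the observed variance: the classic separation
    reliability.  NaN when fewer than 2 usable persons or zero variance.
    """
    usable = np.isfinite(persons.location) & ~persons.extreme & np.isfinite(persons.se)
    if usable.sum() < 2:
        raise ValueError("need at least 2 non-extreme persons for PSI")
    beta = persons.location[usable]
    se2 = persons.se[usable] ** 2
    var = float(np.var(beta, ddof=1))
    if var <= 0:
        warnings.warn("zero person variance; PSI undefined", stacklevel=2)
        return np.nan
    psi = (var - float(se2.mean())) / var
    if psi < 0:
        warnings.warn("negative PSI estimate truncated to 0", stacklevel=2)
        return 0.0
    return min(psi, 1.0)


def comparison_table_from_trace(trace, group_a=None, group_b=None) -> ComparisonTable:
    """Build the per-item-set comparison table from a resolution trace.

    One column per stage: the original item set, then the roster after each
    resolution, using the person estimates of the pass fitted on that roster.
    """
    if not trace.steps:
        raise ValueError("empty resolution trace")
    groups = list(pd.unique(trace.steps[0].persons.group))
    if group_a is None:
        group_a, group_b = groups[0], groups[1]
    table = ComparisonTable(group_a=str(group_a), group_b=str(group_b))
    resolved_so_far = []
    for s in trace.steps:
        label = (
            "original"
            if not resolved_so_far
            else "resolved: " + " + ".join(resolved_so_far)
        )
        ma, mb, _ = group_means(s.persons, group_a, group_b)
        table.add_column(label, ma, mb, person_separation_index(s.persons))
        if s.item_resolved is not None:
            resolved_so_far.append(s.item_resolved)
    return table
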