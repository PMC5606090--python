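"""Reading response data, run configuration, and tabular output writers.

Input formats
-------------
* wide CSV: one row per person; columns ``person_id``, a group column, and
  one integer-scored column per item.  Empty cells or a configurable token
  (default also "NA") are missing.
* long CSV: columns ``person_id``, ``group``, ``item_id``, ``score``;
  absent (person, item) combinations are missing.

Outputs are tab-separated tables with fixed decimal formats so runs are
diffable; all randomness in a run funnels through one seeded generator that
is echoed in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .rasch_core import ItemDef, ItemParameterSet, PersonEstimates, ResponseMatrix

logger = logging.getLogger("raschdif")

__all__ = [
    "RunConfig",
    "read_wide_csv",
    "read_long_csv",
    "write_item_table",
    "write_person_table",
    "write_anova_table",
    "write_comparison_table",
    "write_trace_summary",
]


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the reference analysis setup
    (10 class intervals, adjusted sample size 960, alpha 0.05)."""

    input: str | None = None
    format: str = "wide"  # wide | long
    group_col: str = "group"
    id_col: str = "person_id"
    item_cols: list[str] | None = None
    missing_token: str = "NA"
    n_intervals: int = 10
    n_adjusted: int = 960
    alpha: float = 0.05
    person_method: str = "wle"
    null_category: str = "keep"
    seed: int = 0
    out: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def merged(self, **overrides) -> "RunConfig":
        d = {**self.__dict__}
        d.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**d)


def _parse_scores(frame: pd.DataFrame, item_cols, missing_token: str, path) -> np.ndarray:
    cols = []
    for c in item_cols:
        raw = frame[c].astype(object)
        raw = raw.where(~raw.astype(str).str.strip().isin(["", missing_token]), np.nan)
        try:
            col = pd.to_numeric(raw)
        except (ValueError, TypeError) as exc:
            bad = raw[pd.to_numeric(raw, errors="coerce").isna() & raw.notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ValueError(
                f"{path}: item column {c!r}, line {line}: non-numeric score"
            ) from exc
        cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def read_wide_csv(
    path,
    group_col: str = "group",
    id_col: str = "person_id",
    item_cols: list[str] | None = None,
    missing_token: str = "NA",
) -> ResponseMatrix:
    """Load a wide-format response CSV into a :class:`ResponseMatrix`."""
    try:
        frame = pd.read_csv(path, dtype=object)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    for col in (id_col, group_col):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if item_cols is None:
        item_cols = [c for c in frame.columns if c not in (id_col, group_col)]
    if not item_cols:
        raise ValueError(f"{path}: no item columns found")
    scores = _parse_scores(frame, item_cols, missing_token, path)
    items = []
    for j, c in enumerate(item_cols):
        col = scores[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"{path}: item column {c!r} has no observed scores")
        items.append(ItemDef(item_id=str(c), max_score=max(1, int(obs.max()))))
    return ResponseMatrix(
        person_ids=frame[id_col].to_numpy(dtype=object),
        group=frame[group_col].to_numpy(dtype=object),
        scores=scores,
        items=items,
    )


def read_long_csv(
    path,
    group_col: str = "group",
    id_col: str = "person_id",
    item_col: str = "item_id",
    score_col: str = "score",
    missing_token: str = "NA",
) -> ResponseMatrix:
    """Load a long-format response CSV (person_id, group, item_id, score)."""
    try:
        frame = pd.read_csv(path, dtype=object)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    for col in (id_col, group_col, item_col, score_col):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    wide = frame.pivot_table(
        index=[id_col, group_col],
        columns=item_col,
        values=score_col,
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    item_cols = [c for c in wide.columns if c not in (id_col, group_col)]
    scores = _parse_scores(wide, item_cols, missing_token, path)
    items = []
    for j, c in enumerate(item_cols):
        obs = scores[:, j][~np.isnan(scores[:, j])]
        if obs.size == 0:
            raise ValueError(f"{path}: item {c!r} has no observed scores")
        items.append(ItemDef(item_id=str(c), max_score=max(1, int(obs.max()))))
    return ResponseMatrix(
        person_ids=wide[id_col].to_numpy(dtype=object),
        group=wide[group_col].to_numpy(dtype=object),
        scores=scores,
        items=items,
    )


# ---------------------------------------------------------------------------
# Writers (TSV, fixed decimal formats for diffability)
# ---------------------------------------------------------------------------


def _write(frame: pd.DataFrame, path, float_format="%.5f") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)
    logger.info("wrote %s (%d rows)", path, len(frame))


def write_item_table(items: ItemParameterSet, path) -> None:
    rows = []
    for it in items.items:
        row = {
            "item": it.item_id,
            "group_restriction": it.group_restriction,
            "location": it.location,
            "se_location": it.se_location,
            "max_score": it.max_score,
            "disordered": it.disordered,
        }
        for k, t in enumerate(it.thresholds, start=1):
            row[f"tau{k}"] = t
        rows.append(row)
    _write(pd.DataFrame(rows), path)


def write_person_table(persons: PersonEstimates, path) -> None:
    frame = pd.DataFrame(
        {
            "person_id": persons.person_ids,
            "group": persons.group,
            "total": persons.total,
            "n_answered": persons.n_answered,
            "location": persons.location,
            "se": persons.se,
            "extreme": persons.extreme,
        }
    )
    _write(frame, path)


def write_anova_table(frame: pd.DataFrame, path) -> None:
    """Write a detection-pass report with its caption metadata as # comments."""
    with open(path, "w") as fh:
        for key in ("n_intervals", "n_adjusted", "bonferroni_level", "n_tests"):
            if key in frame.attrs:
                fh.write(f"# {key} = {frame.attrs[key]}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    logger.info("wrote %s (%d items)", path, len(frame))


def write_comparison_table(table, path) -> None:
    frame = table.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# excludes_extremes = {table.excludes_extremes}\n")
        frame.to_csv(fh, sep="\t", float_format="%.3f")
    logger.info("wrote %s", path)


def write_trace_summary(trace, path) -> None:
    rows = []
    for s in trace.steps:
        rows.append(
            {
                "step": s.step,
                "item_resolved": s.item_resolved or "",
                "f_group_at_resolution": s.f_group_at_resolution,
                "n_items_after": len(s.item_ids_after),
                "n_flagged": len(s.analysis.flagged),
                "bonferroni_level": round(s.analysis.threshold, 6),
                "n_tests": s.analysis.n_tests,
            }
        )
    _write(pd.DataFrame(rows), path)
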