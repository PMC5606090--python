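"""DIF detection by two-way ANOVA of standardized residuals.

For each person n and answered item i the standardized residual is

    z_ni = (x_ni - E[x_ni]) / sqrt(V[x_ni])

with the PCM expectation and variance evaluated at the person's estimated
location.  Persons are then binned into C class intervals of approximately
equal size along the latent continuum, and a two-way fixed-effects ANOVA of
the residuals with factors class interval and group is run per item:

* class-interval main effect  -> overall item fit along the continuum,
* group main effect           -> uniform DIF (parallel shift of the EVC),
* group x class interaction   -> non-uniform DIF (curves not parallel).

With very large samples even negligible misfit reaches significance, so the
test statistics may additionally be scaled to a nominal analysis sample size
(default 960) before p-values are evaluated, and the significance level is
Bonferroni-divided by the number of tests performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .rasch_core import (
    ItemParameterSet,
    PersonEstimates,
    ResponseMatrix,
    _moments_grid,
)

logger = logging.getLogger("raschdif")

__all__ = [
    "ResidualMatrix",
    "ClassIntervalAssignment",
    "AnovaResult",
    "standardized_residuals",
    "assign_class_intervals",
    "dif_anova_item",
    "adjust_for_sample_size",
    "bonferroni_threshold",
    "rank_dif_items",
    "dif_analysis",
    "anova_results_frame",
]

_MIN_VARIANCE = 1e-12


@dataclass
class ResidualMatrix:
    """Standardized residuals z (persons x items); NaN where undefined."""

    z: np.ndarray
    person_ids: np.ndarray
    group: np.ndarray
    item_ids: list[str]

    def column(self, item_id: str) -> np.ndarray:
        return self.z[:, self.item_ids.index(item_id)]


@dataclass
class ClassIntervalAssignment:
    """Partition of non-extreme persons into C ordered latent-location bins.

    ``interval`` holds 1..C per person (0 = unassigned: extreme or no
    estimate).  Persons with identical locations always share a bin; target
    bin sizes follow the quantile rule with remainders given to the lowest
    intervals, so realized sizes are as equal as ties permit.
    """

    n_intervals: int
    interval: np.ndarray
    boundaries: np.ndarray
    counts: np.ndarray


@dataclass
class AnovaResult:
    """Per-item two-way ANOVA of residuals: class, group and interaction effects."""

    item_id: str
    group_restriction: str
    f_class: float
    f_group: float
    f_interaction: float
    df_class: tuple
    df_group: tuple
    df_interaction: tuple
    p_class: float
    p_group: float
    p_interaction: float
    n_effective: int
    n_cells: int
    # sample-size-adjusted variants (None until adjust_for_sample_size)
    n_adjusted: int | None = None
    f_class_adj: float = np.nan
    f_group_adj: float = np.nan
    f_interaction_adj: float = np.nan
    p_class_adj: float = np.nan
    p_group_adj: float = np.nan
    p_interaction_adj: float = np.nan

    @property
    def has_group_tests(self) -> bool:
        return np.isfinite(self.f_group) or np.isfinite(self.f_interaction)

    def effective_p(self, effect: str) -> float:
        """Adjusted p-value when available, raw otherwise."""
        adj = getattr(self, f"p_{effect}_adj")
        if self.n_adjusted is not None and np.isfinite(adj):
            return adj
        return getattr(self, f"p_{effect}")

    def effective_f(self, effect: str) -> float:
        adj = getattr(self, f"f_{effect}_adj")
        if self.n_adjusted is not None and np.isfinite(adj):
            return adj
        return getattr(self, f"f_{effect}")


# ---------------------------------------------------------------------------
# Residuals
# ---------------------------------------------------------------------------


def standardized_residuals(
    responses: ResponseMatrix,
    items: ItemParameterSet,
    persons: PersonEstimates,
) -> ResidualMatrix:
    """Compute z_ni = (x_ni - E[x_ni]) / sqrt(V[x_ni]) at estimated locations.

    Cells are NaN where the response is missing, the person is extreme (no
    finite location), or the model variance underflows (warned).
    """
    n, ni = responses.scores.shape
    z = np.full((n, ni), np.nan)
    usable = np.isfinite(persons.location) & ~persons.extreme
    n_tiny = 0
    for j, it_def in enumerate(responses.items):
        item = items[it_def.item_id]
        mask = responses.answered[:, j] & usable
        if not mask.any():
            continue
        beta = persons.location[mask]
        e, v = _moments_grid(item, beta)
        tiny = v < _MIN_VARIANCE
        n_tiny += int(tiny.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            zz = (responses.scores[mask, j] - e) / np.sqrt(v)
        zz[tiny] = np.nan
        z[mask, j] = zz
    if n_tiny:
        warnings.warn(
            f"{n_tiny} residual cell(s) dropped: model variance < {_MIN_VARIANCE}",
            stacklevel=2,
        )
    return ResidualMatrix(
        z=z,
        person_ids=persons.person_ids,
        group=persons.group,
        item_ids=responses.item_ids,
    )


# ---------------------------------------------------------------------------
# Class intervals
# ---------------------------------------------------------------------------


def assign_class_intervals(
    persons: PersonEstimates, n_intervals: int = 10
) -> ClassIntervalAssignment:
    """Bin non-extreme persons into ordered intervals of near-equal size.

    Quantile partition with two deterministic rules: remainders go to the
    lowest-numbered intervals, and persons with tied locations are never split
    across intervals (the whole tie group joins the interval in which its
    first member falls).
    """
    if n_intervals < 2:
        raise ValueError("need at least 2 class intervals")
    usable = np.isfinite(persons.location) & ~persons.extreme
    n_use = int(usable.sum())
    if n_use < n_intervals:
        raise ValueError(
            f"only {n_use} non-extreme persons for {n_intervals} intervals"
        )
    locs = persons.location[usable]
    uniq = np.unique(locs)
    if len(uniq) < n_intervals:
        warnings.warn(
            f"only {len(uniq)} distinct locations; reducing intervals "
            f"{n_intervals} -> {len(uniq)}",
            stacklevel=2,
        )
        n_intervals = len(uniq)

    base, rem = divmod(n_use, n_intervals)
    sizes = np.full(n_intervals, base)
    sizes[:rem] += 1  # remainders to the lowest intervals
    cum_targets = np.cumsum(sizes)

    counts = np.array([(locs == u).sum() for u in uniq])
    interval_of_uniq = np.zeros(len(uniq), dtype=int)
    c = 0
    filled = 0
    for k in range(len(uniq)):
        # tie group joins the interval where its first member falls
        while filled >= cum_targets[c] and c < n_intervals - 1:
            c += 1
        interval_of_uniq[k] = c + 1
        filled += counts[k]

    interval = np.zeros(len(persons), dtype=int)
    idx = np.searchsorted(uniq, persons.location[usable])
    interval[usable] = interval_of_uniq[idx]

    realized = np.bincount(interval, minlength=n_intervals + 1)[1:]
    # a massive tie group can overshoot several quantile targets and leave an
    # interval empty; its boundary is then undefined (NaN)
    boundaries = np.array(
        [
            locs[interval[usable] == c + 1].max() if realized[c] else np.nan
            for c in range(n_intervals)
        ]
    )
    return ClassIntervalAssignment(
        n_intervals=n_intervals,
        interval=interval,
        boundaries=boundaries,
        counts=realized,
    )


# ---------------------------------------------------------------------------
# Per-item ANOVA
# ---------------------------------------------------------------------------


def _extract(table: pd.DataFrame, row: str):
    f = float(table.loc[row, "F"])
    p = float(table.loc[row, "PR(>F)"])
    df = float(table.loc[row, "df"])
    return f, p, df


def dif_anova_item(
    z_item: np.ndarray,
    assignment: ClassIntervalAssignment,
    groups: np.ndarray,
    item_id: str = "",
    group_restriction: str = "all",
) -> AnovaResult:
    """Two-way fixed-effects ANOVA of one item's residuals.

    Factors: class interval and group.  Type II sums of squares for main
    effects (each adjusted for the other), interaction from the full
    factorial; unbalanced and empty cells are handled through the model ranks
    (df adjust automatically, with a warning when cells are empty).  A
    group-restricted (resolved) item gets the one-way class-interval test
    only; its group and interaction entries are NaN.
    """
    ok = np.isfinite(z_item) & (assignment.interval > 0)
    z = z_item[ok]
    iv = assignment.interval[ok]
    g = np.asarray(groups, dtype=object)[ok]
    n_eff = int(ok.sum())
    levels_g = pd.unique(g)
    levels_c = np.unique(iv)
    one_way = group_restriction != "all" or len(levels_g) < 2

    if len(levels_c) < 2:
        raise ValueError(f"item {item_id!r}: fewer than 2 class intervals with data")
    if np.allclose(z, z[0]):
        warnings.warn(
            f"item {item_id!r}: all residuals identical; F undefined", stacklevel=2
        )
        nan3 = (np.nan,) * 3
        return AnovaResult(
            item_id, group_restriction, *nan3, (np.nan, np.nan), (np.nan, np.nan),
            (np.nan, np.nan), *nan3, n_eff, 0,
        )

    df_frame = pd.DataFrame({"z": z, "iv": pd.Categorical(iv), "g": pd.Categorical(g)})

    if one_way:
        model = smf.ols("z ~ C(iv)", data=df_frame).fit()
        table = anova_lm(model, typ=2)
        f_c, p_c, df_c = _extract(table, "C(iv)")
        df_resid = float(table.loc["Residual", "df"])
        return AnovaResult(
            item_id=item_id,
            group_restriction=group_restriction,
            f_class=f_c,
            f_group=np.nan,
            f_interaction=np.nan,
            df_class=(df_c, df_resid),
            df_group=(np.nan, np.nan),
            df_interaction=(np.nan, np.nan),
            p_class=p_c,
            p_group=np.nan,
            p_interaction=np.nan,
            n_effective=n_eff,
            n_cells=len(levels_c),
        )

    cell_counts = df_frame.groupby(["iv", "g"], observed=False).size()
    n_empty = int((cell_counts == 0).sum())
    if n_empty:
        warnings.warn(
            f"item {item_id!r}: {n_empty} empty class x group cell(s); "
            "df adjusted accordingly",
            stacklevel=2,
        )
    model = smf.ols("z ~ C(iv) * C(g)", data=df_frame).fit()
    table = anova_lm(model, typ=2)
    f_c, p_c, df_c = _extract(table, "C(iv)")
    f_g, p_g, df_g = _extract(table, "C(g)")
    f_i, p_i, df_i = _extract(table, "C(iv):C(g)")
    df_resid = float(table.loc["Residual", "df"])
    return AnovaResult(
        item_id=item_id,
        group_restriction=group_restriction,
        f_class=f_c,
        f_group=f_g,
        f_interaction=f_i,
        df_class=(df_c, df_resid),
        df_group=(df_g, df_resid),
        df_interaction=(df_i, df_resid),
        p_class=p_c,
        p_group=p_g,
        p_interaction=p_i,
        n_effective=n_eff,
        n_cells=int((cell_counts > 0).sum()),
    )


def adjust_for_sample_size(result: AnovaResult, n_adjusted: int = 960) -> AnovaResult:
    """Scale test statistics to a nominal analysis sample size.

    When the effective n exceeds ``n_adjusted`` each F statistic is multiplied
    by ``n_adjusted / n_effective`` (numerator df unchanged, denominator df
    recomputed from the adjusted n) before p-values are evaluated; smaller
    samples pass through unchanged.  Raw values are always retained, and the
    adjustment can only weaken significance, never create it.
    """
    if result.n_cells and n_adjusted < result.n_cells:
        raise ValueError(
            f"n_adjusted={n_adjusted} smaller than the {result.n_cells} design cells"
        )
    out = replace(result, n_adjusted=n_adjusted)
    if result.n_effective <= n_adjusted:
        for eff in ("class", "group", "interaction"):
            setattr(out, f"f_{eff}_adj", getattr(result, f"f_{eff}"))
            setattr(out, f"p_{eff}_adj", getattr(result, f"p_{eff}"))
        return out
    scale = n_adjusted / result.n_effective
    for eff in ("class", "group", "interaction"):
        f_raw = getattr(result, f"f_{eff}")
        df1 = getattr(result, f"df_{eff}")[0]
        if not np.isfinite(f_raw):
            continue
        f_adj = f_raw * scale
        df2_adj = max(n_adjusted - result.n_cells, 1)
        p_adj = float(scipy.stats.f.sf(f_adj, df1, df2_adj))
        setattr(out, f"f_{eff}_adj", f_adj)
        setattr(out, f"p_{eff}_adj", p_adj)
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance level alpha / n_tests (reported to 6 decimals)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def count_dif_tests(results: list[AnovaResult]) -> int:
    """Number of tests for the Bonferroni divisor.

    Three tests (class, group, interaction) per ordinary two-group item; one
    test (class-interval fit only) per resolved single-group item copy.
    """
    n = 0
    for r in results:
        n += 3 if r.group_restriction == "all" else 1
    return n


def rank_dif_items(
    results: list[AnovaResult], threshold: float
) -> list[AnovaResult]:
    """Items flagged for DIF, worst first.

    An item is flagged when its group or interaction p-value (sample-size
    adjusted when available) falls below ``threshold``.  Ranked by descending
    group-effect F, interaction F as secondary key, original item order as
    the deterministic tie-break.  Resolved copies carry no group test and are
    never flagged.
    """
    flagged = []
    for pos, r in enumerate(results):
        if r.group_restriction != "all":
            continue
        p_g = r.effective_p("group")
        p_i = r.effective_p("interaction")
        if (np.isfinite(p_g) and p_g < threshold) or (
            np.isfinite(p_i) and p_i < threshold
        ):
            key_g = r.effective_f("group")
            key_i = r.effective_f("interaction")
            flagged.append(
                (
                    -(key_g if np.isfinite(key_g) else -np.inf),
                    -(key_i if np.isfinite(key_i) else -np.inf),
                    pos,
                    r,
                )
            )
    flagged.sort(key=lambda t: t[:3])
    return [t[3] for t in flagged]


# ---------------------------------------------------------------------------
# One full detection pass
# ---------------------------------------------------------------------------


@dataclass
class DifAnalysis:
    """Result of one detection pass: per-item ANOVA plus caption metadata."""

    results: list[AnovaResult]
    assignment: ClassIntervalAssignment
    n_tests: int
    alpha: float
    threshold: float
    n_adjusted: int
    flagged: list[AnovaResult]


def dif_analysis(
    responses: ResponseMatrix,
    items: ItemParameterSet,
    persons: PersonEstimates,
    n_intervals: int = 10,
    n_adjusted: int = 960,
    alpha: float = 0.05,
) -> DifAnalysis:
    """Residuals -> class intervals -> per-item ANOVA -> Bonferroni flags."""
    resid = standardized_residuals(responses, items, persons)
    assignment = assign_class_intervals(persons, n_intervals)
    results = []
    for j, it in enumerate(responses.items):
        res = dif_anova_item(
            resid.z[:, j],
            assignment,
            persons.group,
            item_id=it.item_id,
            group_restriction=it.group_restriction,
        )
        res = adjust_for_sample_size(res, n_adjusted)
        results.append(res)
    n_tests = count_dif_tests(results)
    threshold = bonferroni_threshold(alpha, n_tests)
    flagged = rank_dif_items(results, threshold)
    return DifAnalysis(
        results=results,
        assignment=assignment,
        n_tests=n_tests,
        alpha=alpha,
        threshold=threshold,
        n_adjusted=n_adjusted,
        flagged=flagged,
    )


def anova_results_frame(analysis: DifAnalysis) -> pd.DataFrame:
    """Tabular report of a detection pass (one row per item).

    Mirrors the classic report layout: F and p for class interval, group and
    group-by-class effects, with the caption metadata (interval count,
    adjusted sample size, Bonferroni level) as frame attrs.
    """
    rows = []
    for r in analysis.results:
        rows.append(
            {
                "item": r.item_id,
                "group_restriction": r.group_restriction,
                "F_class": r.effective_f("class"),
                "F_group": r.effective_f("group"),
                "F_interaction": r.effective_f("interaction"),
                "p_class": r.effective_p("class"),
                "p_group": r.effective_p("group"),
                "p_interaction": r.effective_p("interaction"),
                "F_class_raw": r.f_class,
                "F_group_raw": r.f_group,
                "F_interaction_raw": r.f_interaction,
                "n_effective": r.n_effective,
                "flagged": r in analysis.flagged,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["n_intervals"] = analysis.assignment.n_intervals
    frame.attrs["n_adjusted"] = analysis.n_adjusted
    frame.attrs["bonferroni_level"] = round(analysis.threshold, 6)
    frame.attrs["n_tests"] = analysis.n_tests
    return frame
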