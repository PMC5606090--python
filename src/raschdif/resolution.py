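"""Sequential resolution of DIF items and quantification of DIF magnitude.

Real DIF in one item induces artificial DIF in the others: person estimates
are tied to total scores, so expected scores over the item set must sum to
the total, and a group-wise surplus on one item forces a compensating deficit
spread over the rest.  Resolving all initially flagged items simultaneously
therefore risks splitting items whose apparent DIF is purely artefactual.
The procedure implemented here instead resolves one item at a time — always
the currently worst one — refits the model, and retests, terminating when no
item remains significant at the current Bonferroni level.

Resolving (splitting) an item replaces it with one group-specific copy per
group; each copy holds only that group's responses, and all other groups are
structurally missing on it.  The resolved copies are placed on the common
logit scale through the unresolved items (test equating), and the difference
between the copies' locations / expected-score slopes quantifies uniform /
non-uniform DIF respectively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dif_anova import DifAnalysis, dif_analysis
from .rasch_core import (
    FitConfig,
    ItemDef,
    ItemParameterSet,
    PersonEstimates,
    ResponseMatrix,
    _moments_grid,
    estimate_persons,
    fit_items,
)

logger = logging.getLogger("raschdif")

__all__ = [
    "ResolutionStep",
    "ResolutionTrace",
    "DifMagnitude",
    "resolve_item",
    "merge_resolved_item",
    "sequential_resolution",
    "dif_magnitude",
    "resolved_copy_id",
]


def resolved_copy_id(item_id: str, group) -> str:
    return f"{item_id}::{group}"


# ---------------------------------------------------------------------------
# Item splitting
# ---------------------------------------------------------------------------


def resolve_item(responses: ResponseMatrix, item_id: str, groups=None) -> ResponseMatrix:
    """Split one item into group-specific copies.

    The original column is replaced by one copy per group; a copy holds the
    responses of its group only, every other group's cells being structurally
    missing.  Non-missing responses are conserved exactly and all other items
    are untouched.  A group with zero responses on the item gets no copy
    (warned).
    """
    j = responses.item_index(item_id)
    it = responses.items[j]
    if it.group_restriction != "all":
        raise ValueError(f"item {item_id!r} is already resolved")
    if groups is None:
        groups = responses.groups()
    if len(groups) < 2:
        raise ValueError("resolution requires at least 2 groups")

    new_items = list(responses.items[:j])
    new_cols = [responses.scores[:, :j]]
    new_struct = [responses.structural[:, :j]]
    for g in groups:
        in_group = responses.group == g
        col = np.full(responses.n_persons, np.nan)
        col[in_group] = responses.scores[in_group, j]
        if np.isnan(col).all() or not responses.answered[in_group, j].any():
            warnings.warn(
                f"item {item_id!r}: group {g!r} has no responses; copy dropped",
                stacklevel=2,
            )
            continue
        struct = ~in_group  # other groups: structurally missing by design
        new_items.append(
            ItemDef(
                item_id=resolved_copy_id(item_id, g),
                max_score=it.max_score,
                group_restriction=str(g),
            )
        )
        new_cols.append(col[:, None])
        new_struct.append(struct[:, None])
    new_items.extend(responses.items[j + 1 :])
    new_cols.append(responses.scores[:, j + 1 :])
    new_struct.append(responses.structural[:, j + 1 :])

    return ResponseMatrix(
        person_ids=responses.person_ids.copy(),
        group=responses.group.copy(),
        scores=np.hstack(new_cols),
        items=new_items,
        structural=np.hstack(new_struct),
    )


def merge_resolved_item(responses: ResponseMatrix, item_id: str) -> ResponseMatrix:
    """Undo :func:`resolve_item`: recombine the copies into the original column."""
    prefix = f"{item_id}::"
    copy_idx = [
        k for k, it in enumerate(responses.items) if it.item_id.startswith(prefix)
    ]
    if not copy_idx:
        raise KeyError(f"no resolved copies of {item_id!r}")
    first = copy_idx[0]
    max_score = responses.items[first].max_score
    merged = np.full(responses.n_persons, np.nan)
    for k in copy_idx:
        obs = responses.answered[:, k]
        merged[obs] = responses.scores[obs, k]
    keep = [k for k in range(responses.n_items) if k not in copy_idx]
    items = [responses.items[k] for k in keep]
    items.insert(first, ItemDef(item_id=item_id, max_score=max_score))
    scores = responses.scores[:, keep]
    scores = np.insert(scores, first, merged, axis=1)
    struct = responses.structural[:, keep]
    struct = np.insert(struct, first, np.isnan(merged), axis=1)
    struct[:, first] = False
    return ResponseMatrix(
        person_ids=responses.person_ids.copy(),
        group=responses.group.copy(),
        scores=scores,
        items=items,
        structural=struct,
    )


# ---------------------------------------------------------------------------
# Sequential procedure
# ---------------------------------------------------------------------------


@dataclass
class ResolutionStep:
    """One iteration of the detect-resolve loop."""

    step: int
    analysis: DifAnalysis
    item_resolved: str | None  # None on the terminating pass
    f_group_at_resolution: float
    item_ids_after: list[str]
    items: ItemParameterSet = None
    persons: PersonEstimates = None


@dataclass
class ResolutionTrace:
    """Ordered record of the sequential resolve-refit-retest procedure."""

    steps: list[ResolutionStep] = field(default_factory=list)
    final_responses: ResponseMatrix = None
    final_items: ItemParameterSet = None
    final_persons: PersonEstimates = None
    converged: bool = True
    statistical_only: bool = True  # resolution on statistical criteria alone

    @property
    def resolved_items(self) -> list[str]:
        return [s.item_resolved for s in self.steps if s.item_resolved is not None]

    @property
    def initial_flags(self) -> list[str]:
        """Items flagged on the first pass (the simultaneous-resolution list)."""
        if not self.steps:
            return []
        return [r.item_id for r in self.steps[0].analysis.flagged]


@dataclass
class DifMagnitude:
    """Size of uniform and non-uniform DIF from a resolved item's copies.

    ``delta_location`` (logits) is the location difference between the two
    group copies — uniform DIF.  ``delta_slope`` is the difference of the
    expected-score slopes dE/dbeta (= model variance, by the Rasch identity)
    at a reference location — non-uniform DIF.  Wald z statistics use
    composite-likelihood curvature SEs.
    """

    item_id: str
    group_a: str
    group_b: str
    delta_location: float
    se_delta_location: float
    delta_slope: float
    se_delta_slope: float
    reference_location: float

    @property
    def z_location(self) -> float:
        return self.delta_location / self.se_delta_location

    @property
    def z_slope(self) -> float:
        return self.delta_slope / self.se_delta_slope


def _fit_and_estimate(responses, fit_config, person_method):
    items = fit_items(responses, fit_config)
    persons = estimate_persons(responses, items, method=person_method)
    return items, persons


def sequential_resolution(
    responses: ResponseMatrix,
    n_intervals: int = 10,
    n_adjusted: int = 960,
    alpha: float = 0.05,
    max_steps: int | None = None,
    fit_config: FitConfig | None = None,
    person_method: str = "wle",
) -> ResolutionTrace:
    """Run the full detect-resolve loop until no item shows significant DIF.

    Each pass refits the model on the current item roster, re-estimates
    persons, recomputes residual ANOVAs and the Bonferroni level for the
    current number of tests, and resolves the top-ranked significant item
    (largest group-effect F; ties broken by item order).  Terminates when no
    ordinary item is significant for group or interaction, or when every
    original item has been resolved.  The returned trace records every pass.
    """
    groups = responses.groups()
    if len(groups) < 2:
        raise ValueError("DIF analysis requires at least 2 groups")
    trace = ResolutionTrace()
    current = responses
    n_resolvable = sum(1 for it in responses.items if it.group_restriction == "all")
    if max_steps is None:
        max_steps = n_resolvable
    step = 0
    while True:
        try:
            items, persons = _fit_and_estimate(current, fit_config, person_method)
        except Exception as exc:  # non-convergence: return partial trace
            logger.error("refit failed at step %d: %s", step, exc)
            trace.converged = False
            trace.final_responses = current
            return trace
        analysis = dif_analysis(
            current, items, persons, n_intervals=n_intervals,
            n_adjusted=n_adjusted, alpha=alpha,
        )
        if not analysis.flagged or step >= max_steps:
            trace.steps.append(
                ResolutionStep(
                    step=step,
                    analysis=analysis,
                    item_resolved=None,
                    f_group_at_resolution=np.nan,
                    item_ids_after=current.item_ids,
                    items=items,
                    persons=persons,
                )
            )
            break
        worst = analysis.flagged[0]
        logger.info(
            "step %d: resolving %s (group F = %.3f)",
            step,
            worst.item_id,
            worst.effective_f("group"),
        )
        current = resolve_item(current, worst.item_id, groups)
        trace.steps.append(
            ResolutionStep(
                step=step,
                analysis=analysis,
                item_resolved=worst.item_id,
                f_group_at_resolution=worst.effective_f("group"),
                item_ids_after=current.item_ids,
                items=items,
                persons=persons,
            )
        )
        step += 1
    trace.final_responses = current
    trace.final_items = trace.steps[-1].items
    trace.final_persons = trace.steps[-1].persons
    return trace


# ---------------------------------------------------------------------------
# DIF magnitude
# ---------------------------------------------------------------------------


def dif_magnitude(
    items: ItemParameterSet,
    item_id: str,
    reference_location: float,
    group_a=None,
    group_b=None,
) -> DifMagnitude:
    """Quantify uniform and non-uniform DIF from a resolved item's two copies.

    delta_location = location(copy A) - location(copy B); delta_slope =
    V_A(ref) - V_B(ref) via the dE/dbeta = V identity.  Copy order follows
    the fitted item roster unless groups are named explicitly.
    """
    prefix = f"{item_id}::"
    copies = [it for it in items.items if it.item_id.startswith(prefix)]
    if group_a is not None:
        order = [str(group_a), str(group_b)]
        copies = sorted(
            copies, key=lambda it: order.index(it.group_restriction)
            if it.group_restriction in order else len(order)
        )
    if len(copies) < 2:
        raise ValueError(f"item {item_id!r}: need two estimated copies, found {len(copies)}")
    a, b = copies[0], copies[1]
    d_loc = a.location - b.location

    cov = items.theta_cov
    maps = items.theta_maps or {}
    se_loc = np.nan
    se_slope = np.nan
    if cov is not None and a.item_id in maps and b.item_id in maps:
        ca = maps[a.item_id][0]
        cb = maps[b.item_id][0]
        contrast = ca - cb
        se_loc = float(np.sqrt(max(contrast @ cov @ contrast, 0.0)))

    def slope(it):
        return _moments_grid(it, np.array([reference_location]))[1][0]

    d_slope = float(slope(a) - slope(b))

    if cov is not None and a.item_id in maps and b.item_id in maps:
        # delta-method gradient of V(ref) w.r.t. (delta, tau) per copy
        def grad_v(it):
            eps = 1e-5
            g = np.zeros(it.max_score + 1)
            for q in range(it.max_score + 1):
                up = _perturbed(it, q, eps)
                dn = _perturbed(it, q, -eps)
                g[q] = (slope(up) - slope(dn)) / (2 * eps)
            return g

        ga = grad_v(a) @ maps[a.item_id]
        gb = grad_v(b) @ maps[b.item_id]
        gv = ga - gb
        se_slope = float(np.sqrt(max(gv @ cov @ gv, 0.0)))

    return DifMagnitude(
        item_id=item_id,
        group_a=a.group_restriction,
        group_b=b.group_restriction,
        delta_location=d_loc,
        se_delta_location=se_loc,
        delta_slope=d_slope,
        se_delta_slope=se_slope,
        reference_location=reference_location,
    )


def _perturbed(item, q, eps):
    """Copy of an item with parameter q of (delta, tau_1..tau_m) nudged by eps."""
    from dataclasses import replace

    if q == 0:
        return replace(item, location=item.location + eps)
    tau = item.thresholds.copy()
    tau[q - 1] += eps
    return replace(item, thresholds=tau)
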