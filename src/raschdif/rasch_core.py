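"""Polytomous Rasch (partial credit) model: estimation and model curves.

The partial credit model (PCM) gives the probability that person ``n`` with
latent location ``beta_n`` scores ``k`` on item ``i`` with location ``delta_i``
and centred thresholds ``tau_i1..tau_im`` (sum zero) as

    P(X_ni = k) = exp( sum_{h<=k} (beta_n - delta_i - tau_ih) ) / gamma_ni

where the empty sum for ``k = 0`` is zero and ``gamma_ni`` normalises over the
categories ``0..m_i``.  Person and item parameters enter additively on a
common logit scale, which is what permits separate (person-distribution-free)
estimation of the item parameters and equating across structurally missing
designs.

Item parameters are estimated by pairwise conditional maximum likelihood:
for every pair of items, conditioning on the pair's total score removes the
person parameter, leaving a likelihood in item parameters only.  This is the
estimation principle behind classic Rasch software and it accommodates
structurally missing responses (a pair contributes only the persons who
answered both items), which is exactly what resolved, group-restricted item
copies produce.

Person locations are estimated afterwards by Warm's weighted maximum
likelihood (WLE) or plain ML on each person's answered items; persons with
minimum or maximum possible total score carry no finite ML estimate and are
flagged extreme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp

logger = logging.getLogger("raschdif")

__all__ = [
    "InvalidParameterError",
    "EquatingError",
    "ItemDef",
    "ResponseMatrix",
    "ItemParameters",
    "ItemParameterSet",
    "PersonEstimates",
    "EvcPoints",
    "FitConfig",
    "pcm_category_probabilities",
    "score_moments",
    "fit_items",
    "estimate_persons",
    "evc",
    "check_connectivity",
]


class InvalidParameterError(ValueError):
    """Raised when item or person parameters are non-finite or malformed."""


class EquatingError(RuntimeError):
    """Raised when the response design is disconnected and cannot be equated."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemDef:
    """Identity and scoring range of one item column.

    ``group_restriction`` is ``"all"`` for an ordinary item; a resolved,
    group-specific copy carries the label of the single group whose responses
    it holds (all other groups are structurally missing on it).
    """

    item_id: str
    max_score: int
    group_restriction: str = "all"

    def __post_init__(self) -> None:
        if self.max_score < 1:
            raise InvalidParameterError(
                f"item {self.item_id!r}: max_score must be >= 1, got {self.max_score}"
            )


@dataclass
class ResponseMatrix:
    """Persons x items ordinal scores with missingness and group labels.

    ``scores`` is a float matrix with ``NaN`` for missing cells; ``structural``
    marks which missing cells are structural (by design, e.g. resolved item
    copies) rather than incidental non-response.
    """

    person_ids: np.ndarray
    group: np.ndarray
    scores: np.ndarray
    items: list[ItemDef]
    structural: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.person_ids = np.asarray(self.person_ids, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D persons x items matrix")
        n, ni = self.scores.shape
        if len(self.person_ids) != n or len(self.group) != n:
            raise ValueError("person_ids/group length does not match scores rows")
        if len(self.items) != ni:
            raise ValueError("items length does not match scores columns")
        if self.structural is None:
            self.structural = np.zeros_like(self.scores, dtype=bool)
        self.structural = np.asarray(self.structural, dtype=bool)
        if self.structural.shape != self.scores.shape:
            raise ValueError("structural mask shape mismatch")
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item {item_id!r}") from None

    @property
    def answered(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return ~np.isnan(self.scores)

    def groups(self) -> list:
        seen: dict = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def validate(self) -> None:
        ans = self.answered
        for j, it in enumerate(self.items):
            col = self.scores[ans[:, j], j]
            if col.size == 0:
                continue
            if not np.all(np.isfinite(col)):
                raise ValueError(f"item {it.item_id!r}: non-finite scores")
            if np.any(col != np.round(col)):
                raise ValueError(f"item {it.item_id!r}: non-integer scores")
            if col.min() < 0 or col.max() > it.max_score:
                raise ValueError(
                    f"item {it.item_id!r}: scores outside [0, {it.max_score}]"
                )

    def drop_unanswered_persons(self) -> "ResponseMatrix":
        """Return a copy without persons that answered zero items (warns)."""
        keep = self.answered.any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(
                f"excluding {n_drop} person(s) with no non-missing responses",
                stacklevel=2,
            )
            logger.warning("excluded %d person(s) with no responses", n_drop)
        if keep.all():
            return self
        return ResponseMatrix(
            person_ids=self.person_ids[keep],
            group=self.group[keep],
            scores=self.scores[keep],
            items=list(self.items),
            structural=self.structural[keep],
        )

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            person_ids=self.person_ids.copy(),
            group=self.group.copy(),
            scores=self.scores.copy(),
            items=list(self.items),
            structural=self.structural.copy(),
        )


@dataclass
class ItemParameters:
    """Parameters of one item: location (mean threshold) and centred thresholds."""

    item_id: str
    max_score: int
    location: float
    thresholds: np.ndarray  # centred: sum == 0
    group_restriction: str = "all"
    se_location: float = np.nan

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (self.max_score,):
            raise InvalidParameterError(
                f"item {self.item_id!r}: expected {self.max_score} thresholds"
            )

    @property
    def disordered(self) -> bool:
        """True when the Andrich thresholds are not ascending (reported, never fixed)."""
        return bool(np.any(np.diff(self.thresholds) < 0))


@dataclass
class ItemParameterSet:
    """A fitted, jointly identified set of item parameters.

    Identification: item locations sum to zero over the anchored set and
    thresholds are centred per item.  Carries convergence diagnostics and the
    free-parameter covariance needed for Wald tests on parameter contrasts.
    """

    items: list[ItemParameters]
    converged: bool = True
    n_iter: int = 0
    max_grad: float = np.nan
    theta_cov: np.ndarray | None = None
    theta_maps: dict | None = None  # item_id -> (m+1) x p matrix mapping theta to (delta, tau)

    def __getitem__(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"unknown item {item_id!r}")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def locations(self) -> np.ndarray:
        return np.array([it.location for it in self.items])


@dataclass
class PersonEstimates:
    """Per-person latent locations on the common logit scale.

    Extreme persons (minimum or maximum possible score on their answered
    items) have no finite ML location: their ``location``/``se`` are NaN and
    ``extreme`` is set; downstream residual analysis excludes them.
    """

    person_ids: np.ndarray
    group: np.ndarray
    total: np.ndarray
    n_answered: np.ndarray
    location: np.ndarray
    se: np.ndarray
    extreme: np.ndarray
    method: str = "wle"

    def __len__(self) -> int:
        return len(self.person_ids)


@dataclass
class EvcPoints:
    """An expected value curve: E[x] and V[x] on a grid of latent locations."""

    item_id: str
    group_restriction: str
    grid: np.ndarray
    expected: np.ndarray
    variance: np.ndarray
    observed_locations: np.ndarray | None = None
    observed_means: np.ndarray | None = None
    observed_counts: np.ndarray | None = None


@dataclass
class FitConfig:
    """Estimation options for :func:`fit_items`.

    null_category: ``"keep"`` retains never-observed categories (their
    thresholds are only restrained by the optimiser bounds and a warning is
    emitted); ``"collapse"`` removes them by shifting higher scores down.
    """

    max_iter: int = 500
    gtol: float = 1e-6
    null_category: str = "keep"
    bound: float = 30.0
    min_pair_overlap: int = 1
    compute_cov: bool = True


# ---------------------------------------------------------------------------
# PCM probabilities and moments
# ---------------------------------------------------------------------------


def _cumparam(item: ItemParameters) -> np.ndarray:
    """eta_k = sum_{h<=k} (delta + tau_h) for k = 0..m (eta_0 = 0)."""
    m = item.max_score
    eta = np.concatenate([[0.0], np.cumsum(item.location + item.thresholds)])
    assert eta.shape == (m + 1,)
    return eta


def pcm_category_probabilities(location: float, item: ItemParameters) -> np.ndarray:
    """Category probabilities P(X = k), k = 0..m, under the PCM.

    ``location`` is the person position beta in logits.  Thresholds are used
    exactly as given; disordered thresholds are legal and never reordered.
    """
    if not np.isfinite(location):
        raise InvalidParameterError("person location must be finite")
    if not np.all(np.isfinite(item.thresholds)) or not np.isfinite(item.location):
        raise InvalidParameterError(f"item {item.item_id!r}: non-finite parameters")
    k = np.arange(item.max_score + 1)
    logw = k * location - _cumparam(item)
    logw -= logsumexp(logw)
    return np.exp(logw)


def score_moments(location: float, item: ItemParameters) -> tuple[float, float]:
    """Expected score E[x] and model variance V[x] at a person location."""
    p = pcm_category_probabilities(location, item)
    k = np.arange(item.max_score + 1)
    e = float(k @ p)
    v = float((k**2) @ p - e**2)
    return e, v


def _moments_grid(item: ItemParameters, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised E and V over an array of person locations."""
    beta = np.asarray(beta, dtype=float)
    k = np.arange(item.max_score + 1)
    logw = np.outer(beta, k) - _cumparam(item)[None, :]
    logw -= logsumexp(logw, axis=1, keepdims=True)
    p = np.exp(logw)
    e = p @ k
    v = p @ (k**2) - e**2
    return e, v


def _third_central_moment_grid(item: ItemParameters, beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    k = np.arange(item.max_score + 1)
    logw = np.outer(beta, k) - _cumparam(item)[None, :]
    logw -= logsumexp(logw, axis=1, keepdims=True)
    p = np.exp(logw)
    e = p @ k
    return np.einsum("nk,nk->n", p, (k[None, :] - e[:, None]) ** 3)


# ---------------------------------------------------------------------------
# Design connectivity (equating feasibility)
# ---------------------------------------------------------------------------


def check_connectivity(responses: ResponseMatrix, min_overlap: int = 1) -> None:
    """Verify all items are linked through persons answering common items.

    Two items are linked when at least ``min_overlap`` persons answered both.
    A disconnected design cannot be equated onto one logit scale; the raised
    :class:`EquatingError` names the disconnected item blocks.
    """
    ans = responses.answered
    overlap = ans.T.astype(int) @ ans.astype(int)
    g = nx.Graph()
    g.add_nodes_from(range(responses.n_items))
    for i in range(responses.n_items):
        for j in range(i + 1, responses.n_items):
            if overlap[i, j] >= min_overlap:
                g.add_edge(i, j)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        blocks = [
            sorted(responses.items[j].item_id for j in comp) for comp in comps
        ]
        raise EquatingError(
            "response design is disconnected; equating impossible between item "
            f"blocks: {blocks}"
        )


# ---------------------------------------------------------------------------
# Pairwise conditional likelihood fitting
# ---------------------------------------------------------------------------


def _free_param_layout(items: list[ItemDef]):
    """Free parameter vector layout and the linear map theta -> eta.

    theta = (delta_1..delta_{I-1}, tau_{1,1..m1-1}, tau_{2,1..m2-1}, ...)
    with delta_I = -sum(others) and tau_{i,mi} = -sum(others): locations sum
    to zero across the set and thresholds are centred per item.

    Returns (p, eta_index, A) where eta is the stacked vector of
    eta_{i,k}, k = 1..m_i over items, and eta = A @ theta.
    """
    n_items = len(items)
    ms = [it.max_score for it in items]
    p = (n_items - 1) + sum(m - 1 for m in ms)
    eta_rows = sum(ms)
    A = np.zeros((eta_rows, p))
    # column offsets
    delta_cols = list(range(n_items - 1))
    tau_off = []
    off = n_items - 1
    for m in ms:
        tau_off.append(off)
        off += m - 1
    eta_index = {}  # item pos -> slice into eta rows
    row = 0
    for i, m in enumerate(ms):
        eta_index[i] = slice(row, row + m)
        for k in range(1, m + 1):
            r = row + k - 1
            # delta contribution: k * delta_i
            if i < n_items - 1:
                A[r, delta_cols[i]] = k
            else:
                for c in delta_cols:
                    A[r, c] = -k
            # cumulative tau contribution: sum_{h<=k} tau_ih ;
            # tau_im = -sum of free ones so cum at k=m is 0
            if k < m:
                for h in range(k):
                    A[r, tau_off[i] + h] = 1.0
        row += m
    return p, eta_index, A


def _pair_counts(responses: ResponseMatrix, min_overlap: int):
    """Contingency tables N[k, l] for each item pair with joint observations."""
    ans = responses.answered
    pairs = []
    for i in range(responses.n_items):
        for j in range(i + 1, responses.n_items):
            both = ans[:, i] & ans[:, j]
            if both.sum() < max(min_overlap, 1):
                continue
            mi = responses.items[i].max_score
            mj = responses.items[j].max_score
            xi = responses.scores[both, i].astype(int)
            xj = responses.scores[both, j].astype(int)
            tab = np.zeros((mi + 1, mj + 1))
            np.add.at(tab, (xi, xj), 1.0)
            pairs.append((i, j, tab))
    return pairs


_DIAG_CACHE: dict = {}


def _diag_masks(mi: int, mj: int):
    """Boolean anti-diagonal masks of the (mi+1) x (mj+1) cell grid, cached."""
    key = (mi, mj)
    if key not in _DIAG_CACHE:
        tot = np.arange(mi + 1)[:, None] + np.arange(mj + 1)[None, :]
        _DIAG_CACHE[key] = [tot == t for t in range(mi + mj + 1)]
    return _DIAG_CACHE[key]


def _pairwise_nll_grad(eta: np.ndarray, eta_index, pairs):
    """Negative pairwise conditional log-likelihood and its gradient in eta.

    For each item pair, conditioning on the pair total score t leaves
    P(x_i = k | t) free of the person parameter; the gradient in eta is the
    observed minus expected category margin per item.
    """
    nll = 0.0
    grad = np.zeros_like(eta)
    for i, j, tab in pairs:
        ei = eta[eta_index[i]]
        ej = eta[eta_index[j]]
        mi = len(ei)
        mj = len(ej)
        logw = np.concatenate([[0.0], -ei])[:, None] + np.concatenate([[0.0], -ej])[None, :]
        expect = np.zeros_like(logw)
        for t, mask in enumerate(_diag_masks(mi, mj)):
            cells = logw[mask]
            w_t = tab[mask].sum()
            mx = cells.max()
            ez = np.exp(cells - mx)
            z = ez.sum()
            lz = mx + np.log(z)
            nll -= float((tab[mask] * (cells - lz)).sum())
            if w_t > 0:
                expect[mask] = ez / z * w_t
        # d nll / d eta_{i,k} = observed margin - expected margin, k >= 1
        grad[eta_index[i]] += (tab.sum(axis=1) - expect.sum(axis=1))[1:]
        grad[eta_index[j]] += (tab.sum(axis=0) - expect.sum(axis=0))[1:]
    return nll, grad


def _collapse_null_categories(responses: ResponseMatrix) -> ResponseMatrix:
    """Remove never-observed categories by shifting higher scores down."""
    out = responses.copy()
    new_items = []
    for j, it in enumerate(out.items):
        col = out.scores[:, j]
        obs = col[~np.isnan(col)].astype(int)
        counts = np.bincount(obs, minlength=it.max_score + 1)
        if np.all(counts > 0):
            new_items.append(it)
            continue
        keep = np.flatnonzero(counts > 0)
        remap = {int(old): rank for rank, old in enumerate(keep)}
        logger.warning(
            "item %s: collapsing %d null categor(ies)",
            it.item_id,
            it.max_score + 1 - len(keep),
        )
        mask = ~np.isnan(col)
        col[mask] = [remap[int(v)] for v in col[mask]]
        new_items.append(replace(it, max_score=len(keep) - 1))
    out.items = new_items
    return out


def fit_items(
    responses: ResponseMatrix, config: FitConfig | None = None
) -> ItemParameterSet:
    """Estimate PCM item parameters by pairwise conditional maximum likelihood.

    The design must be connected (see :func:`check_connectivity`); locations
    are identified by summing to zero over the fitted set.  Returns parameter
    standard errors from the inverse curvature of the pairwise objective —
    adequate for Wald-type DIF contrasts, documented as composite-likelihood
    approximations.
    """
    cfg = config or FitConfig()
    if responses.n_items < 2:
        raise ValueError("need at least 2 items to fit")
    responses = responses.drop_unanswered_persons()
    check_connectivity(responses, cfg.min_pair_overlap)

    # null categories
    has_null = False
    for j, it in enumerate(responses.items):
        col = responses.scores[:, j]
        obs = col[~np.isnan(col)].astype(int)
        counts = np.bincount(obs, minlength=it.max_score + 1)
        if np.any(counts == 0):
            has_null = True
            warnings.warn(
                f"item {it.item_id!r}: categories {np.flatnonzero(counts == 0).tolist()} "
                "observed 0 times",
                stacklevel=2,
            )
    if has_null and cfg.null_category == "collapse":
        responses = _collapse_null_categories(responses)

    p, eta_index, A = _free_param_layout(responses.items)
    pairs = _pair_counts(responses, cfg.min_pair_overlap)

    def objective(theta):
        eta = A @ theta
        nll, grad_eta = _pairwise_nll_grad(eta, eta_index, pairs)
        return nll, A.T @ grad_eta

    theta0 = np.zeros(p)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(-cfg.bound, cfg.bound)] * p,
        options={"maxiter": cfg.max_iter, "gtol": cfg.gtol, "ftol": 1e-12},
    )
    max_grad = float(np.max(np.abs(res.jac)))
    logger.info(
        "fit_items: %d iterations, max|grad| = %.3g, converged = %s",
        res.nit,
        max_grad,
        res.success,
    )
    if not res.success and max_grad > 1e-3:
        warnings.warn(
            f"item fit did not fully converge (max|grad| = {max_grad:.3g})",
            stacklevel=2,
        )

    theta = res.x
    theta_cov = None
    if cfg.compute_cov:
        # curvature-based covariance (finite difference of analytic gradient)
        h = 1e-5
        H = np.zeros((p, p))
        for a in range(p):
            tp = theta.copy()
            tp[a] += h
            tm = theta.copy()
            tm[a] -= h
            _, gp = objective(tp)
            _, gm = objective(tm)
            H[:, a] = (gp - gm) / (2 * h)
        H = (H + H.T) / 2
        theta_cov = np.linalg.pinv(H)

    eta = A @ theta
    items_out = []
    theta_maps = {}
    n_items = responses.n_items
    for i, it in enumerate(responses.items):
        m = it.max_score
        e = eta[eta_index[i]]
        step = np.diff(np.concatenate([[0.0], e]))  # delta + tau_k
        delta = float(step.mean())
        tau = step - delta
        # linear map theta -> (delta, tau_1..tau_m) for delta-method SEs
        Ai = A[eta_index[i]]  # m x p ; rows are cumulative sums
        steps_map = np.diff(np.vstack([np.zeros(p), Ai]), axis=0)  # m x p
        Mi = np.vstack([steps_map.mean(axis=0), steps_map - steps_map.mean(axis=0)])
        theta_maps[it.item_id] = Mi
        se_loc = (
            float(np.sqrt(max(Mi[0] @ theta_cov @ Mi[0], 0.0)))
            if theta_cov is not None
            else np.nan
        )
        items_out.append(
            ItemParameters(
                item_id=it.item_id,
                max_score=m,
                location=delta,
                thresholds=tau,
                group_restriction=it.group_restriction,
                se_location=se_loc,
            )
        )
        if items_out[-1].disordered:
            logger.info("item %s: disordered thresholds (reported, not reordered)", it.item_id)
    assert abs(sum(x.location for x in items_out)) < 1e-6 * max(1, n_items)
    return ItemParameterSet(
        items=items_out,
        converged=bool(res.success),
        n_iter=int(res.nit),
        max_grad=max_grad,
        theta_cov=theta_cov,
        theta_maps=theta_maps,
    )


# ---------------------------------------------------------------------------
# Person estimation
# ---------------------------------------------------------------------------


def _solve_person(item_list: list[ItemParameters], r: int, method: str) -> tuple[float, float]:
    """Solve the (weighted) likelihood equation for one total score r."""

    def score_fn(beta):
        b = np.array([beta])
        e = 0.0
        v = 0.0
        mu3 = 0.0
        for it in item_list:
            ei, vi = _moments_grid(it, b)
            e += ei[0]
            v += vi[0]
            if method == "wle":
                mu3 += _third_central_moment_grid(it, b)[0]
        s = r - e
        if method == "wle":
            s += mu3 / (2.0 * v)
        return s, v

    lo, hi = -12.0, 12.0
    f = lambda b: score_fn(b)[0]
    flo, fhi = f(lo), f(hi)
    tries = 0
    while flo * fhi > 0 and tries < 5:
        lo -= 8
        hi += 8
        flo, fhi = f(lo), f(hi)
        tries += 1
    beta = brentq(f, lo, hi, xtol=1e-10)
    info = score_fn(beta)[1]
    return float(beta), float(1.0 / np.sqrt(info))


def estimate_persons(
    responses: ResponseMatrix,
    items: ItemParameterSet,
    method: str = "wle",
) -> PersonEstimates:
    """Estimate person locations given fitted item parameters.

    ``method="wle"`` (default) applies Warm's bias correction; ``"ml"`` solves
    the plain likelihood equation (used where the exact total-score constraint
    on residuals matters).  Each person's likelihood uses only the items they
    answered; extreme scorers are flagged with NaN location and SE.
    """
    if method not in ("wle", "ml"):
        raise ValueError(f"unknown person estimation method {method!r}")
    by_id = {it.item_id: it for it in items.items}
    ans = responses.answered
    n = responses.n_persons
    total = np.zeros(n)
    n_answered = ans.sum(axis=1)
    location = np.full(n, np.nan)
    se = np.full(n, np.nan)
    extreme = np.zeros(n, dtype=bool)

    if np.any(n_answered == 0):
        warnings.warn(
            f"{int((n_answered == 0).sum())} person(s) answered no items; excluded",
            stacklevel=2,
        )

    max_possible = np.zeros(n)
    for j, it in enumerate(responses.items):
        col = np.nan_to_num(responses.scores[:, j], nan=0.0)
        total += col
        max_possible += ans[:, j] * it.max_score
    total = total.astype(int)

    extreme = (n_answered > 0) & ((total == 0) | (total == max_possible))

    # solve once per (answered item set, total score)
    cache: dict = {}
    keys = [tuple(row) for row in ans]
    for idx in range(n):
        if n_answered[idx] == 0 or extreme[idx]:
            continue
        key = (keys[idx], total[idx])
        if key not in cache:
            item_list = [
                by_id[responses.items[j].item_id]
                for j in np.flatnonzero(ans[idx])
            ]
            cache[key] = _solve_person(item_list, int(total[idx]), method)
        location[idx], se[idx] = cache[key]

    return PersonEstimates(
        person_ids=responses.person_ids.copy(),
        group=responses.group.copy(),
        total=total,
        n_answered=n_answered,
        location=location,
        se=se,
        extreme=extreme,
        method=method,
    )


# ---------------------------------------------------------------------------
# Expected value curves
# ---------------------------------------------------------------------------


def evc(
    item: ItemParameters,
    grid_range: tuple[float, float] = (-5.0, 5.0),
    grid_step: float = 0.1,
    responses: ResponseMatrix | None = None,
    persons: PersonEstimates | None = None,
    assignment=None,
) -> EvcPoints:
    """Expected value curve of an item over a grid of latent locations.

    When ``responses``, ``persons`` and a class-interval ``assignment`` are
    supplied, observed class-interval mean scores are attached as overlay data
    (the mean observed score and mean location of persons in each interval).
    """
    lo, hi = grid_range
    if not (hi > lo) or grid_step <= 0:
        raise ValueError("empty grid: need grid_range[1] > grid_range[0] and step > 0")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    e, v = _moments_grid(item, grid)
    out = EvcPoints(
        item_id=item.item_id,
        group_restriction=item.group_restriction,
        grid=grid,
        expected=e,
        variance=v,
    )
    if responses is not None and persons is not None and assignment is not None:
        j = responses.item_index(item.item_id)
        ok = responses.answered[:, j] & ~persons.extreme & np.isfinite(persons.location)
        iv = assignment.interval
        locs, means, counts = [], [], []
        for c in range(1, assignment.n_intervals + 1):
            sel = ok & (iv == c)
            if sel.sum() == 0:
                continue
            locs.append(persons.location[sel].mean())
            means.append(responses.scores[sel, j].mean())
            counts.append(int(sel.sum()))
        out.observed_locations = np.array(locs)
        out.observed_means = np.array(means)
        out.observed_counts = np.array(counts)
    return out
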