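"""Synthetic polytomous response data with injectable real DIF.

The generator emulates the study design the methodology targets: a short
psychosomatic-problems scale of 8 items scored in 5 ordered frequency
categories (0 = "seldom or never" .. 4 = "about every day"; higher score =
more frequent problems), answered by two groups (e.g. genders) whose latent
locations are normally distributed on the logit scale.

Real DIF is injected at generation time by giving one group its own item
parameters: uniform DIF shifts the favoured group's item location by exactly
``delta`` logits (favoured = scores higher at the same latent location, so
its location is lowered); non-uniform DIF multiplies that group's threshold
spread, tilting the expected value curve.  A group mean offset ("impact") is
a separate dial — genuine group differences on the trait are not DIF and the
pipeline must not mistake one for the other.

Every run is fully determined by its seed, and the design round-trips
through a plain-text (YAML-compatible) dict for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .rasch_core import ItemDef, ItemParameters, ResponseMatrix

__all__ = [
    "DifInjection",
    "SimulationDesign",
    "SimulationTruth",
    "simulate_responses",
    "sweep_artificial_dif",
    "default_design",
]


@dataclass(frozen=True)
class DifInjection:
    """One real-DIF injection: which item, what kind, how large, who benefits."""

    item: str
    kind: str  # "uniform" | "non_uniform"
    delta: float = 0.0  # logit shift of the favoured group's item location
    spread_multiplier: float = 1.0  # threshold-spread factor (non-uniform)
    favoured_group: str = "girls"

    def __post_init__(self):
        if self.kind not in ("uniform", "non_uniform"):
            raise ValueError(f"unknown DIF kind {self.kind!r}")


@dataclass
class SimulationDesign:
    """Complete, seed-determined specification of one synthetic data set."""

    n_per_group: dict = field(default_factory=lambda: {"boys": 1000, "girls": 1000})
    n_items: int = 8
    n_categories: int = 5
    item_locations: np.ndarray | None = None  # default: equispaced, sum 0
    threshold_spread: float = 1.5  # centred thresholds span [-s, s]
    person_mean: dict = field(default_factory=dict)  # per-group latent mean (impact)
    person_sd: float = 1.0
    dif: list[DifInjection] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_categories < 2:
            raise ValueError("need >= 2 categories")
        m = self.n_categories - 1
        if self.item_locations is None:
            # equispaced difficulties centred on zero
            self.item_locations = np.linspace(-1.0, 1.0, self.n_items)
            self.item_locations -= self.item_locations.mean()
        self.item_locations = np.asarray(self.item_locations, dtype=float)
        if len(self.item_locations) != self.n_items:
            raise ValueError("item_locations length mismatch")
        if self.threshold_spread <= 0:
            raise ValueError("threshold_spread must be positive")
        self._m = m

    @property
    def item_ids(self) -> list[str]:
        return [f"item{j + 1}" for j in range(self.n_items)]

    def base_thresholds(self) -> np.ndarray:
        """Centred thresholds, equispaced over [-spread, +spread]."""
        m = self._m
        if m == 1:
            return np.zeros(1)
        return np.linspace(-self.threshold_spread, self.threshold_spread, m)

    def group_item_parameters(self, group: str) -> list[ItemParameters]:
        """True generating parameters as seen by one group (DIF applied)."""
        out = []
        tau0 = self.base_thresholds()
        for j, iid in enumerate(self.item_ids):
            loc = float(self.item_locations[j])
            tau = tau0.copy()
            for inj in self.dif:
                if inj.item != iid:
                    continue
                if inj.kind == "uniform" and group == inj.favoured_group:
                    loc -= inj.delta  # lower location -> higher expected score
                if inj.kind == "non_uniform" and group == inj.favoured_group:
                    tau = tau * inj.spread_multiplier
            out.append(
                ItemParameters(item_id=iid, max_score=self._m, location=loc, thresholds=tau)
            )
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["item_locations"] = [float(v) for v in self.item_locations]
        d.pop("_m", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        d = dict(d)
        d.pop("_m", None)
        if d.get("item_locations") is not None:
            d["item_locations"] = np.asarray(d["item_locations"], dtype=float)
        d["dif"] = [
            inj if isinstance(inj, DifInjection) else DifInjection(**inj)
            for inj in d.get("dif", [])
        ]
        return cls(**d)


@dataclass
class SimulationTruth:
    """Generating parameters serialized alongside the simulated matrix."""

    design: SimulationDesign
    person_locations: np.ndarray
    item_parameters: dict  # group -> list[ItemParameters]


def default_design(**overrides) -> SimulationDesign:
    """The study-scale default: 8 items, 5 categories, two groups of 1000."""
    return SimulationDesign(**overrides)


def simulate_responses(design: SimulationDesign) -> tuple[ResponseMatrix, SimulationTruth]:
    """Draw a response matrix category-wise from group-specific PCM probabilities."""
    rng = np.random.default_rng(design.seed)
    groups = list(design.n_per_group)
    ids, glabels, rows, betas = [], [], [], []
    item_params = {g: design.group_item_parameters(g) for g in groups}
    m = design.n_categories - 1
    counter = 0
    for g in groups:
        n = design.n_per_group[g]
        mu = design.person_mean.get(g, 0.0)
        beta_g = rng.normal(mu, design.person_sd, size=n)
        # per item, vectorised inverse-CDF draws over the category distribution
        block = np.empty((n, design.n_items))
        for j, item in enumerate(item_params[g]):
            k = np.arange(m + 1)
            eta = np.concatenate([[0.0], np.cumsum(item.location + item.thresholds)])
            logw = np.outer(beta_g, k) - eta[None, :]
            logw -= logw.max(axis=1, keepdims=True)
            p = np.exp(logw)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(n)
            block[:, j] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        rows.append(block)
        betas.append(beta_g)
        ids.extend(f"{g}_{counter + i}" for i in range(n))
        counter += n
        glabels.extend([g] * n)
    scores = np.vstack(rows)
    items = [ItemDef(item_id=iid, max_score=m) for iid in design.item_ids]
    matrix = ResponseMatrix(
        person_ids=np.array(ids, dtype=object),
        group=np.array(glabels, dtype=object),
        scores=scores,
        items=items,
    )
    truth = SimulationTruth(
        design=design,
        person_locations=np.concatenate(betas),
        item_parameters=item_params,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Artificial-DIF sweeps
# ---------------------------------------------------------------------------


def sweep_artificial_dif(
    base_design: SimulationDesign,
    deltas=(0.25, 0.5, 1.0),
    n_dif_items=(1,),
    directions=("same",),
    n_items_grid=None,
    n_replicates: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Map how injected real DIF bleeds into the clean items as artificial DIF.

    For each grid point (injected delta, number of DIF items, direction,
    total item count) and replicate, one data set is generated, fitted, and
    put through the residual ANOVA; the summary records per-replicate
    rejection rates for DIF and clean items, the mean group-effect direction
    induced in clean items, and the bias in the group mean difference.
    """
    from .dif_anova import dif_analysis
    from .rasch_core import estimate_persons, fit_items
    from .measures import group_means

    if n_items_grid is None:
        n_items_grid = (base_design.n_items,)
    groups = list(base_design.n_per_group)
    ga, gb = groups[0], groups[1]
    records = []
    rng = np.random.default_rng(base_design.seed)
    for total_items in n_items_grid:
        for delta in deltas:
            for k_dif in n_dif_items:
                for direction in directions:
                    for rep in range(n_replicates):
                        design = SimulationDesign.from_dict(
                            {
                                **base_design.to_dict(),
                                "n_items": total_items,
                                "item_locations": None,
                                "seed": int(rng.integers(2**31 - 1)),
                                "dif": [],
                            }
                        )
                        dif = []
                        for q in range(k_dif):
                            fav = gb if (direction == "same" or q % 2 == 0) else ga
                            dif.append(
                                DifInjection(
                                    item=design.item_ids[q],
                                    kind="uniform",
                                    delta=delta,
                                    favoured_group=fav,
                                )
                            )
                        design.dif = dif
                        matrix, truth = simulate_responses(design)
                        items = fit_items(matrix)
                        persons = estimate_persons(matrix, items)
                        analysis = dif_analysis(matrix, items, persons)
                        dif_ids = {d.item for d in dif}
                        clean_f, clean_rej, dif_rej = [], [], []
                        for r in analysis.results:
                            sig = r.p_group < alpha if np.isfinite(r.p_group) else False
                            if r.item_id in dif_ids:
                                dif_rej.append(sig)
                            else:
                                clean_rej.append(sig)
                                clean_f.append(r.f_group)
                        _, _, d_obs = group_means(persons, ga, gb)
                        mu_a = design.person_mean.get(ga, 0.0)
                        mu_b = design.person_mean.get(gb, 0.0)
                        records.append(
                            {
                                "n_items": total_items,
                                "delta": delta,
                                "n_dif_items": k_dif,
                                "direction": direction,
                                "replicate": rep,
                                "dif_item_rejection": float(np.mean(dif_rej)),
                                "clean_item_rejection": float(np.mean(clean_rej)),
                                "mean_clean_group_f": float(np.mean(clean_f)),
                                "group_mean_bias": d_obs - (mu_a - mu_b),
                            }
                        )
    return pd.DataFrame(records)
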