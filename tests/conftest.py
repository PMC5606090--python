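"""Shared fixtures: small simulated data sets fitted once per session."""

import numpy as np
import pytest

import raschdif as rd


@pytest.fixture(scope="session")
def example_item():
    """5-category item with thresholds (-2, -1, 1, 2) used in hand-checked examples."""
    return rd.ItemParameters(
        item_id="ex", max_score=4, location=0.3, thresholds=np.array([-2.0, -1.0, 1.0, 2.0])
    )


@pytest.fixture(scope="session")
def clean_fit():
    """No-DIF simulated data (two groups of 400) with fitted items and persons."""
    design = rd.SimulationDesign(n_per_group={"boys": 400, "girls": 400}, seed=2024)
    matrix, truth = rd.simulate_responses(design)
    items = rd.fit_items(matrix)
    persons = rd.estimate_persons(matrix, items)
    return matrix, truth, items, persons


@pytest.fixture(scope="session")
def dif_fit():
    """Data with uniform DIF of 0.8 logits injected into item4, favouring girls."""
    design = rd.SimulationDesign(
        n_per_group={"boys": 500, "girls": 500},
        seed=77,
        dif=[
            rd.DifInjection(
                item="item4", kind="uniform", delta=0.8, favoured_group="girls"
            )
        ],
    )
    matrix, truth = rd.simulate_responses(design)
    items = rd.fit_items(matrix)
    persons = rd.estimate_persons(matrix, items)
    return matrix, truth, items, persons


@pytest.fixture(scope="session")
def recovery_fit():
    """Larger no-DIF sample (n = 2000) for parameter-recovery checks."""
    design = rd.SimulationDesign(n_per_group={"boys": 1000, "girls": 1000}, seed=314)
    matrix, truth = rd.simulate_responses(design)
    items = rd.fit_items(matrix, rd.FitConfig(compute_cov=False))
    persons = rd.estimate_persons(matrix, items)
    return matrix, truth, items, persons


def pcm_probs_oracle(beta, location, thresholds):
    """Independent brute-force PCM evaluation via explicit cumulative sums."""
    m = len(thresholds)
    weights = []
    for k in range(m + 1):
        s = 0.0
        for h in range(1, k + 1):
            s += beta - location - thresholds[h - 1]
        weights.append(np.exp(s))
    weights = np.array(weights)
    return weights / weights.sum()
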