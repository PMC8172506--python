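"""Shared fixtures.

The expensive estimation runs (step-1 and step-2 parameter recovery) are
session-scoped so the acceptance tests and module tests share one fit.
"""

from __future__ import annotations

import numpy as np
import pytest

from proirm import estimation, synthetic_data
from proirm.irt_core import category_probabilities
from proirm.scales import DiaryDataset, DiaryRecord


@pytest.fixture(scope="session")
def item_bank():
    return synthetic_data.default_item_bank(seed=1)


@pytest.fixture(scope="session")
def tiny_dataset():
    dataset, _ = synthetic_data.make_fixture("tiny-2x3")
    return dataset


@pytest.fixture(scope="session")
def markov_strong():
    config = synthetic_data.FIXTURES["markov-strong"]()
    dataset, manifest = synthetic_data.generate_trial(config)
    return config, dataset, manifest


@pytest.fixture(scope="session")
def recovery():
    config = synthetic_data.FIXTURES["recovery-40x120"]()
    dataset, manifest = synthetic_data.generate_trial(config)
    return config, dataset, manifest


def draw_occasions(bank, n_base, n_later, mu, omega2, seed):
    """Independent pseudo-occasion data under the step-1 generative model:
    baseline latent N(0,1), later latent N(mu, omega2)."""
    rng = np.random.default_rng(seed)
    records = []
    idx = 0
    for day, n, m, s2 in ((0, n_base, 0.0, 1.0), (1, n_later, mu, omega2)):
        psi = rng.normal(m, np.sqrt(s2), size=n)
        for p in psi:
            responses = {}
            for it in bank:
                probs = category_probabilities(it, float(p))
                responses[it.item_id] = int(rng.choice(len(probs), p=probs))
            records.append(DiaryRecord(f"occ{idx:05d}", "drug", day, responses))
            idx += 1
    return DiaryDataset(records=records)


STEP1_TRUTH = {"mu": 0.4, "omega2": 1.3}


@pytest.fixture(scope="session")
def step1_fit(item_bank):
    """Step-1 fit on 2,000 independent occasions from known item curves."""
    data = draw_occasions(item_bank, 800, 1200, STEP1_TRUTH["mu"], STEP1_TRUTH["omega2"], seed=5)
    fit = estimation.fit_icfs(data, compute_se=True)
    return data, fit


@pytest.fixture(scope="session")
def step2_fit(recovery):
    """Step-2 fit on the recovery-40x120 fixture with item curves fixed at
    truth (the two-step scheme's second stage)."""
    config, dataset, _ = recovery
    fit = estimation.fit_longitudinal(
        dataset,
        list(config.item_params),
        model="step",
        markov=True,
        iiv=("psi0", "rmax", "t_r"),
        compute_se=True,
        maxiter=60,
    )
    return config, fit
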