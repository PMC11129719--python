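"""Shared fixtures: the paper-scale design and one fully simulated study.

The expensive artifacts (the 1218-triplet design, the calibrated ground
truth, the 4872-trial response table, and the variational fits) are
session-scoped so the acceptance-style tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import woodsim as ws

#: Frozen study conditions for the recovery analyses (see docs/methods.md).
STUDY = dict(n_items=30, coverage=0.10, d_true=5, sparsity=0.5, n_raters=45)
FIT_CFG = dict(epochs=400, learning_rate=0.002)


@pytest.fixture(scope="session")
def paper_design() -> ws.TripletDesign:
    return ws.sample_design(STUDY["n_items"], STUDY["coverage"], seed=1)


@pytest.fixture(scope="session")
def ground_truth(paper_design) -> ws.GroundTruth:
    gt = ws.gen_ground_truth(STUDY["n_items"], STUDY["d_true"], STUDY["sparsity"], seed=2)
    return ws.calibrate_decision_noise(gt, paper_design)


@pytest.fixture(scope="session")
def simulated_trials(paper_design, ground_truth):
    sets = ws.build_participant_sets(paper_design, seed=3)
    return ws.simulate_triplet_responses(ground_truth, ws.trials_table(sets), seed=4)


@pytest.fixture(scope="session")
def simulated_ratings(ground_truth) -> ws.RatingTable:
    return ws.simulate_ratings(ground_truth, STUDY["n_raters"], seed=8)


@pytest.fixture(scope="session")
def train_test_split(simulated_trials):
    return ws.split_trials(simulated_trials, 0.9, seed=5)


@pytest.fixture(scope="session")
def fitted_embedding(train_test_split) -> ws.Embedding:
    train, _ = train_test_split
    post, _ = ws.fit(train, ws.SpikeSlabPrior(), ws.TrainConfig(seed=6, **FIT_CFG))
    return ws.extract_embedding(post)


@pytest.fixture(scope="session")
def fitted_embedding_alt_seed(train_test_split) -> ws.Embedding:
    train, _ = train_test_split
    post, _ = ws.fit(train, ws.SpikeSlabPrior(), ws.TrainConfig(seed=7, **FIT_CFG))
    return ws.extract_embedding(post)


@pytest.fixture(scope="session")
def true_embedding(ground_truth) -> ws.Embedding:
    return ws.Embedding(
        items=list(range(ground_truth.n_items)), loadings=ground_truth.embedding
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
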