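"""Variational triplet embedding: likelihood, fit, pruning, evaluation."""

import math

import numpy as np
import pandas as pd
import pytest

import woodsim as ws
from woodsim.errors import DegenerateModelError, ParameterError
from woodsim.triplet_design import Triplet


def _trial_frame(rows):
    """rows: (target, left, right, response)"""
    return pd.DataFrame(
        [
            ("p", i, t, l, r, 0, 0, 0, resp)
            for i, (t, l, r, resp) in enumerate(rows)
        ],
        columns=["participant_id", "trial_index", "target", "match_left",
                 "match_right", "swapped", "is_catch", "is_practice", "response"],
    )


class TestChoiceProbability:
    def test_symmetric_similarities_give_half(self):
        emb = ws.Embedding(items=[0, 1, 2], loadings=np.array([[1.0], [2.0], [2.0]]))
        assert ws.choice_probability(emb, Triplet.make(0, 1, 2)) == pytest.approx(0.5)

    def test_unit_logit_closed_form(self):
        # s_ta - s_tb = 1 exactly: p = 1/(1+e^-1)
        emb = ws.Embedding(items=[0, 1, 2], loadings=np.array([[1.0], [2.0], [1.0]]))
        p = ws.choice_probability(emb, Triplet(0, 1, 2))  # s=2 vs s=1
        assert p == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-12)

    def test_matches_independent_softmax_on_random_embeddings(self, rng):
        """Oracle equivalence on 100 random small embeddings to 1e-12."""
        for _ in range(100):
            n, d = rng.integers(3, 7), rng.integers(1, 4)
            x = rng.exponential(1.0, size=(n, d))
            emb = ws.Embedding(items=list(range(n)), loadings=x)
            t, a, b = rng.choice(n, size=3, replace=False)
            trip = Triplet(int(t), int(a), int(b))
            s_ta = sum(x[t][k] * x[a][k] for k in range(d))
            s_tb = sum(x[t][k] * x[b][k] for k in range(d))
            oracle = math.exp(s_ta) / (math.exp(s_ta) + math.exp(s_tb))
            assert abs(ws.choice_probability(emb, trip) - oracle) < 1e-12

    def test_complementary_orderings_sum_to_one(self, rng):
        x = rng.exponential(1.0, size=(5, 2))
        emb = ws.Embedding(items=list(range(5)), loadings=x)
        p_ab = ws.choice_probability(emb, Triplet(0, 1, 2))
        p_ba = ws.choice_probability(emb, Triplet(0, 2, 1))
        assert p_ab + p_ba == pytest.approx(1.0, abs=1e-12)

    def test_unknown_item_lookup_error(self):
        emb = ws.Embedding(items=[0, 1, 2], loadings=np.ones((3, 1)))
        with pytest.raises(LookupError):
            ws.choice_probability(emb, Triplet(0, 1, 9))


class TestAccuracy:
    def test_matches_loop_oracle_on_fixture(self, rng):
        x = rng.exponential(1.0, size=(6, 2))
        emb = ws.Embedding(items=list(range(6)), loadings=x)
        rows = []
        for _ in range(20):
            t, a, b = rng.choice(6, size=3, replace=False)
            rows.append((int(t), int(a), int(b), rng.choice(["left", "right"])))
        trials = _trial_frame(rows)
        expected = 0.0
        for t, a, b, resp in rows:
            p = ws.choice_probability(emb, Triplet(t, a, b))
            if p == 0.5:
                expected += 0.5
            else:
                expected += float((p > 0.5) == (resp == "left"))
        assert ws.accuracy(emb, trials) == pytest.approx(expected / 20)

    def test_ties_credited_half(self):
        emb = ws.Embedding(items=[0, 1, 2], loadings=np.ones((3, 1)))
        trials = _trial_frame([(0, 1, 2, "left"), (0, 1, 2, "right")])
        assert ws.accuracy(emb, trials) == pytest.approx(0.5)

    def test_shuffled_responses_near_chance(self, true_embedding, simulated_trials, rng):
        exp = ws.experimental_trials(simulated_trials).copy()
        exp["response"] = rng.permutation(np.where(rng.random(len(exp)) < 0.5, "left", "right"))
        acc = ws.accuracy(true_embedding, exp)
        assert 0.45 <= acc <= 0.55

    def test_generating_embedding_perfect_at_zero_noise(self):
        gt = ws.gen_ground_truth(6, 2, 0.0, seed=1).with_decision_noise(1e-9)
        design = ws.sample_design(6, 1.0, seed=2)
        trials = ws.simulate_triplet_responses(gt, design, seed=3)
        emb = ws.Embedding(items=list(range(6)), loadings=gt.embedding)
        p = ws.synthetic_data.choice_probabilities(gt.with_decision_noise(1.0), trials)
        decided = p != 0.5  # exact ties are credited 0.5, not 1.0
        exp = trials[decided]
        assert ws.accuracy(emb, exp) == pytest.approx(1.0)


class TestNoiseCeiling:
    def test_printed_agreement_distribution(self):
        """The distribution 569 unanimous / 439 three-of-four / 210 split
        over 1218 triplets gives a ceiling that rounds to 82%."""
        dist = ws.AgreementDistribution(
            n_triplets=1218, counts={"unanimous": 569, "majority3": 439, "split2": 210}
        )
        ceiling = ws.noise_ceiling_from_distribution(dist)
        assert ceiling == pytest.approx((569 + 0.75 * 439 + 0.5 * 210) / 1218)
        assert round(ceiling, 2) == 0.82

    def test_all_unanimous_and_all_split(self):
        all_u = ws.AgreementDistribution(10, {"unanimous": 10, "majority3": 0, "split2": 0})
        all_s = ws.AgreementDistribution(10, {"unanimous": 0, "majority3": 0, "split2": 10})
        assert all_u.mean_agreement() == 1.0
        assert all_s.mean_agreement() == 0.5

    def test_noise_ceiling_of_simulated_study(self, simulated_trials):
        ceiling = ws.noise_ceiling(simulated_trials)
        assert 0.79 <= ceiling <= 0.85  # calibrated to 0.82 in expectation


class TestFit:
    def test_strong_one_dimensional_structure_recovered(self):
        """Responses from a well-separated 1-D embedding at low noise are
        predicted with held-out accuracy above 0.9."""
        rng = np.random.default_rng(0)
        x = np.linspace(0.2, 3.0, 12)[:, None]
        gt = ws.GroundTruth(
            embedding=x, attribute_loadings=np.ones((1, 1)),
            decision_noise=0.05, rating_noise_sd=0.0, seed=0,
        )
        design = ws.sample_design(12, 0.6, seed=1)
        trials = ws.simulate_triplet_responses(gt, design, seed=2)
        train, test = ws.split_trials(trials, 0.9, seed=3)
        post, log = ws.fit(
            train, ws.SpikeSlabPrior(),
            ws.TrainConfig(epochs=400, learning_rate=0.01, seed=4),
        )
        emb = ws.extract_embedding(post)
        assert ws.accuracy(emb, test) > 0.9

    def test_pure_noise_held_out_accuracy_at_chance(self):
        gt = ws.gen_ground_truth(10, 2, 0.0, seed=5).with_decision_noise(1e9)
        design = ws.sample_design(10, 0.8, seed=6)
        trials = ws.simulate_triplet_responses(gt, design, seed=7)
        train, test = ws.split_trials(trials, 0.8, seed=8)
        post, _ = ws.fit(train, ws.SpikeSlabPrior(), ws.TrainConfig(epochs=80, seed=9))
        try:
            emb = ws.extract_embedding(post)
        except DegenerateModelError:
            return  # collapsing to nothing on noise is acceptable behaviour
        acc = ws.accuracy(emb, test)
        assert abs(acc - 0.5) <= 3 * np.sqrt(0.25 / len(test))

    def test_training_loss_trend_non_increasing(self, train_test_split):
        train, _ = train_test_split
        post, log = ws.fit(train, ws.SpikeSlabPrior(), ws.TrainConfig(epochs=60, seed=1))
        smoothed = log["loss"].rolling(10).mean().dropna().to_numpy()
        # smoothed trend decreases overall and never rises materially
        assert smoothed[-1] < smoothed[0]
        assert np.all(np.diff(smoothed) < 0.01)

    def test_deterministic_given_seed(self, train_test_split):
        train, _ = train_test_split
        small = train.iloc[:400]
        cfg = ws.TrainConfig(epochs=5, seed=3)
        post1, log1 = ws.fit(small, ws.SpikeSlabPrior(), cfg)
        post2, log2 = ws.fit(small, ws.SpikeSlabPrior(), cfg)
        np.testing.assert_array_equal(post1.mu, post2.mu)
        pd.testing.assert_frame_equal(log1, log2)


class TestExtractEmbedding:
    def test_planted_single_dimension_retained(self):
        mu = np.zeros((10, 4))
        mu[:, 2] = 3.0
        sigma = np.full((10, 4), 0.1)
        post = ws.VariationalPosterior(mu=mu, sigma=sigma)
        emb = ws.extract_embedding(post)
        assert emb.d == 1
        np.testing.assert_allclose(emb.loadings[:, 0], 3.0)

    def test_all_negative_mu_degenerate(self):
        post = ws.VariationalPosterior(mu=-np.ones((5, 3)), sigma=np.full((5, 3), 0.1))
        with pytest.raises(DegenerateModelError):
            ws.extract_embedding(post)

    def test_dimensions_sorted_by_loading_sum(self):
        mu = np.zeros((6, 3))
        mu[:, 0] = 1.0
        mu[:, 1] = 5.0
        mu[:, 2] = 3.0
        post = ws.VariationalPosterior(mu=mu, sigma=np.full((6, 3), 0.01))
        emb = ws.extract_embedding(post)
        sums = emb.loadings.sum(axis=0)
        assert np.all(np.diff(sums) <= 0)


class TestGridSearch:
    def test_single_point_grid(self, train_test_split):
        train, _ = train_test_split
        grid = [(ws.SpikeSlabPrior(), ws.TrainConfig(epochs=5, seed=0))]
        table, best = ws.grid_search(train.iloc[:600], grid, seed=1)
        assert len(table) == 1
        assert best["grid_index"] == 0

    def test_ranking_contract(self, train_test_split):
        train, _ = train_test_split
        grid = [
            (ws.SpikeSlabPrior(), ws.TrainConfig(epochs=5, seed=0)),
            (ws.SpikeSlabPrior(pi=0.4), ws.TrainConfig(epochs=5, learning_rate=0.002, seed=0)),
        ]
        table, best = ws.grid_search(train.iloc[:600], grid, seed=1)
        assert table["test_acc"].iloc[0] == table["test_acc"].max()
        assert best["test_acc"] == pytest.approx(table["test_acc"].iloc[0])

    def test_default_grid_enumerates_162_points(self):
        grid = ws.default_grid()
        assert len(grid) == 162
        combos = {(p.family, c.learning_rate, p.spike_scale, p.slab_scale, p.pi) for p, c in grid}
        assert len(combos) == 162

    def test_empty_grid_rejected(self, train_test_split):
        with pytest.raises(ParameterError):
            ws.grid_search(train_test_split[0], [], seed=0)


@pytest.fixture(scope="module")
def low_noise_2d_trials():
    """Four repetitions of a 15-item design from a 2-D ground truth at
    near-zero decision noise (repetitions ensure CV folds test mostly
    seen triplets, as in the repeated-measures protocol)."""
    gt = ws.gen_ground_truth(15, 2, 0.2, seed=10).with_decision_noise(0.05)
    design = ws.sample_design(15, 0.3, seed=11)
    reps = [ws.simulate_triplet_responses(gt, design, seed=12 + k) for k in range(4)]
    return pd.concat(reps, ignore_index=True)


class TestDimensionalityCV:
    def test_single_candidate(self, low_noise_2d_trials):
        d_hat, table = ws.estimate_dimensionality_cv(low_noise_2d_trials, [1], folds=2, seed=0, epochs=30)
        assert d_hat == 1

    def test_recovers_low_noise_two_dims(self, low_noise_2d_trials):
        d_hat, table = ws.estimate_dimensionality_cv(
            low_noise_2d_trials, [1, 2, 3, 4, 5], folds=3, seed=0, epochs=150
        )
        assert d_hat in (2, 3)

    def test_training_accuracy_grows_with_dimension(self, low_noise_2d_trials):
        exp = ws.experimental_trials(low_noise_2d_trials)
        accs = [
            ws.accuracy(ws.fit_ml(exp, d, epochs=150, seed=1), exp) for d in (1, 2, 3)
        ]
        assert accs[1] >= accs[0] - 0.02 and accs[2] >= accs[1] - 0.02
        assert accs[2] > accs[0]

    def test_empty_candidate_list_rejected(self, low_noise_2d_trials):
        with pytest.raises(ParameterError):
            ws.estimate_dimensionality_cv(low_noise_2d_trials, [], folds=2, seed=0)
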