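"""Latent class model core: cardinality rules, EM, imputation, criterion C."""

import numpy as np
import pytest

from ldforest import (EmConfig, criterion_c, delta_information, em_learn,
                      entropy, impute, latent_cardinality,
                      mutual_information, regularization_cardinality,
                      scaled_mutual_information)
from ldforest.lcm import LatentClassModel, posterior


class TestCardinalityRules:
    @pytest.mark.parametrize("size,expected", [(10, 4), (100, 20), (2, 2)])
    def test_affine_rule_reference_parameters(self, size, expected):
        assert latent_cardinality(size, a=0.2, b=2, card_max=20) == expected

    def test_floor_at_two(self):
        assert latent_cardinality(2, a=0.0, b=0.5, card_max=20) == 2

    def test_bad_card_max(self):
        with pytest.raises(ValueError):
            latent_cardinality(5, 0.2, 2, card_max=1)

    @pytest.mark.parametrize("cards,expected", [
        ([3] * 10, 19683),   # 3^10 / 3 = 3^9
        ([7], 1),
        ([2, 3], 2),
    ])
    def test_regularization_rule(self, cards, expected):
        assert regularization_cardinality(cards) == expected

    def test_regularization_empty(self):
        with pytest.raises(ValueError):
            regularization_cardinality([])


def make_deterministic_model(k=3):
    """Children are identity functions of a k-state latent."""
    eye = np.eye(k) * 0.994 + 0.003
    eye /= eye.sum(axis=0, keepdims=True)
    return LatentClassModel(
        latent_id="H", cardinality=k, child_ids=[0, 1],
        prior=np.ones(k) / k, child_cpts=[eye, eye])


class TestEmLearn:
    def test_duplicated_column_is_fully_captured(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 50)
        data = np.column_stack([x, x])
        model = em_learn(data, 2, EmConfig(n_restarts=5), seed=0)
        lv = impute(model, data)
        # the latent must carry all of x's information
        assert mutual_information(lv, x) == pytest.approx(entropy(x), abs=1e-6)

    def test_independent_children_reach_independence_loglik(self):
        rng = np.random.default_rng(4)
        n = 5000
        data = np.column_stack([rng.integers(0, 2, n), rng.integers(0, 3, n)])
        model = em_learn(data, 2, seed=1)
        indep = 0.0
        for j in range(2):
            counts = np.bincount(data[:, j])
            p = counts / n
            indep += float((counts[counts > 0] * np.log(p[p > 0])).sum())
        assert abs(model.loglik_trace[-1] - indep) < 1e-3 * n

    def test_trace_nondecreasing_and_best_of_restarts(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 3, size=(200, 4))
        best = em_learn(data, 3, EmConfig(n_restarts=4), seed=9)
        assert np.all(np.diff(best.loglik_trace) >= -1e-8)
        singles = [em_learn(data, 3, EmConfig(n_restarts=1), seed=9)]
        assert best.loglik_trace[-1] >= max(
            s.loglik_trace[-1] for s in singles) - 1e-6

    def test_em_monotonicity_on_many_random_instances(self):
        rng = np.random.default_rng(6)
        for i in range(200):
            n = int(rng.integers(20, 60))
            c = int(rng.integers(2, 4))
            data = rng.integers(0, int(rng.integers(2, 4)), size=(n, c))
            m = em_learn(data, int(rng.integers(2, 4)),
                         EmConfig(n_restarts=1, max_iter=40), seed=i)
            assert np.all(np.diff(m.loglik_trace) >= -1e-8)

    def test_constant_data_warns_but_fits(self):
        data = np.zeros((30, 2), dtype=int)
        with pytest.warns(UserWarning):
            m = em_learn(data, 2, seed=0)
        assert m.prior.sum() == pytest.approx(1.0)

    def test_bad_cardinality(self):
        with pytest.raises(ValueError):
            em_learn(np.zeros((10, 2), dtype=int), 1, seed=0)


class TestImpute:
    def test_map_recovers_deterministic_latent_up_to_labels(self):
        from ldforest import Forest, sample_fhlcm

        f = Forest()
        for s in ("A", "B", "C", "D", "E"):
            f.add_observed(s, 3)
        cpt = np.eye(3) * 0.96 + 0.02
        cpt /= cpt.sum(axis=0, keepdims=True)
        f.add_latent("H1_1", 3, ["A", "B", "C", "D", "E"],
                     np.array([0.3, 0.3, 0.4]), [cpt] * 5,
                     np.zeros(0, dtype=np.int64))
        f.imputed = None
        matrix, latents = sample_fhlcm(f, 500, seed=11)
        model = em_learn(matrix.values, 3, EmConfig(n_restarts=5), seed=2)
        lv = impute(model, matrix.values)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(latents["H1_1"], lv) >= 0.9

    def test_uniform_posterior_ties_to_state_zero(self):
        m = LatentClassModel("H", 2, [0, 1], np.array([0.5, 0.5]),
                             [np.full((2, 2), 0.5), np.full((2, 2), 0.5)])
        data = np.array([[0, 1], [1, 0], [1, 1]])
        assert np.array_equal(impute(m, data, "map"), np.zeros(3))

    def test_sampling_reproducible_and_calibrated(self):
        m = make_deterministic_model()
        rng = np.random.default_rng(8)
        data = rng.integers(0, 3, size=(10000, 2))
        s1 = impute(m, data, "sample", seed=42)
        s2 = impute(m, data, "sample", seed=42)
        assert np.array_equal(s1, s2)
        post = posterior(m, data)
        for k in range(3):
            expected = post[:, k].sum()
            sd = np.sqrt((post[:, k] * (1 - post[:, k])).sum())
            assert abs((s1 == k).sum() - expected) <= 3 * sd + 1e-9

    def test_column_mismatch(self):
        m = make_deterministic_model()
        with pytest.raises(ValueError):
            impute(m, np.zeros((5, 3), dtype=int))


class TestCriteria:
    def test_latent_identical_to_children_is_one(self):
        x = np.array([0, 1, 1, 0, 1, 0])
        m = make_deterministic_model(2)
        assert criterion_c(m, np.column_stack([x, x]), x) == pytest.approx(1.0)

    def test_term_by_term_oracle(self, rng):
        child = rng.integers(0, 2, size=(300, 3))
        lv = rng.integers(0, 3, 300)
        m = make_deterministic_model()
        expected = np.mean([scaled_mutual_information(child[:, j], lv)
                            for j in range(3)])
        assert criterion_c(m, child, lv) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_child_order(self, rng):
        child = rng.integers(0, 2, size=(200, 4))
        lv = rng.integers(0, 2, 200)
        m = make_deterministic_model()
        assert criterion_c(m, child, lv) == pytest.approx(
            criterion_c(m, child[:, ::-1], lv), abs=1e-12)

    def test_delta_counts_bits_over_edges(self, rng):
        x = rng.integers(0, 2, 400)
        m = make_deterministic_model(2)
        k = 3
        child = np.column_stack([x] * k)
        assert delta_information(m, child, x) == pytest.approx(
            k * entropy(x), abs=1e-9)
        other = rng.integers(0, 2, size=(400, 2))
        expected = sum(mutual_information(other[:, j], x) for j in range(2))
        assert delta_information(m, other, x) == pytest.approx(expected,
                                                               abs=1e-12)


class TestParameterRecovery:
    def test_strongly_separated_lcm_recovered(self):
        """Sampling a 3-state, 5-child LCM with sharp CPTs and refitting must
        recover the latent assignment (ARI >= 0.9)."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(21)
        n, k = 2000, 3
        true_h = rng.integers(0, k, n)
        cpt = np.eye(k) * 0.85 + 0.05  # conditional modes = 0.90
        data = np.column_stack([
            np.array([rng.choice(k, p=cpt[:, h]) for h in true_h])
            for _ in range(5)])
        model = em_learn(data, k, EmConfig(n_restarts=3), seed=3)
        lv = impute(model, data)
        assert adjusted_rand_score(true_h, lv) >= 0.9
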