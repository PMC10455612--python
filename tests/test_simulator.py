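"""Tests for the synthetic-data generator (study-design conditions)."""

import math

import numpy as np
import pytest

from mggum import (
    ItemBank,
    PersonSample,
    ResponseMatrix,
    ResponseScale,
    SimulationCondition,
    apply_missingness,
    draw_item_parameters,
    draw_persons_and_covariates,
    generate_responses,
    simulate_dataset,
    write_dataset,
)
from mggum.estimate import read_covariates, read_itemmap, read_responses


def big_condition(**over):
    base = dict(n_persons=100_000, n_traits=2, items_per_trait=5, n_options=2,
                missing_prop=0.0, trait_cor=0.5, trait_covariate_cor=0.25)
    base.update(over)
    return SimulationCondition(**base)


class TestItemParameters:
    def test_generating_intervals(self):
        cond = SimulationCondition(n_traits=5, items_per_trait=10, n_options=2)
        items = draw_item_parameters(cond, np.random.default_rng(0))
        # 1000 draws by repeating across seeds
        alphas, deltas = [items.alpha], [items.delta]
        for s in range(1, 20):
            b = draw_item_parameters(cond, np.random.default_rng(s))
            alphas.append(b.alpha)
            deltas.append(b.delta)
        alphas = np.concatenate(alphas)
        deltas = np.concatenate(deltas)
        assert alphas.size == 1000
        assert alphas.min() >= 0.5 and alphas.max() <= 2.0
        assert deltas.min() >= -2.0 and deltas.max() <= 2.0

    def test_tau_intervals_and_ordering_four_options(self):
        cond = SimulationCondition(n_traits=2, items_per_trait=10, n_options=4)
        items = draw_item_parameters(cond, np.random.default_rng(1))
        assert items.tau.shape == (20, 3)
        assert np.all(items.tau[:, 0] < items.tau[:, 1])
        assert np.all(items.tau[:, 1] < items.tau[:, 2])
        assert np.all((items.tau[:, 0] >= -3.5) & (items.tau[:, 0] <= -2.5))
        assert np.all((items.tau[:, 2] >= -1.5) & (items.tau[:, 2] <= -0.5))

    def test_binary_tau_interval(self):
        cond = SimulationCondition(n_options=2)
        items = draw_item_parameters(cond, np.random.default_rng(2))
        assert np.all((items.tau >= -3.0) & (items.tau <= -1.0))

    def test_block_trait_assignment(self):
        cond = SimulationCondition(n_traits=3, items_per_trait=4)
        items = draw_item_parameters(cond, np.random.default_rng(3))
        np.testing.assert_array_equal(items.dimension, np.repeat([0, 1, 2], 4))

    def test_directions_match_true_locations(self):
        cond = SimulationCondition(n_traits=5, items_per_trait=10)
        items = draw_item_parameters(cond, np.random.default_rng(4))
        for d, delta in zip(items.direction, items.delta):
            if delta < -1.5:
                assert d == "negative"
            elif delta > 1.5:
                assert d == "positive"
            else:
                assert d == "neutral"

    def test_seed_determinism(self):
        cond = SimulationCondition(n_options=4)
        a = draw_item_parameters(cond, np.random.default_rng(11))
        b = draw_item_parameters(cond, np.random.default_rng(11))
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.tau, b.tau)

    def test_unsupported_options(self):
        with pytest.raises(ValueError):
            SimulationCondition(n_options=3)


class TestPersonsAndCovariates:
    def test_moments_large_sample(self):
        persons = draw_persons_and_covariates(big_condition(),
                                              np.random.default_rng(5))
        full = np.hstack([persons.theta, persons.X])
        assert np.all(np.abs(full.mean(axis=0)) < 0.01)
        assert np.all(np.abs(full.var(axis=0) - 1.0) < 0.02)

    def test_stated_correlations(self):
        persons = draw_persons_and_covariates(big_condition(),
                                              np.random.default_rng(6))
        R = np.corrcoef(np.hstack([persons.theta, persons.X]).T)
        assert abs(R[0, 1] - 0.5) < 0.01            # trait-trait
        assert abs(R[2, 3]) < 0.01                  # covariate-covariate
        assert np.all(np.abs(R[:2, 2:] - 0.25) < 0.01)   # trait-covariate

    def test_zero_covariate_correlation_independent(self):
        persons = draw_persons_and_covariates(
            big_condition(trait_covariate_cor=0.0), np.random.default_rng(7))
        R = np.corrcoef(np.hstack([persons.theta, persons.X]).T)
        assert np.all(np.abs(R[:2, 2:]) < 0.01)

    def test_non_psd_rejected(self):
        cond = SimulationCondition(n_traits=2, trait_cor=0.0,
                                   trait_covariate_cor=0.9)
        with pytest.raises(ValueError, match="positive semi-definite"):
            draw_persons_and_covariates(cond, np.random.default_rng(8))

    def test_perfect_trait_correlation_supported(self):
        cond = SimulationCondition(n_persons=5000, n_traits=2, trait_cor=1.0)
        persons = draw_persons_and_covariates(cond, np.random.default_rng(9))
        np.testing.assert_allclose(persons.theta[:, 0], persons.theta[:, 1],
                                   atol=1e-8)


class TestResponses:
    def test_values_in_range(self):
        sim = simulate_dataset(SimulationCondition(n_persons=300, n_options=4),
                               np.random.default_rng(10))
        assert sim.responses.values.min() >= 0
        assert sim.responses.values.max() <= 3

    def test_cell_frequency_matches_kernel(self):
        # 200k replicate draws of the e/(1+e) configuration
        items = ItemBank(dimension=[0], alpha=[1.0], delta=[0.0],
                         tau=np.array([[-1.0]]), direction=["neutral"])
        persons = PersonSample(theta=np.zeros((200_000, 1)))
        resp = generate_responses(persons, items, ResponseScale(1),
                                  np.random.default_rng(12))
        freq = resp.values.mean()
        assert abs(freq - math.e / (1 + math.e)) < 0.005

    def test_high_discrimination_concentrates_at_agreement(self):
        items = ItemBank(dimension=[0], alpha=[30.0], delta=[0.0],
                         tau=np.array([[-1.0]]), direction=["neutral"])
        persons = PersonSample(theta=np.zeros((2000, 1)))
        resp = generate_responses(persons, items, ResponseScale(1),
                                  np.random.default_rng(13))
        assert resp.values.mean() > 0.999


class TestMissingness:
    def test_exact_count(self):
        resp = ResponseMatrix(values=np.zeros((50, 20), dtype=int))
        out = apply_missingness(resp, 0.2, np.random.default_rng(14))
        assert out.missing_mask.sum() == 200

    def test_zero_proportion_identity(self):
        resp = ResponseMatrix(values=np.arange(20).reshape(4, 5) % 2)
        out = apply_missingness(resp, 0.0, np.random.default_rng(15))
        np.testing.assert_array_equal(out.values, resp.values)
        assert not out.missing_mask.any()

    def test_same_seed_same_mask(self):
        resp = ResponseMatrix(values=np.zeros((30, 10), dtype=int))
        a = apply_missingness(resp, 0.2, np.random.default_rng(16))
        b = apply_missingness(resp, 0.2, np.random.default_rng(16))
        np.testing.assert_array_equal(a.missing_mask, b.missing_mask)


class TestEndToEnd:
    def test_full_pipeline_reproducible(self):
        cond = SimulationCondition(n_persons=80, n_traits=2, items_per_trait=5,
                                   n_options=4, missing_prop=0.2,
                                   trait_cor=0.5, trait_covariate_cor=0.25,
                                   seed=99)
        a = simulate_dataset(cond)
        b = simulate_dataset(cond)
        np.testing.assert_array_equal(a.responses.values, b.responses.values)
        np.testing.assert_array_equal(a.responses.missing_mask,
                                      b.responses.missing_mask)
        np.testing.assert_array_equal(a.persons.theta, b.persons.theta)

    def test_true_structure(self):
        cond = SimulationCondition(trait_cor=0.5, trait_covariate_cor=0.25)
        s = cond.true_structure()
        assert s.omega[0, 1] == 0.5
        np.testing.assert_allclose(s.beta, 0.25)
        assert s.sigma2 == pytest.approx(1 - 2 * 0.25 ** 2)

    def test_csv_round_trip(self, tmp_path):
        cond = SimulationCondition(n_persons=40, n_traits=2, items_per_trait=3,
                                   n_options=4, missing_prop=0.1,
                                   trait_covariate_cor=0.25, seed=5)
        sim = simulate_dataset(cond)
        out = write_dataset(sim, tmp_path / "d")
        resp = read_responses(out / "responses.csv")
        np.testing.assert_array_equal(resp.missing_mask,
                                      sim.responses.missing_mask)
        obs = ~resp.missing_mask
        np.testing.assert_array_equal(resp.values[obs],
                                      sim.responses.values[obs])
        items = read_itemmap(out / "itemmap.csv")
        np.testing.assert_array_equal(items.dimension, sim.items.dimension)
        np.testing.assert_allclose(items.tau, sim.items.tau)
        X = read_covariates(out / "covariates.csv")
        np.testing.assert_allclose(X, sim.persons.X)
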