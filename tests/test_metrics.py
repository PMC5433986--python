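import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linprog

from lifetraj import (
    LRSHistogram,
    earth_mover_distance,
    lrs_histogram,
    predict_lrs,
    relative_bias,
    scaled_entropy,
    stationary_distribution,
    transition_matrix,
    within_individual_variance,
)
from lifetraj.metrics import TransitionMatrix
from lifetraj.model import BreedingTrajectoryModel, BreedingTrajectoryResults, DesignData

probs = st.floats(0.001, 0.999)


def emd_lp(c1: np.ndarray, c2: np.ndarray) -> float:
    """Minimum-cost transport between equal-mass count vectors (LP oracle)."""
    n, m = len(c1), len(c2)
    cost = np.abs(np.subtract.outer(np.arange(n), np.arange(m))).ravel()
    a_eq, b_eq = [], []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1.0
        a_eq.append(row)
        b_eq.append(c1[i])
    for j in range(m):
        row = np.zeros(n * m)
        row[j::m] = 1.0
        a_eq.append(row)
        b_eq.append(c2[j])
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)


class TestTransitionMatrix:
    def test_symmetric_null(self):
        tm = transition_matrix(0.0, 0.0)
        assert tm.as_array() == pytest.approx(np.full((2, 2), 0.5))

    def test_logistic_evaluation(self):
        tm = transition_matrix(0.0, math.log(2))
        assert tm.p == pytest.approx(2 / 3)
        assert tm.p_star == pytest.approx(0.5)

    @given(mu=st.floats(-3, 3), gamma=st.floats(-3, 3))
    def test_log_odds_ratio_recovers_gamma(self, mu, gamma):
        tm = transition_matrix(mu, gamma)
        lor = math.log(tm.p * (1 - tm.p_star) / (tm.p_star * (1 - tm.p)))
        assert lor == pytest.approx(gamma, abs=1e-9)

    def test_rows_sum_to_one(self):
        tm = transition_matrix(0.4, -0.8)
        assert tm.as_array().sum(axis=1) == pytest.approx([1.0, 1.0])


class TestStationaryDistribution:
    def test_symmetric(self):
        assert stationary_distribution(TransitionMatrix(0.5, 0.5)) == pytest.approx(
            (0.5, 0.5)
        )

    def test_known_ratio(self):
        # p = 2/3, p* = 1/2: psi21 = 1/3, psi12 = 1/2, pi ratio 2:3
        pi = stationary_distribution(TransitionMatrix(p_star=0.5, p=2 / 3))
        assert pi == pytest.approx((0.4, 0.6))

    @given(p_star=probs, p=probs)
    def test_left_eigenvector_property(self, p_star, p):
        tm = TransitionMatrix(p_star=p_star, p=p)
        pi = np.array(stationary_distribution(tm))
        assert pi @ tm.as_array() == pytest.approx(pi, abs=1e-12)
        assert pi.sum() == pytest.approx(1.0)

    def test_two_absorbing_states_undefined(self):
        with pytest.raises(ValueError, match="absorbing"):
            stationary_distribution(TransitionMatrix(p_star=0.0, p=1.0))


class TestScaledEntropy:
    def test_coin_flip_transitions_have_entropy_one(self):
        assert scaled_entropy(TransitionMatrix(0.5, 0.5)).scaled_entropy == 1.0

    def test_deterministic_chain_has_entropy_zero(self):
        assert scaled_entropy(TransitionMatrix(p_star=0.0, p=1.0)).scaled_entropy == 0.0

    def test_hand_computed_value(self):
        # mu = 0, gamma = log 2: pi = (2/5, 3/5), H = .4 ln2 + .6 (ln3 - 2/3 ln2)
        ent = scaled_entropy(transition_matrix(0.0, math.log(2)))
        h = 0.4 * math.log(2) + 0.6 * (math.log(3) - (2 / 3) * math.log(2))
        assert ent.entropy_nats == pytest.approx(h)
        assert ent.scaled_entropy == pytest.approx(h / math.log(2))
        assert ent.scaled_entropy == pytest.approx(0.951, abs=5e-4)

    @given(p_star=probs, p=probs)
    def test_bounded_on_unit_interval(self, p_star, p):
        se = scaled_entropy(TransitionMatrix(p_star=p_star, p=p)).scaled_entropy
        assert 0.0 <= se <= 1.0 + 1e-12

    def test_decreasing_in_state_dependence_magnitude(self):
        gammas = [0.0, 0.5, 1.0, 2.0, 4.0]
        vals = [
            scaled_entropy(transition_matrix(0.0, g)).scaled_entropy for g in gammas
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        neg = [
            scaled_entropy(transition_matrix(0.0, -g)).scaled_entropy
            for g in gammas
        ]
        assert all(a > b for a, b in zip(neg, neg[1:]))


class TestWithinIndividualVariance:
    def test_null_value(self):
        assert within_individual_variance(0.0, 0.0) == pytest.approx(0.5)

    def test_state_dependent_value(self):
        assert within_individual_variance(0.0, math.log(2)) == pytest.approx(
            2 / 9 + 1 / 4
        )

    @given(mu=st.floats(-3, 3), gamma=st.floats(-3, 3))
    def test_term_swap_symmetry(self, mu, gamma):
        assert within_individual_variance(mu, gamma) == pytest.approx(
            within_individual_variance(mu + gamma, -gamma), abs=1e-12
        )


def _manual_fit(spec_name, mu, gamma=0.0, sigma=0.0, n_obs=50):
    """A converged results object at chosen parameter values."""
    d = DesignData(
        responses=np.tile([0.0, 1.0], n_obs // 2),
        lag_covariate=np.tile([0.0, 1.0], n_obs // 2),
        individual_index=np.repeat(np.arange(n_obs // 2), 2),
    )
    model = BreedingTrajectoryModel(d, spec_name)
    return BreedingTrajectoryResults(
        model=model,
        mu_hat=mu,
        gamma_hat=gamma,
        sigma_repro_hat=sigma,
        loglik=-1.0,
        converged=True,
    )


class TestPredictLRS:
    def test_total_conserved(self, rng):
        fit = _manual_fit("Mnil", mu=0.3)
        lifespans = rng.integers(2, 20, size=200)
        hist = predict_lrs(fit, lifespans, rng, max_occasions=42)
        assert hist.total == 200
        assert len(hist.counts) == 43

    def test_independent_coin_model_mean(self, rng):
        fit = _manual_fit("Mnil", mu=0.0)
        lifespans = np.full(20_000, 4)
        hist = predict_lrs(fit, lifespans, rng, max_occasions=4)
        vals = np.arange(5)
        mean = (hist.counts * vals).sum() / hist.total
        assert mean == pytest.approx(2.0, abs=0.03)
        # full Binomial(4, 1/2) pmf check
        from scipy.stats import binom

        expected = binom.pmf(vals, 4, 0.5)
        assert hist.counts / hist.total == pytest.approx(expected, abs=0.02)

    def test_degenerate_frailty_matches_fixed_model(self):
        lifespans = np.full(500, 6)
        h_nil = predict_lrs(
            _manual_fit("Mnil", mu=0.2), lifespans, np.random.default_rng(3), 6
        )
        h_hpdh = predict_lrs(
            _manual_fit("MHPDH", mu=0.2, sigma=0.0),
            lifespans,
            np.random.default_rng(3),
            6,
        )
        assert np.array_equal(h_nil.counts, h_hpdh.counts)

    def test_nonconverged_fit_refused(self, rng):
        fit = _manual_fit("Mnil", mu=0.0)
        fit.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            predict_lrs(fit, [3, 4], rng)


class TestEarthMoverDistance:
    def test_identical_histograms(self):
        h = LRSHistogram([3, 1, 4, 1])
        assert earth_mover_distance(h, h) == 0.0

    def test_two_units_moved_one_step(self):
        assert (
            earth_mover_distance(LRSHistogram([2, 0]), LRSHistogram([0, 2])) == 2.0
        )

    def test_unequal_totals_rejected(self):
        with pytest.raises(ValueError, match="totals"):
            earth_mover_distance(LRSHistogram([1, 0]), LRSHistogram([1, 1]))

    def test_matches_lp_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            c1 = rng.integers(0, 10, size=6)
            c2 = rng.integers(0, 10, size=6)
            # balance the masses
            diff = c1.sum() - c2.sum()
            if diff > 0:
                c2[rng.integers(0, 6)] += diff
            else:
                c1[rng.integers(0, 6)] += -diff
            got = earth_mover_distance(LRSHistogram(c1), LRSHistogram(c2))
            assert got == pytest.approx(emd_lp(c1, c2), abs=1e-7)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(50):
            total = int(rng.integers(5, 30))
            h = [
                lrs_histogram(rng.integers(0, 6, size=total), 5) for _ in range(3)
            ]
            d01 = earth_mover_distance(h[0], h[1])
            d10 = earth_mover_distance(h[1], h[0])
            d02 = earth_mover_distance(h[0], h[2])
            d12 = earth_mover_distance(h[1], h[2])
            assert d01 == d10  # symmetry
            assert d01 >= 0.0
            if np.array_equal(h[0].counts, h[1].counts):
                assert d01 == 0.0
            assert d02 <= d01 + d12 + 1e-9  # triangle inequality


class TestRelativeBias:
    def test_exact_estimate_has_zero_bias(self):
        assert relative_bias(0.66, [0.66]).relative_bias_pct == 0.0

    def test_capping_with_floored_denominator(self):
        # truth 0.01, estimate 0.5: raw bias 4,900% capped to 100%
        assert relative_bias(0.01, [0.5]).relative_bias_pct == 100.0

    def test_plain_percentage(self):
        assert relative_bias(1.0, [0.8]).relative_bias_pct == pytest.approx(-20.0)

    def test_negative_cap(self):
        assert relative_bias(1.0, [-2.0]).relative_bias_pct == -100.0

    def test_empty_estimates_rejected(self):
        with pytest.raises(ValueError):
            relative_bias(1.0, [np.nan])
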