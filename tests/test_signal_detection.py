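"""Synchronous scenario: confidence maps, WBC vs the exact Bayes oracle,
Belief Consensus averaging, and the run driver."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascade_consensus.networks import (
    Topology,
    generate_connected_rgg,
    metropolis_hastings_weights,
    safe_epsilon,
)
from cascade_consensus.signal_detection import (
    SDConfig,
    SDPopulation,
    accuracy_from_confidence,
    belief_consensus_step,
    confidence_from_accuracy,
    destabilized_consensus_step,
    direct_bayes_posterior,
    initialize_population,
    prior_log_odds,
    run_synchronous,
    sample_accuracies,
    wbc_step,
)


class TestConfidenceMaps:
    def test_chance_accuracy_gives_zero_confidence(self):
        assert confidence_from_accuracy(0.5) == 0.0

    def test_three_to_one_odds(self):
        assert confidence_from_accuracy(0.75) == pytest.approx(np.log(3))
        assert accuracy_from_confidence(np.log(3)) == pytest.approx(0.75)

    @pytest.mark.parametrize("alpha", np.linspace(0.01, 0.99, 25))
    def test_round_trip_identity(self, alpha):
        assert accuracy_from_confidence(confidence_from_accuracy(alpha)) == pytest.approx(
            alpha, abs=1e-12
        )

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                confidence_from_accuracy(bad)

    def test_extreme_confidence_saturates_without_overflow(self):
        assert accuracy_from_confidence(1e6) == pytest.approx(1.0, abs=1e-300)
        assert accuracy_from_confidence(-1e6) == pytest.approx(0.0, abs=1e-300)
        assert np.isfinite(accuracy_from_confidence(1e6))

    def test_logistic_monotone(self):
        cs = np.linspace(-10, 10, 50)
        assert np.all(np.diff(accuracy_from_confidence(cs)) > 0)


class TestPriorLogOdds:
    def test_flat_prior_is_zero(self):
        assert prior_log_odds(0.5, 1) == 0.0
        assert prior_log_odds(0.5, -1) == 0.0

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.75, 0.9])
    def test_antisymmetry(self, p):
        assert prior_log_odds(p, 1) == pytest.approx(-prior_log_odds(p, -1))

    def test_three_to_one_prior(self):
        assert prior_log_odds(0.75, 1) == pytest.approx(np.log(3))

    def test_domain(self):
        with pytest.raises(ValueError):
            prior_log_odds(0.0, 1)


class TestSampleAccuracies:
    def test_zero_spread_is_deterministic(self):
        acc = sample_accuracies(0.5, 0.0, 10, seed=0)
        assert np.all(acc == 0.5)
        assert np.all(confidence_from_accuracy(acc) == 0.0)

    def test_flip_rule_forces_above_chance(self):
        acc = sample_accuracies(0.5, 0.5, 5000, seed=1)
        assert np.all(acc >= 0.5)
        assert np.all(acc < 1.0)

    def test_mean_accuracy_increases_with_spread(self):
        # folded-normal mean: mu=0.5 folded about 0.5 has mean
        # 0.5 + sigma * sqrt(2/pi)
        for sigma in (0.1, 0.3):
            acc = sample_accuracies(0.5, sigma, 200000, seed=2)
            expected = 0.5 + sigma * np.sqrt(2 / np.pi)
            assert np.mean(acc) == pytest.approx(expected, rel=0.02)


class TestWBCStep:
    def test_isolated_agent_unchanged_under_flat_prior(self):
        topo = Topology.from_pairs(1, [])
        pop = SDPopulation(opinions=[1], confidences=[0.7])
        new = wbc_step(pop, topo, 0.5)
        assert new.opinions[0] == 1
        assert new.confidences[0] == pytest.approx(0.7)

    def test_outvoted_centre_adopts_majority_evidence(self):
        # centre (+1, c=1) with neighbours (-1, c=2) and (+1, c=0.5):
        # s = 1 - 2 + 0.5 = -0.5 -> opinion -1, confidence 0.5; and
        # logistic(0.5) must equal the exact naive-Bayes posterior of S=-1
        topo = Topology.from_pairs(3, [(0, 1), (0, 2)])
        pop = SDPopulation(opinions=[1, -1, 1], confidences=[1.0, 2.0, 0.5])
        new = wbc_step(pop, topo, 0.5)
        assert new.opinions[0] == -1
        assert new.confidences[0] == pytest.approx(0.5)
        oracle = direct_bayes_posterior([(1, 1.0), (-1, 2.0), (1, 0.5)], 0.5, -1)
        assert accuracy_from_confidence(0.5) == pytest.approx(oracle, abs=1e-12)

    def test_star_centre_confidence_grows_linearly_in_neighbour_count(self):
        confs = []
        for k in (2, 4, 8):
            topo = Topology.from_pairs(k + 1, [(0, j) for j in range(1, k + 1)])
            pop = SDPopulation(
                opinions=np.ones(k + 1, dtype=int),
                confidences=np.full(k + 1, 1.5),
            )
            confs.append(wbc_step(pop, topo, 0.5).confidences[0])
        assert confs[0] == pytest.approx(1.5 * 3)
        assert confs[1] == pytest.approx(1.5 * 5)
        assert confs[2] == pytest.approx(1.5 * 9)

    def test_tie_retains_previous_opinion(self):
        topo = Topology.from_pairs(2, [(0, 1)])
        pop = SDPopulation(opinions=[1, -1], confidences=[1.0, 1.0])
        new = wbc_step(pop, topo, 0.5)
        assert new.opinions[0] == 1
        assert new.opinions[1] == -1

    def test_size_mismatch_and_nonfinite_rejected(self):
        topo = Topology.from_pairs(2, [(0, 1)])
        with pytest.raises(ValueError):
            wbc_step(SDPopulation(opinions=[1], confidences=[1.0]), topo)
        bad = SDPopulation(opinions=[1, 1], confidences=[1.0, 1.0])
        bad.confidences[0] = np.inf
        with pytest.raises(ValueError):
            wbc_step(bad, topo)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_posterior_log_odds_identity(self, data):
        """The WBC linear sum is exactly the naive-Bayes posterior log-odds."""
        n_votes = data.draw(st.integers(1, 9))
        opinions = data.draw(
            st.lists(st.sampled_from([-1, 1]), min_size=n_votes, max_size=n_votes)
        )
        confs = data.draw(
            st.lists(
                st.floats(0.0, 5.0, allow_nan=False),
                min_size=n_votes,
                max_size=n_votes,
            )
        )
        p_plus = data.draw(st.floats(0.05, 0.95))
        votes = list(zip(opinions, confs))
        post_plus = direct_bayes_posterior(votes, p_plus, 1)
        post_minus = direct_bayes_posterior(votes, p_plus, -1)
        assert post_plus + post_minus == pytest.approx(1.0, abs=1e-12)
        log_odds = np.log(post_plus) - np.log(post_minus)
        linear = sum(o * c for o, c in votes) + prior_log_odds(p_plus, 1)
        assert log_odds == pytest.approx(linear, abs=1e-10)


class TestDirectBayesPosterior:
    def test_single_vote_flat_prior_recovers_accuracy(self):
        c = 1.3
        assert direct_bayes_posterior([(1, c)], 0.5, 1) == pytest.approx(
            accuracy_from_confidence(c)
        )

    def test_opposing_equal_votes_cancel(self):
        votes = [(1, 2.0), (-1, 2.0)]
        assert direct_bayes_posterior(votes, 0.5, 1) == pytest.approx(0.5)
        assert direct_bayes_posterior(votes, 0.5, -1) == pytest.approx(0.5)


class TestBeliefConsensus:
    def test_two_agent_antisymmetric_pair_decays_to_zero(self):
        topo = Topology.from_pairs(2, [(0, 1)])
        v, eps = 3.0, 0.4
        pop = SDPopulation(opinions=[1, -1], confidences=[v, v])
        new = belief_consensus_step(pop, topo, eps)
        # y' = ((1 - 2 eps) v, -(1 - 2 eps) v): antisymmetry preserved
        assert new.signed_evidence[0] == pytest.approx(v * (1 - 2 * eps))
        assert new.signed_evidence[1] == pytest.approx(-v * (1 - 2 * eps))

    def test_sum_conserved_per_step(self):
        topo, _ = generate_connected_rgg(15, 0.4, seed=3)
        rng = np.random.default_rng(0)
        pop = SDPopulation(
            opinions=rng.choice([-1, 1], 15), confidences=rng.uniform(0, 3, 15)
        )
        eps = safe_epsilon(topo)
        total = pop.signed_evidence.sum()
        for _ in range(50):
            pop = belief_consensus_step(pop, topo, eps)
            assert pop.signed_evidence.sum() == pytest.approx(total, abs=1e-9)

    def test_complete_graph_eps_one_over_n_averages_in_one_step(self):
        n = 6
        topo = Topology.complete(n)
        rng = np.random.default_rng(1)
        pop = SDPopulation(
            opinions=rng.choice([-1, 1], n), confidences=rng.uniform(0, 2, n)
        )
        mean = pop.signed_evidence.mean()
        new = belief_consensus_step(pop, topo, 1.0 / n)
        assert np.allclose(new.signed_evidence, mean, atol=1e-12)

    def test_converges_to_initial_mean(self):
        topo, _ = generate_connected_rgg(20, 0.45, seed=11)
        rng = np.random.default_rng(2)
        pop = SDPopulation(
            opinions=rng.choice([-1, 1], 20), confidences=rng.uniform(0, 3, 20)
        )
        mean = pop.signed_evidence.mean()
        eps = safe_epsilon(topo)
        for _ in range(20000):
            pop = belief_consensus_step(pop, topo, eps)
            if np.max(np.abs(pop.signed_evidence - mean)) < 1e-8:
                break
        assert np.max(np.abs(pop.signed_evidence - mean)) < 1e-6

    def test_bad_epsilon_rejected(self):
        topo = Topology.complete(4)
        pop = SDPopulation(opinions=[1] * 4, confidences=[1.0] * 4)
        with pytest.raises(ValueError):
            belief_consensus_step(pop, topo, 0.0)
        with pytest.raises(ValueError):
            belief_consensus_step(pop, topo, 0.9)  # diag of I - eps L negative


class TestDestabilizedConsensus:
    def test_zero_gain_reduces_to_belief_consensus(self):
        topo, _ = generate_connected_rgg(10, 0.5, seed=4)
        rng = np.random.default_rng(3)
        pop = SDPopulation(
            opinions=rng.choice([-1, 1], 10), confidences=rng.uniform(0, 2, 10)
        )
        eps = safe_epsilon(topo)
        a = belief_consensus_step(pop, topo, eps)
        b = destabilized_consensus_step(pop, topo, 0.0, epsilon_avg=eps)
        assert np.allclose(a.signed_evidence, b.signed_evidence)

    @pytest.mark.parametrize("seed", range(20))
    def test_positive_mean_drives_all_signs_positive(self, seed):
        topo, _ = generate_connected_rgg(12, 0.45, seed=seed)
        rng = np.random.default_rng(seed)
        y0 = rng.normal(0.3, 1.0, 12)
        if y0.mean() <= 0:
            y0 = -y0  # ensure a positive-mean initial condition
        pop = SDPopulation(
            opinions=np.where(y0 >= 0, 1, -1).astype(int), confidences=np.abs(y0)
        )
        for _ in range(400):
            pop = destabilized_consensus_step(pop, topo, 0.2)
        assert np.all(pop.opinions == 1)

    def test_explicit_mh_matrix_accepted(self):
        topo, _ = generate_connected_rgg(8, 0.5, seed=6)
        f = metropolis_hastings_weights(topo)
        pop = SDPopulation(opinions=[1] * 8, confidences=[1.0] * 8)
        new = destabilized_consensus_step(pop, topo, 0.1, weight_matrix=f)
        assert np.allclose(new.signed_evidence, 1.1)  # (eps I + F) 1 = (1+eps) 1


class TestWBCInstabilityAndRenormalization:
    def test_magnitudes_grow_without_bound(self):
        topo = Topology.from_pairs(3, [(0, 1), (1, 2)])
        pop = SDPopulation(opinions=[1, -1, 1], confidences=[1.0, 0.5, 2.0])
        norms = []
        for _ in range(30):
            pop = wbc_step(pop, topo, 0.5)
            norms.append(np.linalg.norm(pop.signed_evidence) * np.exp(pop.renorm_log_scale))
        assert norms[-1] > 1e3 * norms[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_renormalized_signs_match_exact_rational_trajectory(self, seed):
        """Float trajectory with renormalization reproduces the sign pattern
        of the exact (Fraction) linear recursion on small graphs."""
        rng = np.random.default_rng(seed)
        n = 4
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.6]
        if not pairs:
            pairs = [(0, 1)]
        topo = Topology.from_pairs(n, pairs)
        adj = topo.adjacency()
        # huge initial confidences so the 1e100 renormalization triggers
        base = [Fraction(int(v), 100) * Fraction(10**99) for v in rng.integers(50, 400, n)]
        signs = rng.choice([-1, 1], n)
        y_exact = [Fraction(int(s)) * b for s, b in zip(signs, base)]
        pop = SDPopulation(
            opinions=signs.astype(int),
            confidences=np.array([float(b) for b in base]),
        )
        for _ in range(10):
            y_exact = [
                y_exact[i] + sum(Fraction(int(adj[i, j])) * y_exact[j] for j in range(n))
                for i in range(n)
            ]
            prev = pop.opinions.copy()
            pop = wbc_step(pop, topo, 0.5)
            exact_signs = [
                (1 if y > 0 else (-1 if y < 0 else int(prev[i])))
                for i, y in enumerate(y_exact)
            ]
            assert list(pop.opinions) == exact_signs
        assert pop.renorm_log_scale > 0  # renormalization actually happened


class TestRunSynchronous:
    def test_initial_unanimity_ends_at_time_zero(self):
        topo = Topology.complete(5)
        cfg = SDConfig(n=5, sigma_alpha=0.0)
        initial = SDPopulation(opinions=np.ones(5, dtype=int), confidences=np.ones(5))
        res = run_synchronous(cfg, topo, seed=0, accuracies=np.full(5, 0.7), initial=initial)
        assert res.outcome == "unanimous-correct"
        assert res.consensus_time == 0

    def test_isolated_nodes_time_out_without_initial_unanimity(self):
        topo = Topology.from_pairs(6, [])
        cfg = SDConfig(n=6, sigma_alpha=0.3, max_iterations=50)
        initial = SDPopulation(
            opinions=np.array([1, -1, 1, -1, 1, -1]), confidences=np.ones(6)
        )
        res = run_synchronous(cfg, topo, seed=0, accuracies=np.full(6, 0.7), initial=initial)
        assert res.outcome == "timeout"
        assert res.consensus_time is None

    def test_wbc_faster_but_no_more_accurate_than_bc(self):
        """Paired runs: summation reaches unanimity sooner than averaging,
        at equal or lower group accuracy."""
        from cascade_consensus.experiments import ExperimentConfig, paired_comparison

        cfg = ExperimentConfig(
            scenario="signal-detection",
            n=50,
            kappa=10.0,
            sweep_values=(0.3,),
            replicates=40,
            master_seed=77,
        )
        runs = paired_comparison(cfg)
        wbc = runs[runs.algorithm == "WBC"]
        bc = runs[runs.algorithm == "BC"]
        assert wbc.consensus_time.mean() < bc.consensus_time.mean()
        acc_w = (wbc.outcome == "unanimous-correct").mean()
        acc_b = (bc.outcome == "unanimous-correct").mean()
        se = np.sqrt(acc_b * (1 - acc_b) / len(bc)) + 1e-12
        assert acc_w <= acc_b + 3 * se

    def test_deterministic_given_seed(self):
        topo, _ = generate_connected_rgg(20, 0.4, seed=8)
        cfg = SDConfig(n=20, sigma_alpha=0.3)
        r1 = run_synchronous(cfg, topo, seed=123)
        r2 = run_synchronous(cfg, topo, seed=123)
        assert r1.outcome == r2.outcome
        assert r1.consensus_time == r2.consensus_time
        assert np.array_equal(r1.final_signed_evidence, r2.final_signed_evidence)


def test_initialize_population_accuracy_semantics():
    acc = np.full(20000, 0.8)
    pop = initialize_population(acc, true_state=-1, seed=0)
    assert np.mean(pop.opinions == -1) == pytest.approx(0.8, abs=0.01)
    assert np.allclose(pop.confidences, np.log(4))
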