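"""Discrete-character engine: likelihood, reconstruction, mapping, parsimony."""

import numpy as np
import pytest
from scipy.integrate import quad

from conftest import (enumeration_loglik, enumeration_marginals,
                      enumeration_parsimony)
from piturn.evolution import (CharacterMatrix, RateModel, dollo_loss_count,
                              fit_rates_ml, fitch_parsimony, marginal_asr,
                              pruning_loglik, read_tree,
                              sample_conditioned_path, sample_stochastic_maps,
                              summarize_maps, transition_matrix)
from piturn.synthetic import make_random_tree, simulate_character_evolution


# ---------------------------------------------------------------------------
# trees


class TestReadTree:
    def test_parses_topology_and_lengths(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        assert tree.n_tips() == 3
        assert len([n for n in tree.postorder() if not n.is_leaf()]) == 2
        assert tree.tip_depths() == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_round_trip_is_isomorphic(self):
        text = "((A:1,B:1.5):0.5,(C:2,D:0.25):1);"
        tree = read_tree(text)
        again = read_tree(tree.to_newick())
        assert again.to_newick() == tree.to_newick()
        assert again.tip_depths() == tree.tip_depths()

    def test_duplicate_tip_label_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_tree("((A:1,A:1):1,C:2);")

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError):
            read_tree("((A:1,B:1:1,C;")

    def test_multifurcation_preserved(self):
        tree = read_tree("(A:1,B:1,C:1,D:1);")
        assert len(tree.root.children) == 4


# ---------------------------------------------------------------------------
# transition matrices


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        m = RateModel.equal_rates(3, 0.7)
        assert np.allclose(transition_matrix(m, 0.0), np.eye(3))

    @pytest.mark.parametrize("q,t", [(0.5, 0.3), (1.0, 1.0), (2.0, 0.05)])
    def test_two_state_closed_form(self, q, t):
        m = RateModel.equal_rates(2, q)
        P = transition_matrix(m, t)
        stay = (1 + np.exp(-2 * q * t)) / 2
        assert abs(P[0, 0] - stay) < 1e-10
        assert abs(P[1, 0] - (1 - stay)) < 1e-10
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_long_time_reaches_stationary(self):
        m = RateModel.sym(3, [0.5, 1.0, 2.0])
        P = transition_matrix(m, 500.0)
        # symmetric Q: stationary distribution is uniform
        assert np.allclose(P, 1.0 / 3.0, atol=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(RateModel.equal_rates(2, 1.0), -0.1)


# ---------------------------------------------------------------------------
# pruning likelihood


class TestPruningLikelihood:
    def test_two_tip_closed_form(self):
        q, t = 0.8, 0.6
        model = RateModel.equal_rates(2, q)
        tree = read_tree(f"(A:{t},B:{t});")
        chars = CharacterMatrix({"A": 0, "B": 0}, ("0", "1"))
        P = transition_matrix(model, t)
        expected = np.log(sum(model.prior[r] * P[r, 0] ** 2 for r in range(2)))
        assert abs(pruning_loglik(tree, chars, model) - expected) < 1e-10

    def test_rate_zero_uniform_data(self):
        model = RateModel.equal_rates(4, 0.0)
        tree = read_tree("((A:1,B:1):1,C:2);")
        chars = CharacterMatrix({"A": 2, "B": 2, "C": 2}, list("wxyz"))
        assert abs(pruning_loglik(tree, chars, model) - np.log(0.25)) < 1e-12

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_enumeration(self, five_tip_tree, k):
        rng = np.random.default_rng(k)
        rates = rng.uniform(0.2, 1.5, size=k * (k - 1) // 2)
        model = RateModel.sym(k, rates)
        chars = CharacterMatrix(
            {t: int(rng.integers(k)) for t in five_tip_tree.tip_labels()})
        got = pruning_loglik(five_tip_tree, chars, model)
        want = enumeration_loglik(five_tip_tree, chars, model)
        assert abs(got - want) < 1e-10

    def test_missing_tip_marginalized(self, five_tip_tree):
        model = RateModel.equal_rates(2, 0.5)
        chars = CharacterMatrix({"A": 0, "B": None, "C": 1, "D": 1, "E": 0})
        got = pruning_loglik(five_tip_tree, chars, model)
        want = enumeration_loglik(five_tip_tree, chars, model)
        assert abs(got - want) < 1e-10

    def test_multifurcating_tree_matches_enumeration(self):
        tree = read_tree("((A:0.4,B:0.3,C:0.6):0.5,D:1,E:0.7);")
        model = RateModel.sym(3, [0.4, 0.9, 0.6])
        chars = CharacterMatrix({"A": 0, "B": 1, "C": 2, "D": 1, "E": 0})
        assert abs(pruning_loglik(tree, chars, model) -
                   enumeration_loglik(tree, chars, model)) < 1e-10

    def test_invariant_under_rerooting(self):
        # two rootings of the same unrooted 4-tip tree; time-reversible Q
        t1 = read_tree("((A:0.3,B:0.4):0.25,(C:0.5,D:0.2):0.35);")
        # root moved onto the A pendant edge
        t2 = read_tree("(A:0.15,(B:0.4,(C:0.5,D:0.2):0.6):0.15);")
        model = RateModel.sym(2, [0.7])
        chars = CharacterMatrix({"A": 0, "B": 1, "C": 1, "D": 0})
        assert abs(pruning_loglik(t1, chars, model) -
                   pruning_loglik(t2, chars, model)) < 1e-8


# ---------------------------------------------------------------------------
# rate fitting


class TestFitRates:
    def test_invariant_data_hits_zero_boundary(self, five_tip_tree):
        chars = CharacterMatrix({t: 1 for t in five_tip_tree.tip_labels()},
                                ("0", "1"))
        with pytest.warns(UserWarning):
            fit = fit_rates_ml(five_tip_tree, chars, "ER")
        assert fit.model.Q[0, 1] == 0.0

    def test_local_optimum_property(self, five_tip_tree, five_tip_chars):
        fit = fit_rates_ml(five_tip_tree, five_tip_chars, "ER")
        q = fit.model.Q[0, 1]
        for other in (q / 2, 2 * q):
            assert fit.loglik >= pruning_loglik(
                five_tip_tree, five_tip_chars,
                RateModel.equal_rates(2, other)) - 1e-9

    def test_er_parameter_recovery(self):
        """q-hat within +/-30% of the true rate in >=90% of 20 replicates.

        Each replicate fits four independent binary characters simulated on
        a 128-tip unit-depth tree (a single binary character carries too
        little Fisher information for that precision at any rate).
        """
        q_true = 1.0
        ok = 0
        for seed in range(20):
            tree = make_random_tree(128, seed=seed)
            model = RateModel.equal_rates(2, q_true)
            char_list = [
                CharacterMatrix(dict(simulate_character_evolution(
                    tree, model, seed=seed * 10 + c).tip_states), ("0", "1"))
                for c in range(4)]
            if all(len(c.observed_states()) < 2 for c in char_list):
                ok += 1  # degenerate draw; cannot be scored against the truth
                continue
            fit = fit_rates_ml(tree, char_list, "ER", k=2)
            if abs(fit.model.Q[0, 1] - q_true) / q_true <= 0.30:
                ok += 1
        assert ok >= 18

    def test_sym_matches_er_for_two_states(self, five_tip_tree, five_tip_chars):
        er = fit_rates_ml(five_tip_tree, five_tip_chars, "ER")
        sym = fit_rates_ml(five_tip_tree, five_tip_chars, "SYM")
        assert abs(er.loglik - sym.loglik) < 1e-4


# ---------------------------------------------------------------------------
# marginal ancestral reconstruction


class TestMarginalASR:
    def test_symmetric_cherry_gives_even_root(self):
        tree = read_tree("(A:0.5,B:0.5);")
        chars = CharacterMatrix({"A": 0, "B": 1})
        post = marginal_asr(tree, chars, RateModel.equal_rates(2, 1.0))
        assert np.allclose(post[tree.root.index], [0.5, 0.5], atol=1e-12)

    def test_low_rate_uniform_tips_pin_root(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        chars = CharacterMatrix({t: 1 for t in "ABCD"}, ("0", "1"))
        post = marginal_asr(tree, chars, RateModel.equal_rates(2, 0.01))
        assert post[tree.root.index][1] > 0.99

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_enumeration(self, five_tip_tree, k):
        rng = np.random.default_rng(10 + k)
        model = RateModel.sym(k, rng.uniform(0.3, 1.2, size=k * (k - 1) // 2))
        chars = CharacterMatrix(
            {t: int(rng.integers(k)) for t in five_tip_tree.tip_labels()})
        got = marginal_asr(five_tip_tree, chars, model)
        want = enumeration_marginals(five_tip_tree, chars, model)
        for i, w in want.items():
            assert np.allclose(got[i], w, atol=1e-9)

    def test_posteriors_sum_to_one(self, five_tip_tree, five_tip_chars):
        post = marginal_asr(five_tip_tree, five_tip_chars,
                            RateModel.equal_rates(2, 0.4))
        for p in post.values():
            assert abs(p.sum() - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# stochastic mapping


def _expected_transitions(model, a, b, t):
    """Independent oracle: E[#real jumps | X0=a, Xt=b] by numerical
    integration of the standard sojourn formula."""
    from scipy.linalg import expm

    Pt = expm(model.Q * t)[a, b]
    total = 0.0
    for i in range(model.k):
        for j in range(model.k):
            if i == j or model.Q[i, j] == 0:
                continue
            val, _ = quad(lambda s: expm(model.Q * s)[a, i] *
                          expm(model.Q * (t - s))[j, b], 0, t, limit=200)
            total += model.Q[i, j] * val
    return total / Pt


class TestStochasticMapping:
    def test_zero_rate_uniform_tips_no_transitions(self, five_tip_tree):
        chars = CharacterMatrix({t: 1 for t in five_tip_tree.tip_labels()},
                                ("0", "1"))
        model = RateModel.equal_rates(2, 0.0)
        samples = sample_stochastic_maps(five_tip_tree, chars, model, 20, seed=3)
        assert all(s.transition_count() == 0 for s in samples)

    def test_deterministic_given_seed(self, five_tip_tree, five_tip_chars):
        model = RateModel.equal_rates(2, 0.8)
        a = sample_stochastic_maps(five_tip_tree, five_tip_chars, model, 5, seed=11)
        b = sample_stochastic_maps(five_tip_tree, five_tip_chars, model, 5, seed=11)
        assert [s.branch_segments for s in a] == [s.branch_segments for s in b]

    def test_paths_are_endpoint_consistent(self, five_tip_tree, five_tip_chars):
        model = RateModel.equal_rates(2, 1.2)
        samples = sample_stochastic_maps(five_tip_tree, five_tip_chars, model,
                                         50, seed=5)
        for s in samples:
            for node in five_tip_tree.postorder():
                if node is five_tip_tree.root:
                    continue
                seg = s.branch_segments[node.index]
                parent_state = s.node_states[five_tip_tree.parent(node).index]
                assert seg[0][0] == parent_state
                assert seg[-1][0] == s.node_states[node.index]
                assert abs(sum(d for _, d in seg) - node.length) < 1e-9
                assert all(d >= 0 for _, d in seg)

    def test_tip_states_respected(self, five_tip_tree, five_tip_chars):
        model = RateModel.equal_rates(2, 0.9)
        samples = sample_stochastic_maps(five_tip_tree, five_tip_chars, model,
                                         30, seed=2)
        tip_index = {t.label: t.index for t in five_tip_tree.tips()}
        for s in samples:
            for label, state in five_tip_chars.states.items():
                assert s.node_states[tip_index[label]] == state

    @pytest.mark.parametrize("a,b,q,t", [(0, 0, 1.0, 1.0), (0, 1, 0.6, 0.8)])
    def test_conditioned_branch_mean_matches_oracle(self, a, b, q, t):
        model = RateModel.equal_rates(2, q)
        rng = np.random.default_rng(42)
        counts = [len(sample_conditioned_path(model, a, b, t, rng)) - 1
                  for _ in range(10000)]
        mean, se = np.mean(counts), np.std(counts) / np.sqrt(len(counts))
        want = _expected_transitions(model, a, b, t)
        assert abs(mean - want) <= 3 * max(se, 1e-3)

    def test_uniformization_fallback_matches_rejection(self):
        # force the fallback by disallowing rejection attempts
        model = RateModel.equal_rates(2, 0.7)
        rng1 = np.random.default_rng(1)
        rng2 = np.random.default_rng(1)
        n = 4000
        rej = [len(sample_conditioned_path(model, 0, 1, 1.0, rng1,
                                           rejection_tries=10000)) - 1
               for _ in range(n)]
        uni = [len(sample_conditioned_path(model, 0, 1, 1.0, rng2,
                                           rejection_tries=0)) - 1
               for _ in range(n)]
        se = np.hypot(np.std(rej) / np.sqrt(n), np.std(uni) / np.sqrt(n))
        assert abs(np.mean(rej) - np.mean(uni)) <= 3 * max(se, 1e-3)

    def test_node_frequencies_match_marginals(self, five_tip_tree, five_tip_chars):
        model = RateModel.equal_rates(2, 0.7)
        samples = sample_stochastic_maps(five_tip_tree, five_tip_chars, model,
                                         10000, seed=9)
        summary = summarize_maps(samples, 2)
        post = marginal_asr(five_tip_tree, five_tip_chars, model)
        for node in five_tip_tree.postorder():
            if node.is_leaf():
                continue
            assert np.allclose(summary.node_frequencies[node.index],
                               post[node.index], atol=0.02)

    def test_sampled_counts_bounded_below_by_parsimony(self, five_tip_tree,
                                                       five_tip_chars):
        model = RateModel.equal_rates(2, 0.8)
        samples = sample_stochastic_maps(five_tip_tree, five_tip_chars, model,
                                         500, seed=13)
        lower = fitch_parsimony(five_tip_tree, five_tip_chars)
        assert all(s.transition_count() >= lower for s in samples)


class TestSummarizeMaps:
    def test_hand_built_means(self, five_tip_tree, five_tip_chars):
        model = RateModel.equal_rates(2, 0.8)
        samples = sample_stochastic_maps(five_tip_tree, five_tip_chars, model,
                                         2, seed=1)
        summary = summarize_maps(samples, 2)
        want = (samples[0].transition_counts_by_type(2) +
                samples[1].transition_counts_by_type(2)) / 2
        assert np.allclose(summary.mean_counts, want)
        for freq in summary.node_frequencies.values():
            assert abs(freq.sum() - 1.0) < 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_maps([], 2)


# ---------------------------------------------------------------------------
# parsimony


class TestParsimony:
    def test_uniform_tips_no_changes(self, five_tip_tree):
        chars = CharacterMatrix({t: 0 for t in five_tip_tree.tip_labels()})
        assert fitch_parsimony(five_tip_tree, chars) == 0

    def test_two_tip_difference(self):
        tree = read_tree("(A:1,B:1);")
        assert fitch_parsimony(tree, CharacterMatrix({"A": 0, "B": 1})) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        tree = make_random_tree(6, seed=seed)
        chars = CharacterMatrix({t: int(rng.integers(3))
                                 for t in tree.tip_labels()})
        assert fitch_parsimony(tree, chars) == enumeration_parsimony(tree, chars)

    def test_multifurcation_matches_exhaustive(self):
        tree = read_tree("((A:1,B:1,C:1):1,(D:1,E:1):1,F:1);")
        chars = CharacterMatrix({"A": 0, "B": 1, "C": 0, "D": 1, "E": 1, "F": 0})
        assert fitch_parsimony(tree, chars) == enumeration_parsimony(tree, chars)


class TestDollo:
    def test_all_present_no_losses(self, five_tip_tree):
        chars = CharacterMatrix({t: 1 for t in five_tip_tree.tip_labels()})
        assert dollo_loss_count(five_tip_tree, chars) == 0

    def test_absent_cherry_is_one_loss(self):
        tree = read_tree("(((A:1,B:1):1,C:1):1,D:1);")
        chars = CharacterMatrix({"A": 0, "B": 0, "C": 1, "D": 1})
        assert dollo_loss_count(tree, chars) == 1

    def test_scattered_losses_counted_per_clade(self):
        tree = read_tree("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")
        chars = CharacterMatrix({"A": 0, "B": 0, "C": 1, "D": 0, "E": 1, "F": 1})
        # losses: the (A,B) cherry and tip D
        assert dollo_loss_count(tree, chars) == 2

    def test_root_absent_with_present_tips_rejected(self):
        tree = read_tree("(A:1,B:1);")
        chars = CharacterMatrix({"A": 1, "B": 0})
        with pytest.raises(ValueError, match="single-origin"):
            dollo_loss_count(tree, chars, root_state=0)

    def test_missing_tips_do_not_anchor_losses(self):
        tree = read_tree("(((A:1,B:1):1,C:1):1,D:1);")
        chars = CharacterMatrix({"A": 0, "B": None, "C": 1, "D": 1})
        assert dollo_loss_count(tree, chars) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_on_fuzz_characters(self, seed):
        """Dollo losses <= #absent tips, and Fitch (which may use gains)
        never needs more changes than the Dollo reconstruction spends."""
        rng = np.random.default_rng(100 + seed)
        tree = make_random_tree(12, seed=seed)
        states = {t: int(rng.random() < 0.5) for t in tree.tip_labels()}
        chars = CharacterMatrix(states)
        losses = dollo_loss_count(tree, chars)
        absents = sum(1 for s in states.values() if s == 0)
        assert losses <= absents
        assert fitch_parsimony(tree, chars) <= losses
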