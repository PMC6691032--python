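from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dmcmcp as d
from dmcmcp.analysis import log_spaced_eval_points
from dmcmcp.errors import EmptySampleError, InvalidArgumentError, TaggingError


def chain_record(i, chosen, chain_id="c-0", category="c", current=None):
    cur = current if current is not None else chosen
    return d.TrialRecord("p", 0, i, "chain", chain_id, category,
                         cur, chosen, cur, chosen, chosen)


class TestEmpiricalDistribution:
    def test_stuck_chain_is_a_point_mass(self):
        log = [chain_record(i, "b", current="b") for i in range(10)]
        dist = d.empirical_distribution(log, ["a", "b", "c"])
        assert np.array_equal(dist.freqs, [0.0, 1.0, 0.0])

    def test_frequencies_sum_to_one(self, small_session_log):
        _, log = small_session_log
        ids = sorted({r.chosen_id for r in log})
        dist = d.empirical_distribution(log, ids)
        assert abs(dist.freqs.sum() - 1.0) < 1e-9

    def test_burn_in_applies_per_chain(self):
        log = [chain_record(i, "a", chain_id="c-0") for i in range(5)]
        log += [chain_record(i + 5, "b", chain_id="c-1") for i in range(5)]
        dist = d.empirical_distribution(log, ["a", "b"], burn_in=3)
        assert dist.n_samples == 4  # two chains keep 2 trials each
        assert np.allclose(dist.freqs, [0.5, 0.5])

    def test_chain_concatenation_order_irrelevant(self, small_session_log):
        _, log = small_session_log
        ids = sorted({r.chosen_id for r in log})
        chains = {}
        for r in log:
            if r.trial_type == "chain":
                chains.setdefault(r.chain_id, []).append(r)
        reordered = [r for cid in sorted(chains, reverse=True) for r in chains[cid]]
        a = d.empirical_distribution(log, ids)
        b = d.empirical_distribution(reordered, ids)
        assert np.allclose(a.freqs, b.freqs)

    def test_excessive_burn_in_errors(self):
        log = [chain_record(i, "a") for i in range(3)]
        with pytest.raises(EmptySampleError):
            d.empirical_distribution(log, ["a"], burn_in=3)

    def test_choices_and_states_modes_coincide_on_chain_trials(self, small_session_log):
        _, log = small_session_log
        ids = sorted({r.chosen_id for r in log})
        a = d.empirical_distribution(log, ids, count_mode="choices")
        b = d.empirical_distribution(log, ids, count_mode="states")
        assert np.allclose(a.freqs, b.freqs)


class TestSlidingCumulativeAverage:
    features = np.array([[0.0], [1.0], [2.0]])
    ids = ["a", "b", "c"]

    def test_constant_chain_gives_constant_average(self):
        log = [chain_record(i, "b") for i in range(20)]
        pts, means = d.sliding_cumulative_average(log, self.features, self.ids)
        assert np.allclose(means, 1.0)

    def test_window_one_tracks_each_choice(self):
        log = [chain_record(0, "a"), chain_record(1, "c"), chain_record(2, "b")]
        pts, means = d.sliding_cumulative_average(
            log, self.features, self.ids, window=1, eval_points=[1, 2, 3]
        )
        assert np.allclose(means.ravel(), [0.0, 2.0, 1.0])

    def test_early_points_average_from_first_trial(self):
        log = [chain_record(0, "a"), chain_record(1, "c"), chain_record(2, "c")]
        pts, means = d.sliding_cumulative_average(
            log, self.features, self.ids, window=50, eval_points=[2]
        )
        assert means[0, 0] == pytest.approx(1.0)  # mean of features 0 and 2

    def test_out_of_range_eval_point_rejected(self):
        log = [chain_record(0, "a")]
        with pytest.raises(InvalidArgumentError):
            d.sliding_cumulative_average(log, self.features, self.ids, eval_points=[5])

    def test_default_eval_points_are_log_spaced_unique(self):
        pts = log_spaced_eval_points(1000)
        assert len(pts) == len(np.unique(pts))
        assert pts[0] == 1 and pts[-1] == 1000


class TestL1Distance:
    def test_identity_and_full_displacement(self):
        h = np.array([0.5, 0.5, 0.0])
        assert d.l1_histogram_distance(h, h) == 0.0
        assert d.l1_histogram_distance(
            np.array([1.0, 0.0]), np.array([0.0, 1.0])
        ) == 2.0

    def test_hand_sum(self):
        got = d.l1_histogram_distance(
            np.array([0.5, 0.5, 0.0]), np.array([0.25, 0.25, 0.5])
        )
        assert got == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            d.l1_histogram_distance(np.ones(3), np.ones(4))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_metric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        h = [rng.dirichlet(np.ones(5)) for _ in range(3)]
        d01 = d.l1_histogram_distance(h[0], h[1])
        assert d01 == pytest.approx(d.l1_histogram_distance(h[1], h[0]))
        assert d01 <= (
            d.l1_histogram_distance(h[0], h[2]) + d.l1_histogram_distance(h[2], h[1])
        ) + 1e-12


class TestWithinBetweenConvergence:
    @staticmethod
    def make_log(assignments):
        """assignments: {(category, chain_id): list of chosen ids}"""
        log = []
        t = 0
        for (cat, cid), chosen in assignments.items():
            for c in chosen:
                log.append(chain_record(t, c, chain_id=cid, category=cat))
                t += 1
        return log

    def test_identical_chains_have_zero_distances(self):
        seq = ["a", "b", "a", "b"]
        log = self.make_log({
            ("x", "x-0"): seq, ("x", "x-1"): seq,
            ("y", "y-0"): seq, ("y", "y-1"): seq,
        })
        curves = d.within_between_convergence(log, item_ids=["a", "b"])
        assert all(np.allclose(v, 0) for v in curves["within"].values())
        assert all(np.allclose(v, 0) for v in curves["between"].values())

    def test_disjoint_categories_are_maximally_distant(self):
        log = self.make_log({
            ("x", "x-0"): ["a"] * 4, ("x", "x-1"): ["a"] * 4,
            ("y", "y-0"): ["b"] * 4, ("y", "y-1"): ["b"] * 4,
        })
        curves = d.within_between_convergence(log, item_ids=["a", "b"])
        assert np.allclose(curves["between"][("x", "y")], 2.0)

    def test_separated_targets_converge_within_below_between(self, stimuli8, graph8):
        # two categories with opposite unimodal targets; after enough trials
        # chains of a category agree with each other more than across
        lo = d.make_target_distribution(stimuli8, "unimodal",
                                        modes=[stimuli8.features[0]], width=0.5)
        hi = d.make_target_distribution(stimuli8, "unimodal",
                                        modes=[stimuli8.features[7]], width=0.5)
        targets = {"low": lo, "high": hi}

        class SplitOracle:
            stochastic = True

            def __init__(self):
                self.sub = {
                    cat: d.SimulatedChooser(t, seed=i)
                    for i, (cat, t) in enumerate(targets.items())
                }

            def choose(self, current, proposal, category):
                return self.sub[category].choose(current, proposal, category)

        config = d.SessionConfig(categories=["low", "high"], chains_per_category=2,
                                 trials_per_chain=400, n_practice=0, n_catch=0,
                                 catch_pass_threshold=0, seed=0)
        log = d.run_session(config, graph8, SplitOracle())
        curves = d.within_between_convergence(log, item_ids=stimuli8.item_ids)
        final_within = np.mean([v[-1] for v in curves["within"].values()])
        final_between = curves["between"][("high", "low")][-1]
        assert final_within < final_between

    def test_single_chain_per_category_rejected(self):
        log = self.make_log({("x", "x-0"): ["a"] * 3, ("y", "y-0"): ["b"] * 3})
        with pytest.raises(InvalidArgumentError):
            d.within_between_convergence(log, item_ids=["a", "b"])


class TestCategoryFrequency:
    def test_hand_counted_proportions(self):
        log = [chain_record(i, c) for i, c in enumerate("wwxy")]
        tags = {"w": "A", "x": "B", "y": "C"}
        assert d.category_frequency(log, tags) == {"A": 0.5, "B": 0.25, "C": 0.25}

    def test_proportions_sum_to_one(self, small_session_log):
        _, log = small_session_log
        tags = {r.chosen_id: "even" if i % 2 else "odd"
                for i, r in enumerate(log)}
        freqs = d.category_frequency(log, tags)
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_untagged_item_raises_with_id(self):
        log = [chain_record(0, "mystery")]
        with pytest.raises(TaggingError, match="mystery"):
            d.category_frequency(log, {})

    def test_tag_permutation_permutes_output(self):
        log = [chain_record(i, c) for i, c in enumerate("wwxy")]
        base = d.category_frequency(log, {"w": "A", "x": "B", "y": "C"})
        swapped = d.category_frequency(log, {"w": "B", "x": "A", "y": "C"})
        assert swapped["B"] == base["A"] and swapped["A"] == base["B"]


class TestTopK:
    def test_modal_item_first(self):
        log = [chain_record(i, c) for i, c in enumerate("babbc")]
        top = d.top_k_items(log, 1)
        assert top.items == [("b", 3)]

    def test_ties_break_to_lower_id(self):
        log = [chain_record(i, c) for i, c in enumerate("abba")]
        assert d.top_k_items(log, 2).items == [("a", 2), ("b", 2)]

    def test_short_list_flagged(self):
        log = [chain_record(0, "a")]
        top = d.top_k_items(log, 5)
        assert top.short_list and top.items == [("a", 1)]

    def test_matches_independent_counting_oracle(self, small_session_log):
        _, log = small_session_log
        counts = Counter(r.chosen_id for r in log if r.trial_type == "chain")
        expected = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
        assert d.top_k_items(log, 10).items == expected
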