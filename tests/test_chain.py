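import numpy as np
import pytest
from scipy import stats

import dmcmcp as d
from dmcmcp.errors import ConfigError


class ForcedOracle:
    """Deterministic test oracle choosing always the proposal or always the current."""

    stochastic = False

    def __init__(self, accept: bool):
        self.accept = accept

    def choose(self, current, proposal, category=""):
        return proposal if self.accept else current


class TestRunTrial:
    def test_forced_acceptance_always_moves(self, graph8):
        state = d.ChainState("c-0", "c", current=0)
        rng = np.random.default_rng(0)
        for _ in range(30):
            before = state.current
            rec = d.run_trial(state, graph8, d.ProposalSpec(), ForcedOracle(True), rng)
            assert rec.chosen_id == rec.proposal_id
            assert state.current != before or rec.current_id == rec.proposal_id
        assert len(state.history) == 30

    def test_forced_rejection_never_moves(self, graph8):
        state = d.ChainState("c-0", "c", current=3)
        rng = np.random.default_rng(1)
        for _ in range(30):
            d.run_trial(state, graph8, d.ProposalSpec(), ForcedOracle(False), rng)
        assert state.current == 3
        assert all(h == 3 for h in state.history)

    def test_move_rate_matches_luce_closed_form(self, graph8, target8):
        # long run: per-pair acceptance approaches p(x')/(p(x')+p(x))
        oracle = d.SimulatedChooser(target8, gamma=1.0, seed=5)
        state = d.ChainState("c-0", "c", current=0)
        rng = np.random.default_rng(2)
        offers, moves = {}, {}
        for _ in range(40_000):
            rec = d.run_trial(state, graph8, d.ProposalSpec(), oracle, rng)
            key = (rec.current_id, rec.proposal_id)
            offers[key] = offers.get(key, 0) + 1
            moves[key] = moves.get(key, 0) + (rec.chosen_id == rec.proposal_id)
        index = {item: i for i, item in enumerate(graph8.item_ids)}
        checked = 0
        for key, n in offers.items():
            if n < 400:
                continue
            expected = d.luce_choice_prob(
                target8.probs[index[key[0]]], target8.probs[index[key[1]]], 1.0
            )
            assert abs(moves[key] / n - expected) < 0.05
            checked += 1
        assert checked >= 5


class TestRunSession:
    def test_reference_session_has_452_trials(self, graph8, target8):
        config = d.SessionConfig(seed=0)  # 4 chains x 100 + 12 practice + 40 catch
        oracle = d.SimulatedChooser(target8, seed=0)
        pairs = d.make_catch_pairs(target8, config.n_catch, rng=0)
        log = d.run_session(config, graph8, oracle, catch_pairs=pairs)
        assert len(log) == 452
        assert sum(r.trial_type == "chain" for r in log) == 400
        assert sum(r.trial_type == "practice" for r in log) == 12
        assert sum(r.trial_type == "catch" for r in log) == 40

    def test_session_without_catch_trials_has_412(self, graph8, target8):
        config = d.SessionConfig(categories=["morality"], chains_per_category=4,
                                 n_catch=0, catch_pass_threshold=0, seed=1)
        oracle = d.SimulatedChooser(target8, seed=1)
        log = d.run_session(config, graph8, oracle)
        assert len(log) == 412

    def test_practice_and_catch_never_advance_chains(self, small_session_log):
        # replay check: consecutive chain trials of each chain must join up,
        # i.e. the interleaved practice/catch trials left no trace on states
        _, log = small_session_log
        last_state = {}
        for rec in log:
            if rec.trial_type != "chain":
                continue
            if rec.chain_id in last_state:
                assert rec.current_id == last_state[rec.chain_id]
            last_state[rec.chain_id] = rec.chosen_id

    def test_practice_trials_come_first(self, small_session_log):
        _, log = small_session_log
        types = [r.trial_type for r in log]
        n_practice = sum(t == "practice" for t in types)
        assert all(t == "practice" for t in types[:n_practice])
        assert all(t != "practice" for t in types[n_practice:])

    def test_empty_session_rejected(self):
        with pytest.raises(ConfigError):
            d.SessionConfig(trials_per_chain=0, n_practice=0, n_catch=0,
                            catch_pass_threshold=0)

    def test_catch_trials_required_pairs(self, graph8, target8):
        config = d.SessionConfig(seed=0)
        with pytest.raises(ConfigError):
            d.run_session(config, graph8, d.SimulatedChooser(target8, seed=0))

    def test_seeded_session_reproducible(self, graph8, target8):
        config = d.SessionConfig(categories=["c"], chains_per_category=2,
                                 trials_per_chain=20, n_practice=2, n_catch=4,
                                 catch_pass_threshold=3, seed=42)
        pairs = d.make_catch_pairs(target8, 4, rng=1)
        logs = [
            d.run_session(config, graph8, d.SimulatedChooser(target8, seed=8),
                          catch_pairs=pairs)
            for _ in range(2)
        ]
        assert logs[0] == logs[1]


class TestLinking:
    @pytest.fixture()
    def linked_logs(self, graph8, target8):
        config = d.SessionConfig(categories=["happy", "sad"], chains_per_category=2,
                                 trials_per_chain=25, n_practice=2, n_catch=4,
                                 catch_pass_threshold=0, seed=3)
        oracle = d.SimulatedChooser(target8, seed=4)
        pairs = d.make_catch_pairs(target8, 4, rng=2)
        first = d.run_session(config, graph8, oracle, catch_pairs=pairs)
        second = d.link_sessions(first, config, graph8, oracle, catch_pairs=pairs)
        return config, first, second

    def test_next_session_starts_at_previous_final_state(self, linked_logs, graph8):
        config, first, second = linked_logs
        finals = {}
        for rec in first:
            if rec.trial_type == "chain":
                finals[rec.chain_id] = rec.chosen_id
        starts = {}
        for rec in second:
            if rec.trial_type == "chain" and rec.chain_id not in starts:
                starts[rec.chain_id] = rec.current_id
        assert starts == finals

    def test_ten_linked_sessions_make_thousand_trial_chains(self, graph8, target8):
        config = d.SessionConfig(categories=["happy", "sad"], chains_per_category=2,
                                 trials_per_chain=100, n_practice=0, n_catch=0,
                                 catch_pass_threshold=0, seed=5)
        oracle = d.SimulatedChooser(target8, seed=6)
        log = d.run_linked_sessions(config, graph8, oracle, n_sessions=10)
        counts = {}
        for rec in log:
            if rec.trial_type == "chain":
                counts[rec.chain_id] = counts.get(rec.chain_id, 0) + 1
        assert set(counts.values()) == {1000}

    def test_structural_mismatch_rejected(self, linked_logs, graph8, target8):
        config, first, _ = linked_logs
        other = d.SessionConfig(categories=["x"], chains_per_category=1,
                                trials_per_chain=10, n_practice=0, n_catch=0,
                                catch_pass_threshold=0, seed=0)
        with pytest.raises(ConfigError):
            d.link_sessions(first, other, graph8, d.SimulatedChooser(target8, seed=0))


class TestCatchExclusion:
    def test_attentive_responder_passes(self, graph8, target8):
        # forced-current oracle always picks the first offered item, which the
        # engine sets to the designated correct catch item
        config = d.SessionConfig(categories=["c"], chains_per_category=1,
                                 trials_per_chain=5, n_practice=0, n_catch=40,
                                 catch_pass_threshold=27, seed=0)
        pairs = d.make_catch_pairs(target8, 40, rng=0)
        log = d.run_session(config, graph8, ForcedOracle(False), catch_pairs=pairs)
        result = d.catch_exclusion(log, 27)
        assert result.passed and result.n_correct == 40

    def test_boundary_is_inclusive(self):
        def catch(i, chosen):
            return d.TrialRecord("p", 0, i, "catch", "-", "c", "hi", "lo",
                                 "hi", "lo", chosen, correct_id="hi")

        log = [catch(i, "hi" if i < 26 else "lo") for i in range(40)]
        assert not d.catch_exclusion(log, 27).passed
        log = [catch(i, "hi" if i < 27 else "lo") for i in range(40)]
        assert d.catch_exclusion(log, 27).passed

    def test_zero_threshold_always_passes(self):
        assert d.catch_exclusion([], 0).passed

    def test_missing_catch_trials_with_threshold_errors(self):
        rec = d.TrialRecord("p", 0, 0, "chain", "c-0", "c", "a", "b", "a", "b", "a")
        with pytest.raises(ConfigError):
            d.catch_exclusion([rec], 27)


class TestBinomialCatchThreshold:
    @pytest.mark.parametrize("n,alpha,expected", [(1, 0.6, 1), (2, 0.3, 2)])
    def test_hand_computed_small_cases(self, n, alpha, expected):
        assert d.binomial_catch_threshold(n, alpha) == expected

    def test_matches_scipy_tail_oracle(self):
        # independent oracle: smallest k with survival P(X >= k) < alpha
        for n, alpha in [(10, 0.05), (40, 0.01), (25, 0.001)]:
            k = d.binomial_catch_threshold(n, alpha)
            tail = lambda kk: stats.binom.sf(kk - 1, n, 0.5)
            assert tail(k) < alpha
            assert k == 0 or tail(k - 1) >= alpha

    def test_forty_catch_trials_at_one_percent(self):
        # the exact tail puts the criterion at 28 of 40: P(X>=27) ~ .0192 is
        # not below .01, P(X>=28) ~ .0083 is.  The conventional threshold of
        # 27 is one trial more lenient than the exact computation.
        k = d.binomial_catch_threshold(40, 0.01)
        assert k == 28
        assert stats.binom.sf(26, 40, 0.5) >= 0.01 > stats.binom.sf(27, 40, 0.5)
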