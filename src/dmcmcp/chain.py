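"""The pairwise-choice sampling engine.

A session is a sequence of two-alternative trials.  Chain trials implement
one sampler step each: propose x' from the graph walk, offer (x, x') to the
chooser in a randomized left/right order, and move the chain to whichever
item was chosen (choosing x' is acceptance, choosing x is rejection).
Sessions also carry practice trials (warm-up, excluded from analysis) and
catch trials (pairs with an objectively correct answer, used to exclude
inattentive responders); neither ever advances a chain.

Chains can be linked across participants — each session starts every chain at
the previous session's final state — to build long chains from many short
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np

from .bmatching import ProposalGraph
from .chooser import ChoiceOracle
from .errors import ConfigError, InvalidArgumentError, StuckProposalError
from .fixtures import TargetDistribution
from .proposals import ProposalSpec, mixture_proposal
from .util import as_rng

__all__ = [
    "TrialRecord",
    "ChainState",
    "SessionConfig",
    "CatchResult",
    "make_catch_pairs",
    "run_trial",
    "run_session",
    "link_sessions",
    "run_linked_sessions",
    "catch_exclusion",
    "binomial_catch_threshold",
]

#: how many times a trial redraws a proposal equal to the current state
PROPOSAL_RETRY_LIMIT = 100


@dataclass(slots=True)
class TrialRecord:
    """One presented pair and its outcome, in presentation order."""

    participant_id: str
    session_index: int
    trial_index: int
    trial_type: str  # chain | practice | catch
    chain_id: str
    category: str
    current_id: str
    proposal_id: str
    left_id: str
    right_id: str
    chosen_id: str
    correct_id: str = ""  # catch trials only

    def validate(self) -> None:
        if self.trial_type not in ("chain", "practice", "catch"):
            raise InvalidArgumentError(f"unknown trial_type {self.trial_type!r}")
        if self.chosen_id not in (self.left_id, self.right_id):
            raise InvalidArgumentError(
                f"trial {self.trial_index}: chosen {self.chosen_id!r} is not an offered item"
            )
        if {self.left_id, self.right_id} != {self.current_id, self.proposal_id}:
            raise InvalidArgumentError(
                f"trial {self.trial_index}: display pair does not match (current, proposal)"
            )


@dataclass
class ChainState:
    """One chain's identity, current position and visit history (post-trial states)."""

    chain_id: str
    category: str
    current: int
    history: list[int] = field(default_factory=list)


@dataclass
class SessionConfig:
    """Everything needed to run one participant's session.

    Defaults mirror the reference face sessions: 100 trials for each of
    4 chains, 12 practice trials, 40 catch trials with a pass threshold of
    27, uniform-neighbour proposals with a 10% uniform jump — 452 trials in
    total.
    """

    categories: list[str] = field(default_factory=lambda: ["happy", "sad"])
    chains_per_category: int = 2
    trials_per_chain: int = 100
    n_practice: int = 12
    n_catch: int = 40
    catch_pass_threshold: int = 27
    proposal: ProposalSpec = field(default_factory=ProposalSpec)
    seed: int = 0
    interleave: str = "round_robin"

    def __post_init__(self) -> None:
        if len(self.categories) == 0 or self.chains_per_category < 0:
            raise ConfigError("need at least one category and a nonnegative chain count")
        if min(self.trials_per_chain, self.n_practice, self.n_catch) < 0:
            raise ConfigError("trial counts must be nonnegative")
        if self.interleave != "round_robin":
            raise ConfigError(f"unknown interleave policy {self.interleave!r}")
        if self.total_trials == 0:
            raise ConfigError("empty session: no chain, practice or catch trials")

    @property
    def chain_ids(self) -> list[str]:
        return [
            f"{cat}-{k}" for cat in self.categories for k in range(self.chains_per_category)
        ]

    @property
    def n_chains(self) -> int:
        return len(self.categories) * self.chains_per_category

    @property
    def total_trials(self) -> int:
        return self.n_chains * self.trials_per_chain + self.n_practice + self.n_catch


def make_catch_pairs(
    target: TargetDistribution, n_catch: int, rng: int | np.random.Generator = 0
) -> list[tuple[int, int]]:
    """Build (correct, foil) catch pairs from a known target distribution.

    Pairs an item from the top decile of target probability with one from the
    bottom decile — the simulated analogue of choosing pairs whose better
    category member is clearly obvious.
    """
    if n_catch < 1:
        return []
    rng = as_rng(rng)
    order = np.argsort(target.probs, kind="stable")
    k = max(1, target.n_items // 10)
    low, high = order[:k], order[-k:]
    return [
        (int(rng.choice(high)), int(rng.choice(low)))
        for _ in range(n_catch)
    ]


def run_trial(
    state: ChainState,
    graph: ProposalGraph,
    spec: ProposalSpec,
    oracle: ChoiceOracle,
    rng: np.random.Generator,
    participant_id: str = "p000",
    session_index: int = 0,
    trial_index: int = 0,
) -> TrialRecord:
    """Execute one chain trial, advancing ``state`` in place.

    A proposal equal to the current state is redrawn (two identical options
    would make the question meaningless), up to ``PROPOSAL_RETRY_LIMIT``
    attempts.
    """
    current = state.current
    proposal = current
    for _ in range(PROPOSAL_RETRY_LIMIT):
        proposal = mixture_proposal(graph, current, spec, rng)
        if proposal != current:
            break
    else:
        raise StuckProposalError(
            f"no proposal distinct from state {current} after {PROPOSAL_RETRY_LIMIT} draws"
        )
    left, right = (current, proposal) if rng.random() < 0.5 else (proposal, current)
    chosen = oracle.choose(current, proposal, state.category)
    if chosen not in (current, proposal):
        raise InvalidArgumentError(f"oracle returned {chosen}, not one of the offered items")
    ids = graph.item_ids
    record = TrialRecord(
        participant_id=participant_id,
        session_index=session_index,
        trial_index=trial_index,
        trial_type="chain",
        chain_id=state.chain_id,
        category=state.category,
        current_id=ids[current],
        proposal_id=ids[proposal],
        left_id=ids[left],
        right_id=ids[right],
        chosen_id=ids[chosen],
    )
    state.current = chosen
    state.history.append(chosen)
    return record


def _practice_record(
    config: SessionConfig,
    graph: ProposalGraph,
    oracle: ChoiceOracle,
    rng: np.random.Generator,
    category: str,
    participant_id: str,
    session_index: int,
    trial_index: int,
) -> TrialRecord:
    a = int(rng.integers(graph.n))
    b = int(rng.integers(graph.n - 1))
    if b >= a:
        b += 1
    left, right = (a, b) if rng.random() < 0.5 else (b, a)
    chosen = oracle.choose(a, b, category)
    ids = graph.item_ids
    return TrialRecord(
        participant_id, session_index, trial_index, "practice", "-", category,
        ids[a], ids[b], ids[left], ids[right], ids[chosen],
    )


def _catch_record(
    graph: ProposalGraph,
    oracle: ChoiceOracle,
    rng: np.random.Generator,
    pair: tuple[int, int],
    category: str,
    participant_id: str,
    session_index: int,
    trial_index: int,
) -> TrialRecord:
    correct, foil = pair
    left, right = (correct, foil) if rng.random() < 0.5 else (foil, correct)
    chosen = oracle.choose(correct, foil, category)
    ids = graph.item_ids
    return TrialRecord(
        participant_id, session_index, trial_index, "catch", "-", category,
        ids[correct], ids[foil], ids[left], ids[right], ids[chosen],
        correct_id=ids[correct],
    )


def run_session(
    config: SessionConfig,
    graph: ProposalGraph,
    oracle: ChoiceOracle,
    init_states: dict[str, int] | None = None,
    catch_pairs: list[tuple[int, int]] | None = None,
    participant_id: str = "p000",
    session_index: int = 0,
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Run one participant's full session and return the ordered trial log.

    Practice trials come first, then chain trials interleaved round-robin over
    chains with catch trials inserted at seeded uniform-random positions.
    Practice and catch trials never advance any chain.  ``init_states`` maps
    chain id to a starting item index; missing chains start at a
    uniform-random item (an arbitrary initial state is all the sampler needs).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, session_index])
    if config.n_catch > 0 and not catch_pairs:
        raise ConfigError("session has catch trials but no catch pairs were provided")
    init_states = dict(init_states or {})
    unknown = set(init_states) - set(config.chain_ids)
    if unknown:
        raise ConfigError(f"init_states name unknown chains: {sorted(unknown)}")
    states: dict[str, ChainState] = {}
    for cat in config.categories:
        for k in range(config.chains_per_category):
            cid = f"{cat}-{k}"
            start = init_states.get(cid, int(rng.integers(graph.n)))
            if not 0 <= start < graph.n:
                raise ConfigError(f"initial state {start} for chain {cid} is out of range")
            states[cid] = ChainState(chain_id=cid, category=cat, current=start)

    log: list[TrialRecord] = []
    trial_index = 0
    for i in range(config.n_practice):
        category = config.categories[i % len(config.categories)]
        log.append(
            _practice_record(config, graph, oracle, rng, category,
                             participant_id, session_index, trial_index)
        )
        trial_index += 1

    n_main = config.n_chains * config.trials_per_chain
    slots = ["chain"] * n_main
    if config.n_catch > 0:
        positions = rng.choice(n_main + config.n_catch, size=config.n_catch, replace=False)
        for pos in sorted(positions):
            slots.insert(pos, "catch")
    chain_cursor = 0
    catch_cursor = 0
    for slot in slots:
        if slot == "chain":
            cid = config.chain_ids[chain_cursor % config.n_chains]
            chain_cursor += 1
            log.append(
                run_trial(states[cid], graph, config.proposal, oracle, rng,
                          participant_id, session_index, trial_index)
            )
        else:
            pair = catch_pairs[catch_cursor % len(catch_pairs)]
            category = config.categories[catch_cursor % len(config.categories)]
            catch_cursor += 1
            log.append(
                _catch_record(graph, oracle, rng, pair, category,
                              participant_id, session_index, trial_index)
            )
        trial_index += 1
    return log


def final_chain_states(log: list[TrialRecord], graph: ProposalGraph) -> dict[str, int]:
    """Last state of each chain in a log (the chosen item of its last chain trial)."""
    index = {item: i for i, item in enumerate(graph.item_ids)}
    finals: dict[str, int] = {}
    for rec in log:
        if rec.trial_type == "chain":
            finals[rec.chain_id] = index[rec.chosen_id]
    return finals


def link_sessions(
    prev_log: list[TrialRecord],
    config: SessionConfig,
    graph: ProposalGraph,
    oracle: ChoiceOracle,
    catch_pairs: list[tuple[int, int]] | None = None,
    participant_id: str | None = None,
    session_index: int | None = None,
) -> list[TrialRecord]:
    """Run the next participant's session starting where the previous one left off."""
    finals = final_chain_states(prev_log, graph)
    if set(finals) != set(config.chain_ids):
        raise ConfigError(
            f"cannot link: previous log has chains {sorted(finals)}, "
            f"config expects {sorted(config.chain_ids)}"
        )
    if session_index is None:
        session_index = max(r.session_index for r in prev_log) + 1
    if participant_id is None:
        participant_id = f"p{session_index:03d}"
    return run_session(
        config, graph, oracle,
        init_states=finals, catch_pairs=catch_pairs,
        participant_id=participant_id, session_index=session_index,
    )


def run_linked_sessions(
    config: SessionConfig,
    graph: ProposalGraph,
    oracle: ChoiceOracle,
    n_sessions: int,
    catch_pairs: list[tuple[int, int]] | None = None,
) -> list[TrialRecord]:
    """Chain ``n_sessions`` sessions end to end; returns the concatenated log."""
    if n_sessions < 1:
        raise ConfigError("need at least one session")
    log = run_session(config, graph, oracle, catch_pairs=catch_pairs,
                      participant_id="p000", session_index=0)
    full = list(log)
    for _ in range(n_sessions - 1):
        log = link_sessions(log, config, graph, oracle, catch_pairs=catch_pairs)
        full.extend(log)
    return full


@dataclass
class CatchResult:
    passed: bool
    n_correct: int
    n_catch: int


def catch_exclusion(log: list[TrialRecord], threshold: int) -> CatchResult:
    """Apply the attention criterion: pass iff >= ``threshold`` catch trials correct."""
    catches = [r for r in log if r.trial_type == "catch"]
    if not catches and threshold > 0:
        raise ConfigError("log contains no catch trials but the threshold is positive")
    n_correct = sum(1 for r in catches if r.chosen_id == r.correct_id)
    return CatchResult(passed=n_correct >= threshold, n_correct=n_correct, n_catch=len(catches))


def binomial_catch_threshold(n_catch: int, alpha: float) -> int:
    """Smallest k with P(Binomial(n_catch, 1/2) >= k) < alpha, by exact tail summation.

    This is the principled counterpart to a hand-set pass threshold: a
    responder guessing at random clears k or more catch trials with
    probability below alpha.
    """
    if n_catch < 1:
        raise InvalidArgumentError("need at least one catch trial")
    if not 0.0 < alpha < 1.0:
        raise InvalidArgumentError("alpha must lie in (0, 1)")
    denom = 2**n_catch
    alpha_exact = Fraction(alpha)
    tail = denom  # sum_{i >= 0} C(n, i)
    for k in range(n_catch + 2):
        if Fraction(tail, denom) < alpha_exact:
            return k
        if k <= n_catch:
            tail -= comb(n_catch, k)
    return n_catch + 1  # pragma: no cover - loop always returns
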