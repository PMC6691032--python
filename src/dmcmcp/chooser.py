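"""Choice oracles: who (or what) answers "which is the better category member?".

The sampler's acceptance step is a two-alternative forced choice.  When the
chooser follows the ratio (Luce) rule,

    P(choose x' over x) = p(x'|c) / (p(x'|c) + p(x|c)),

the choice is exactly the Barker acceptance function, so the chain converges
to p(x|c).  More deterministic responders are modelled by exponentiating each
strength by gamma, in which case the chain converges to p^gamma renormalized —
item *ordering* is preserved even when gamma is unknown.

Implementations: :class:`SimulatedChooser` (draws from the exponentiated Luce
rule given a known target — the simulation workhorse) and
:class:`ReplayChooser` (replays recorded human sessions through the engine).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import (
    EndOfLogError,
    InvalidArgumentError,
    ReplayDesyncError,
)
from .fixtures import TargetDistribution
from .util import as_rng

__all__ = ["ChoiceOracle", "luce_choice_prob", "SimulatedChooser", "ReplayChooser"]


@runtime_checkable
class ChoiceOracle(Protocol):
    """Anything that picks one of two offered items for a category."""

    stochastic: bool

    def choose(self, current: int, proposal: int, category: str) -> int:
        """Return one of ``current`` / ``proposal`` (as item indices)."""
        ...


def luce_choice_prob(p_current: float, p_proposal: float, gamma: float = 1.0) -> float:
    """Probability of choosing the proposal under the exponentiated Luce rule.

    Returns ``p_proposal**gamma / (p_proposal**gamma + p_current**gamma)``.
    If exactly one option has probability 0 it is never chosen (regardless of
    gamma); both zero is an error — a degenerate target should fail loudly,
    not coin-flip.
    """
    if p_current < 0 or p_proposal < 0:
        raise InvalidArgumentError("choice strengths must be nonnegative")
    if gamma < 0:
        raise InvalidArgumentError("gamma must be nonnegative")
    if p_current == 0 and p_proposal == 0:
        raise InvalidArgumentError("both options have zero probability; choice undefined")
    if p_proposal == 0:
        return 0.0
    if p_current == 0:
        return 1.0
    if gamma == 0:
        return 0.5
    # ratio form for numerical stability at large gamma or tiny probabilities
    log_ratio = gamma * (math.log(p_current) - math.log(p_proposal))
    if log_ratio > 700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(log_ratio))


@dataclass
class SimulatedChooser:
    """A Luce-rule responder with a known target distribution.

    ``gamma`` models responder determinism: 1 is probability matching, larger
    values are more deterministic, 0 is pure guessing.  The exponent is a
    property of the decision-maker, so it lives here and not on the engine —
    the engine never needs to know it.
    """

    target: TargetDistribution
    gamma: float = 1.0
    seed: int | np.random.Generator = 0
    stochastic: bool = field(default=True, init=False)

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise InvalidArgumentError("gamma must be nonnegative")
        self._rng = as_rng(self.seed)

    def _check(self, idx: int) -> None:
        if not 0 <= idx < self.target.n_items:
            raise InvalidArgumentError(
                f"item index {idx} outside the target universe (n={self.target.n_items})"
            )

    def choose(self, current: int, proposal: int, category: str = "") -> int:
        self._check(current)
        self._check(proposal)
        if current == proposal:
            return current
        prob = luce_choice_prob(
            float(self.target.probs[current]), float(self.target.probs[proposal]), self.gamma
        )
        return proposal if self._rng.random() < prob else current


class ReplayChooser:
    """Replays a recorded session: answers each offered pair with the logged choice.

    Matching against the log is order-insensitive in the pair (the engine may
    present (x, x') where the log stored (x', x)), but any genuine mismatch
    raises :class:`ReplayDesyncError` with both positions so desyncs are
    debuggable rather than silent.
    """

    stochastic = False

    def __init__(self, records: Sequence, item_ids: Sequence[str]):
        self._records = list(records)
        self._index = {item: i for i, item in enumerate(item_ids)}
        self._ids = list(item_ids)
        self.cursor = 0

    def choose(self, current: int, proposal: int, category: str = "") -> int:
        if self.cursor >= len(self._records):
            raise EndOfLogError(f"replay log exhausted after {self.cursor} records")
        rec = self._records[self.cursor]
        offered = {self._ids[current], self._ids[proposal]}
        logged = {rec.current_id, rec.proposal_id}
        if offered != logged:
            raise ReplayDesyncError(
                f"at log position {self.cursor}: engine offered {sorted(offered)}, "
                f"log recorded {sorted(logged)}"
            )
        self.cursor += 1
        return self._index[rec.chosen_id]
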