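"""Proposal generation: random walks on the proposal graph.

The q(x'; x) of the sampler.  Three schemes, all mixed with a small uniform
jump:

* ``uniform_neighbor`` — propose uniformly among the current node's
  neighbours;
* ``geometric_walk`` — draw a step count k from a geometric distribution on
  {1, 2, ...} and walk k uniform-neighbour steps, proposing the endpoint
  (which widens exploration beyond immediate neighbours);
* with probability ``jump_prob`` (0.10 in the reference sessions), ignore the
  graph and propose an item uniformly at random, which guarantees
  irreducibility and aperiodicity and lets the chain hop between modes.

On a degree-regular graph every one of these proposal distributions is
symmetric, which is what the pairwise-choice acceptance rule requires;
:func:`proposal_distribution` enumerates Q exactly on small graphs so the
symmetry can be checked rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bmatching import ProposalGraph
from .errors import InvalidArgumentError
from .util import as_rng

__all__ = [
    "ProposalSpec",
    "uniform_neighbor_proposal",
    "geometric_walk_proposal",
    "mixture_proposal",
    "ProposalMatrix",
    "proposal_distribution",
]

#: proposal_distribution refuses graphs larger than this (exact enumeration only).
ENUMERATION_SIZE_LIMIT = 512


@dataclass(frozen=True)
class ProposalSpec:
    """Configuration of the proposal scheme.

    ``geom_param`` is the success probability of the geometric step-count
    distribution (support {1, 2, ...}); it is ignored for
    ``uniform_neighbor``.  ``jump_prob`` is the probability of a global
    uniform jump, drawn before the base proposal.
    """

    kind: str = "uniform_neighbor"
    geom_param: float = 0.5
    jump_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_neighbor", "geometric_walk"):
            raise InvalidArgumentError(f"unknown proposal kind {self.kind!r}")
        if not 0.0 <= self.jump_prob <= 1.0:
            raise InvalidArgumentError("jump_prob must lie in [0, 1]")
        if self.kind == "geometric_walk" and not 0.0 < self.geom_param <= 1.0:
            raise InvalidArgumentError("geom_param must lie in (0, 1]")


def _neighbors_or_raise(graph: ProposalGraph, x: int) -> np.ndarray:
    nbrs = graph.neighbors(x)
    if len(nbrs) == 0:
        raise InvalidArgumentError(
            f"node {x} is isolated; validate the graph before running a chain"
        )
    return nbrs


def uniform_neighbor_proposal(
    graph: ProposalGraph, x: int, rng: int | np.random.Generator
) -> int:
    """One uniform draw from the neighbours of ``x`` (never ``x`` itself)."""
    rng = as_rng(rng)
    nbrs = _neighbors_or_raise(graph, x)
    return int(nbrs[rng.integers(len(nbrs))])


def geometric_walk_proposal(
    graph: ProposalGraph, x: int, geom_param: float, rng: int | np.random.Generator
) -> int:
    """Endpoint of a k-step uniform random walk, k ~ Geometric(geom_param) on {1, 2, ...}.

    The endpoint may equal ``x`` (the walk can return); callers that need a
    distinct proposal redraw.  ``geom_param=1`` degenerates to a single step,
    i.e. :func:`uniform_neighbor_proposal`.
    """
    if not 0.0 < geom_param <= 1.0:
        raise InvalidArgumentError("geom_param must lie in (0, 1]")
    rng = as_rng(rng)
    steps = int(rng.geometric(geom_param))
    node = x
    for _ in range(steps):
        nbrs = _neighbors_or_raise(graph, node)
        node = int(nbrs[rng.integers(len(nbrs))])
    return node


def mixture_proposal(
    graph: ProposalGraph, x: int, spec: ProposalSpec, rng: int | np.random.Generator
) -> int:
    """Jump-with-probability-epsilon mixture over the base proposal.

    The jump branch is drawn first; a jump proposes uniformly over *all*
    items, possibly ``x`` itself.
    """
    rng = as_rng(rng)
    if graph.n < 2:
        raise InvalidArgumentError("need at least 2 items to propose")
    if spec.jump_prob > 0 and rng.random() < spec.jump_prob:
        return int(rng.integers(graph.n))
    if spec.kind == "uniform_neighbor":
        return uniform_neighbor_proposal(graph, x, rng)
    return geometric_walk_proposal(graph, x, spec.geom_param, rng)


@dataclass
class ProposalMatrix:
    """Exactly enumerated proposal distribution Q plus truncation bookkeeping."""

    Q: np.ndarray
    truncated_mass: float
    truncation_warning: bool


def proposal_distribution(
    graph: ProposalGraph, spec: ProposalSpec, truncation: int = 64
) -> ProposalMatrix:
    """Enumerate Q[x, x'] exactly for small graphs.

    The single-step walk matrix is ``W[x, y] = A[x, y] / deg(x)``; the
    geometric scheme gives ``Q_base = sum_k p (1-p)^(k-1) W^k`` truncated at
    ``truncation`` steps (remaining mass ``(1-p)^truncation`` is reported, and
    flagged if it exceeds 1e-6).  The uniform jump then mixes in as
    ``Q = (1-eps) Q_base + eps/n``.  Rows sum to 1 up to the truncated mass.
    """
    n = graph.n
    if n > ENUMERATION_SIZE_LIMIT:
        raise InvalidArgumentError(
            f"exact enumeration is limited to n <= {ENUMERATION_SIZE_LIMIT} (got n={n})"
        )
    degrees = graph.degrees().astype(float)
    if np.any(degrees == 0):
        raise InvalidArgumentError("graph has isolated nodes; Q is undefined there")
    W = graph.adjacency.astype(float) / degrees[:, None]
    if spec.kind == "uniform_neighbor":
        Q_base = W
        truncated = 0.0
    else:
        p = spec.geom_param
        Q_base = np.zeros((n, n))
        Wk = np.eye(n)
        weight = p
        for _ in range(truncation):
            Wk = Wk @ W
            Q_base += weight * Wk
            weight *= 1.0 - p
        truncated = (1.0 - p) ** truncation
    eps = spec.jump_prob
    Q = (1.0 - eps) * Q_base + eps / n
    return ProposalMatrix(Q=Q, truncated_mass=(1.0 - eps) * truncated,
                          truncation_warning=(1.0 - eps) * truncated > 1e-6)
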