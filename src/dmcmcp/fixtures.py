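"""Synthetic stimulus sets and ground-truth targets.

Pairwise-choice chains are normally driven by human participants looking at a
real database of images or words.  For development, testing and simulation we
need stimulus sets whose subjective category distribution is *known*, so that
chain output can be compared against ground truth.  This module generates such
fixtures: random low-dimensional feature clouds, mixture-of-Gaussian target
distributions over them (unimodal, bimodal, or uniform), and controlled
degradations of a similarity matrix for robustness studies.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .util import as_rng

__all__ = [
    "StimulusSet",
    "TargetDistribution",
    "make_stimuli",
    "make_target_distribution",
    "perturb_similarity",
    "ring_proposal_graph",
]


@dataclass
class StimulusSet:
    """A discrete universe of candidate category members.

    Parameters
    ----------
    item_ids
        Ordered, unique identifiers.  All other per-item arrays in the package
        (features, similarity rows, target probabilities) follow this order.
    features
        Optional ``(n, d)`` float array of per-item feature vectors.
    category_tags
        Optional per-item label (e.g. a moral foundation or a season),
        keyed by item id.
    pixel_data
        Optional per-item small RGB raster (``(h, w, 3)`` uint8 arrays),
        keyed by item id; used by the color-histogram similarity path.
    """

    item_ids: list[str]
    features: np.ndarray | None = None
    category_tags: dict[str, str] | None = None
    pixel_data: dict[str, np.ndarray] | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.item_ids = list(self.item_ids)
        if len(set(self.item_ids)) != len(self.item_ids):
            raise InvalidArgumentError("item_ids must be unique")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.ndim != 2 or self.features.shape[0] != len(self.item_ids):
                raise InvalidArgumentError(
                    "features must be a 2-d array with one row per item "
                    f"(got shape {self.features.shape} for {len(self.item_ids)} items)"
                )
        self._index = {item: i for i, item in enumerate(self.item_ids)}

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def index_of(self, item_id: str) -> int:
        return self._index[item_id]

    def __len__(self) -> int:
        return self.n_items

    def __iter__(self):
        return iter(self.item_ids)


@dataclass
class TargetDistribution:
    """A (possibly subjective) probability distribution p(x|c) over items.

    ``gamma`` is the choice-rule exponent carried alongside the distribution:
    a chain driven by an exponentiated-Luce chooser converges to
    ``probs**gamma`` renormalized, which :meth:`exponentiated` computes.
    """

    probs: np.ndarray
    gamma: float = 1.0
    item_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1:
            raise InvalidArgumentError("probs must be a 1-d vector")
        if np.any(self.probs < 0):
            raise InvalidArgumentError("probs must be nonnegative")
        total = self.probs.sum()
        if total <= 0:
            raise InvalidArgumentError("probs must have positive total mass")
        if abs(total - 1.0) > 1e-9:
            self.probs = self.probs / total
        if self.gamma < 0:
            raise InvalidArgumentError("gamma must be nonnegative")

    @property
    def n_items(self) -> int:
        return self.probs.shape[0]

    def exponentiated(self, gamma: float | None = None) -> np.ndarray:
        """Return ``probs**gamma`` renormalized (the chain's actual stationary law)."""
        g = self.gamma if gamma is None else gamma
        p = np.power(self.probs, g)
        return p / p.sum()


def make_stimuli(n: int, d: int, seed: int | np.random.Generator = 0) -> StimulusSet:
    """Generate ``n`` items with i.i.d. standard-normal features in ``d`` dimensions.

    Item ids are ``item0000 ... item{n-1}``.  Identical seeds give identical
    feature matrices.
    """
    if n < 2:
        raise InvalidArgumentError(f"need at least 2 items for a chain, got n={n}")
    if d < 1:
        raise InvalidArgumentError(f"feature dimension must be >= 1, got d={d}")
    rng = as_rng(seed)
    features = rng.standard_normal((n, d))
    ids = [f"item{i:04d}" for i in range(n)]
    return StimulusSet(item_ids=ids, features=features)


def make_target_distribution(
    stimuli: StimulusSet,
    kind: str = "bimodal",
    modes: list[np.ndarray] | None = None,
    width: float = 1.0,
    gamma: float = 1.0,
) -> TargetDistribution:
    """Build a ground-truth category distribution over a stimulus set.

    ``kind``:

    * ``"uniform"`` — 1/n per item; needs no features.
    * ``"unimodal"`` / ``"bimodal"`` — probabilities proportional to a
      mixture of isotropic Gaussian kernels of bandwidth ``width`` centred at
      ``modes`` (one centre for unimodal, two or more for bimodal), evaluated
      at each item's feature vector.  Defaults: unimodal centres at the
      feature-space origin; bimodal centres at ±2 along the first axis.

    Mixture kinds emulate the structured — and possibly multimodal — category
    representations the sampler is meant to recover.
    """
    n = stimuli.n_items
    if kind == "uniform":
        return TargetDistribution(np.full(n, 1.0 / n), gamma=gamma, item_ids=stimuli.item_ids)
    if kind not in ("unimodal", "bimodal"):
        raise InvalidArgumentError(f"unknown target kind {kind!r}")
    if stimuli.features is None:
        raise InvalidArgumentError(f"kind={kind!r} requires stimuli with features")
    d = stimuli.features.shape[1]
    if modes is None:
        if kind == "unimodal":
            modes = [np.zeros(d)]
        else:
            lo, hi = np.zeros(d), np.zeros(d)
            lo[0], hi[0] = -2.0, 2.0
            modes = [lo, hi]
    if len(modes) == 0:
        raise InvalidArgumentError("mixture kinds need at least one mode centre")
    if kind == "unimodal" and len(modes) != 1:
        raise InvalidArgumentError("unimodal target takes exactly one mode centre")
    if kind == "bimodal" and len(modes) < 2:
        raise InvalidArgumentError("bimodal target needs at least two mode centres")
    if width <= 0:
        raise InvalidArgumentError("kernel width must be positive")
    density = np.zeros(n)
    for centre in modes:
        centre = np.asarray(centre, dtype=float)
        if centre.shape != (d,):
            raise InvalidArgumentError(
                f"mode centre shape {centre.shape} does not match feature dimension {d}"
            )
        sq = np.sum((stimuli.features - centre) ** 2, axis=1)
        density += np.exp(-sq / (2.0 * width**2))
    return TargetDistribution(density, gamma=gamma, item_ids=stimuli.item_ids)


def perturb_similarity(
    S: np.ndarray, noise_level: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Add symmetric zero-mean Gaussian noise to a similarity matrix.

    The noise standard deviation is ``noise_level`` times the standard
    deviation of the off-diagonal entries of ``S``, which makes
    ``noise_level`` unit-free: 1 means "noise as large as the signal's own
    spread".  The diagonal is left untouched and the output is exactly
    symmetric.  Used to study how sampler efficiency degrades when the
    similarity assumed for graph construction drifts from the truth.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidArgumentError("S must be square")
    if not np.allclose(S, S.T, atol=1e-9):
        raise InvalidArgumentError("S must be symmetric")
    if noise_level < 0:
        raise InvalidArgumentError("noise_level must be nonnegative")
    if noise_level == 0:
        return S.copy()
    rng = as_rng(seed)
    n = S.shape[0]
    off = ~np.eye(n, dtype=bool)
    scale = noise_level * float(np.std(S[off]))
    noise = np.zeros_like(S)
    iu = np.triu_indices(n, k=1)
    noise[iu] = rng.standard_normal(len(iu[0])) * scale
    noise = noise + noise.T
    out = S + noise
    np.fill_diagonal(out, np.diag(S))
    return out


def ring_proposal_graph(stimuli: StimulusSet, b: int):
    """Deterministic, exactly b-regular, connected fixture graph.

    Items are sorted by their first feature coordinate and placed on a ring;
    each node is joined to its ``b/2`` nearest ring neighbours on either side.
    For low-dimensional fixtures this aligns edges with feature similarity
    while guaranteeing exact regularity and connectivity — properties the
    approximate matcher only achieves approximately.  Requires even ``b`` with
    ``b < n``.
    """
    from .bmatching import ProposalGraph  # local import to avoid a cycle

    if stimuli.features is None:
        raise InvalidArgumentError("ring_proposal_graph requires stimuli with features")
    n = stimuli.n_items
    if b % 2 != 0 or not (0 < b < n):
        raise InvalidArgumentError(f"ring graph needs even b in (0, n); got b={b}, n={n}")
    order = np.argsort(stimuli.features[:, 0], kind="stable")
    adjacency = np.zeros((n, n), dtype=np.int8)
    for pos in range(n):
        for step in range(1, b // 2 + 1):
            i, j = order[pos], order[(pos + step) % n]
            adjacency[i, j] = adjacency[j, i] = 1
    return ProposalGraph(adjacency=adjacency, b=b, item_ids=list(stimuli.item_ids))
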