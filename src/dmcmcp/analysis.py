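"""Turning trial logs into distribution estimates and convergence diagnostics.

Once a chain has mixed, the items it visits are samples from the (possibly
exponentiated) category distribution, so the basic estimator is simply the
normalized visit count.  The diagnostics mirror how such chains are usually
examined: cumulative feature averages over a sliding window, L1 distances
between cumulative histograms of different chains (within-category distances
should fall below between-category ones as chains converge), per-tag choice
proportions, and top-k most-chosen items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .chain import TrialRecord
from .errors import EmptySampleError, InvalidArgumentError, TaggingError

__all__ = [
    "EmpiricalDistribution",
    "empirical_distribution",
    "sliding_cumulative_average",
    "l1_histogram_distance",
    "within_between_convergence",
    "category_frequency",
    "top_k_items",
    "log_spaced_eval_points",
]


@dataclass
class EmpiricalDistribution:
    """Normalized post-burn-in visit frequencies over the item universe."""

    item_ids: list[str]
    freqs: np.ndarray
    n_samples: int
    burn_in: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.freqs < 0) or abs(self.freqs.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("frequencies must be nonnegative and sum to 1")


def _chain_trials(log: Sequence[TrialRecord]) -> list[TrialRecord]:
    return [r for r in log if r.trial_type == "chain"]


def _by_chain(log: Sequence[TrialRecord]) -> dict[str, list[TrialRecord]]:
    chains: dict[str, list[TrialRecord]] = {}
    for rec in _chain_trials(log):
        chains.setdefault(rec.chain_id, []).append(rec)
    return chains


def empirical_distribution(
    log: Sequence[TrialRecord],
    item_ids: Sequence[str],
    burn_in: int = 0,
    count_mode: str = "choices",
) -> EmpiricalDistribution:
    """Estimate the category distribution from a trial log.

    ``burn_in`` chain trials are dropped from the start of *each* chain.
    ``count_mode="choices"`` counts the chosen item of every remaining chain
    trial; ``"states"`` counts the chain's post-trial states.  Because the
    state after a trial *is* the chosen item, the two coincide on chain
    trials; both ignore practice and catch trials (which never advance a
    chain).  The distinction is kept for callers thinking in sampler terms
    versus choice-count terms.
    """
    if count_mode not in ("choices", "states"):
        raise InvalidArgumentError(f"unknown count_mode {count_mode!r}")
    if burn_in < 0:
        raise InvalidArgumentError("burn_in must be nonnegative")
    index = {item: i for i, item in enumerate(item_ids)}
    counts = np.zeros(len(index))
    n_samples = 0
    for chain_log in _by_chain(log).values():
        for rec in chain_log[burn_in:]:
            counts[index[rec.chosen_id]] += 1
            n_samples += 1
    if n_samples == 0:
        raise EmptySampleError(f"no chain trials survive burn_in={burn_in}")
    return EmpiricalDistribution(
        item_ids=list(item_ids), freqs=counts / n_samples,
        n_samples=n_samples, burn_in=burn_in,
    )


def log_spaced_eval_points(n_trials: int, n_points: int = 40) -> np.ndarray:
    """Unique integer trial counts on a log grid from 1 to ``n_trials``."""
    if n_trials < 1:
        raise InvalidArgumentError("need at least one trial")
    pts = np.unique(np.round(np.logspace(0, np.log10(n_trials), n_points)).astype(int))
    return pts[(pts >= 1) & (pts <= n_trials)]


def sliding_cumulative_average(
    log: Sequence[TrialRecord],
    features: np.ndarray,
    item_ids: Sequence[str],
    window: int = 50,
    eval_points: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean feature vector of recently chosen items, at log-spaced trial counts.

    At eval point t the average runs over the chosen items of trials
    max(1, t-window+1)..t — i.e. the ``window`` most recent trials, or all
    trials so far when fewer than ``window`` have happened.  Returns
    ``(eval_points, means)`` with one row of ``means`` per eval point.
    """
    if window < 1:
        raise InvalidArgumentError("window must be >= 1")
    trials = _chain_trials(log)
    if not trials:
        raise EmptySampleError("log contains no chain trials")
    index = {item: i for i, item in enumerate(item_ids)}
    chosen = np.array([index[r.chosen_id] for r in trials])
    n = len(chosen)
    if eval_points is None:
        eval_points = log_spaced_eval_points(n)
    eval_points = np.asarray(eval_points, dtype=int)
    if eval_points.min() < 1 or eval_points.max() > n:
        raise InvalidArgumentError(
            f"eval points must lie in [1, {n}], got range "
            f"[{eval_points.min()}, {eval_points.max()}]"
        )
    feats = np.asarray(features, dtype=float)
    means = np.empty((len(eval_points), feats.shape[1]))
    for row, t in enumerate(eval_points):
        start = max(0, t - window)
        means[row] = feats[chosen[start:t]].mean(axis=0)
    return eval_points, means


def l1_histogram_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """Sum of absolute bin differences; 2 means fully displaced normalized mass."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise InvalidArgumentError(f"histogram shapes differ: {h1.shape} vs {h2.shape}")
    return float(np.abs(h1 - h2).sum())


def _cumulative_item_histogram(item_ids: Sequence[str]):
    """Default histogram_fn: normalized item-frequency vector of a choice prefix."""
    index = {item: i for i, item in enumerate(item_ids)}

    def hist(chosen_ids: Sequence[str]) -> np.ndarray:
        counts = np.zeros(len(index))
        for c in chosen_ids:
            counts[index[c]] += 1
        return counts / counts.sum()

    return hist


def within_between_convergence(
    log: Sequence[TrialRecord],
    histogram_fn: Callable[[Sequence[str]], np.ndarray] | None = None,
    item_ids: Sequence[str] | None = None,
    eval_points: Sequence[int] | None = None,
) -> dict:
    """Within- vs between-category L1 distance of cumulative chain histograms.

    For each eval point t, a histogram is computed from the first t choices of
    every chain (via ``histogram_fn``, e.g. a color histogram of chosen
    images; defaults to the normalized item-frequency vector, which needs
    ``item_ids``).  The curves report the mean pairwise L1 distance between
    chains of the same category and between each pair of distinct categories.
    Converging chains show the within curve falling below the between curves.
    """
    chains = _by_chain(log)
    by_cat: dict[str, list[str]] = {}
    for cid, recs in chains.items():
        by_cat.setdefault(recs[0].category, []).append(cid)
    if len(by_cat) < 2:
        raise InvalidArgumentError("need chains in at least two categories")
    for cat, cids in by_cat.items():
        if len(cids) < 2:
            raise InvalidArgumentError(
                f"category {cat!r} has a single chain; within-category distance undefined"
            )
    if histogram_fn is None:
        if item_ids is None:
            raise InvalidArgumentError("default histogram needs item_ids")
        histogram_fn = _cumulative_item_histogram(item_ids)
    min_len = min(len(recs) for recs in chains.values())
    if eval_points is None:
        eval_points = log_spaced_eval_points(min_len)
    eval_points = np.asarray(eval_points, dtype=int)
    if eval_points.max() > min_len:
        raise InvalidArgumentError(
            f"eval point {eval_points.max()} exceeds shortest chain length {min_len}"
        )

    cats = sorted(by_cat)
    within = {cat: [] for cat in cats}
    between = {(a, b): [] for i, a in enumerate(cats) for b in cats[i + 1:]}
    for t in eval_points:
        hists = {
            cid: histogram_fn([r.chosen_id for r in recs[:t]])
            for cid, recs in chains.items()
        }
        for cat in cats:
            cids = by_cat[cat]
            ds = [
                l1_histogram_distance(hists[a], hists[b])
                for i, a in enumerate(cids) for b in cids[i + 1:]
            ]
            within[cat].append(float(np.mean(ds)))
        for (a, b) in between:
            ds = [
                l1_histogram_distance(hists[x], hists[y])
                for x in by_cat[a] for y in by_cat[b]
            ]
            between[(a, b)].append(float(np.mean(ds)))
    return {
        "eval_points": eval_points,
        "within": {cat: np.array(v) for cat, v in within.items()},
        "between": {pair: np.array(v) for pair, v in between.items()},
    }


def category_frequency(
    log: Sequence[TrialRecord], item_category_map: dict[str, str]
) -> dict[str, float]:
    """Proportion of chain-trial choices landing in each item tag, summing to 1."""
    counts: dict[str, int] = {}
    total = 0
    for rec in _chain_trials(log):
        if rec.chosen_id not in item_category_map:
            raise TaggingError(f"chosen item {rec.chosen_id!r} has no category tag")
        tag = item_category_map[rec.chosen_id]
        counts[tag] = counts.get(tag, 0) + 1
        total += 1
    if total == 0:
        raise EmptySampleError("log contains no chain trials")
    return {tag: c / total for tag, c in sorted(counts.items())}


@dataclass
class TopKResult:
    items: list[tuple[str, int]]  # (item_id, choice count), descending
    short_list: bool  # True when fewer distinct items than requested


def top_k_items(log: Sequence[TrialRecord], k: int) -> TopKResult:
    """The k most-chosen items with counts; ties break toward the lower item id."""
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    counts: dict[str, int] = {}
    for rec in _chain_trials(log):
        counts[rec.chosen_id] = counts.get(rec.chosen_id, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return TopKResult(items=ranked[:k], short_list=len(ranked) < k)
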