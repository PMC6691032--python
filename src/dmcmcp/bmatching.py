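"""Degree-constrained proposal graphs via maximum-weight b-matching.

A random walk only yields a *symmetric* proposal distribution when every node
has the same degree, so the proposal graph is chosen to maximise total edge
similarity subject to each node having degree b (no self-edges, undirected):

    max_G  sum_{i<j} G_ij S_ij   s.t.  sum_j G_ij = b,  G_ii = 0,  G_ij = G_ji.

Two solvers are provided:

* :func:`bmatch_exact` — brute-force enumeration with pruning, capped at a
  small documented instance size.  It exists as a test oracle, not for
  production scale.
* :func:`bmatch_message_passing` — a max-product belief-propagation scheme in
  which each node repeatedly scores candidate partners and keeps its b best;
  mutual selections become edges.  Output degrees can deviate slightly from b,
  so a degree report travels with the graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import InfeasibleMatchingError, InvalidArgumentError, SizeLimitError
from .util import as_rng

__all__ = [
    "ProposalGraph",
    "GraphValidationReport",
    "bmatch_exact",
    "bmatch_message_passing",
    "largest_connected_component",
    "validate_graph",
]

#: bmatch_exact refuses instances larger than this many nodes.
EXACT_SIZE_LIMIT = 12


@dataclass
class ProposalGraph:
    """Undirected proposal graph: binary adjacency, target degree b, item ordering."""

    adjacency: np.ndarray
    b: int
    item_ids: list[str]
    degree_report: dict | None = None
    converged: bool | None = None
    #: indices into the graph this one was extracted from (component extraction)
    original_indices: np.ndarray | None = None
    _neighbors: list[np.ndarray] | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        if self.adjacency.ndim != 2 or self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise InvalidArgumentError("adjacency must be square")
        if self.adjacency.shape[0] != len(self.item_ids):
            raise InvalidArgumentError("adjacency size does not match item_ids")
        self.adjacency = (self.adjacency != 0).astype(np.int8)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbour indices of node ``i`` (cached after first use)."""
        if self._neighbors is None:
            self._neighbors = [np.flatnonzero(self.adjacency[k]) for k in range(self.n)]
        return self._neighbors[i]

    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))

    def objective(self, S: np.ndarray) -> float:
        """Total similarity along edges, counting each unordered pair once."""
        S = np.asarray(S, dtype=float)
        return float((np.triu(self.adjacency, 1) * np.triu(S, 1)).sum())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g


def _check_instance(S: np.ndarray, b: int) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidArgumentError("S must be square")
    n = S.shape[0]
    if not 1 <= b <= n - 1:
        raise InvalidArgumentError(f"b must satisfy 1 <= b <= n-1 (got b={b}, n={n})")
    return S


def _default_ids(n: int) -> list[str]:
    return [f"item{i:04d}" for i in range(n)]


def bmatch_exact(
    S: np.ndarray, b: int, item_ids: list[str] | None = None, size_limit: int = EXACT_SIZE_LIMIT
) -> ProposalGraph:
    """Optimal b-regular graph by pruned enumeration (small instances only).

    Among all simple b-regular graphs on n nodes, returns one maximising total
    edge similarity; ties break toward the lexicographically smallest edge
    set.  Raises :class:`InfeasibleMatchingError` when ``n*b`` is odd (no
    b-regular graph exists) and :class:`SizeLimitError` above ``size_limit``
    nodes — larger instances belong to :func:`bmatch_message_passing`.
    """
    S = _check_instance(S, b)
    n = S.shape[0]
    if n > size_limit:
        raise SizeLimitError(
            f"exact matcher is capped at n <= {size_limit}; use bmatch_message_passing for n={n}"
        )
    if (n * b) % 2 != 0:
        raise InfeasibleMatchingError(f"no {b}-regular graph on {n} nodes: n*b is odd")
    if b == n - 1:
        adjacency = np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8)
        return ProposalGraph(adjacency, b, item_ids or _default_ids(n), converged=True)

    best: list = [None, None]  # [weight, edge tuple]

    def bound(i: int, residual: list[int]) -> float:
        # admissible: each unfilled node takes its residual-many best remaining
        # partners; every edge is counted at most twice, so halve the sum
        open_nodes = [j for j in range(i, n) if residual[j] > 0]
        total = 0.0
        for j in open_nodes:
            weights = sorted((S[j, k] for k in open_nodes if k != j), reverse=True)
            total += sum(weights[: residual[j]])
        return 0.5 * total

    def recurse(i: int, residual: list[int], edges: list[tuple[int, int]], weight: float) -> None:
        if i == n:
            if best[0] is None or weight > best[0] or (weight == best[0] and tuple(edges) < best[1]):
                best[0], best[1] = weight, tuple(edges)
            return
        need = residual[i]
        if need == 0:
            recurse(i + 1, residual, edges, weight)
            return
        available = [j for j in range(i + 1, n) if residual[j] > 0]
        if need > len(available):
            return  # infeasible branch
        # prune on an optimistic completion; strict < keeps tie-break exploration
        if best[0] is not None and weight + bound(i, residual) < best[0]:
            return
        # visit heavy partner sets first so the incumbent tightens quickly;
        # the explicit (weight, lexicographic) comparison above keeps the
        # documented tie-break independent of visit order
        available.sort(key=lambda j: -S[i, j])
        for combo in itertools.combinations(available, need):
            added = 0.0
            for j in combo:
                residual[j] -= 1
                added += S[i, j]
            residual[i] = 0
            edges.extend((i, j) for j in combo)
            recurse(i + 1, residual, edges, weight + added)
            del edges[len(edges) - need:]
            residual[i] = need
            for j in combo:
                residual[j] += 1

    recurse(0, [b] * n, [], 0.0)
    if best[1] is None:  # pragma: no cover - n*b even with b <= n-1 is always feasible
        raise InfeasibleMatchingError(f"no {b}-regular graph on {n} nodes found")
    adjacency = np.zeros((n, n), dtype=np.int8)
    for i, j in best[1]:
        adjacency[i, j] = adjacency[j, i] = 1
    return ProposalGraph(adjacency, b, item_ids or _default_ids(n), converged=True)


def _mp_iterate(
    W: np.ndarray, b: int, M0: np.ndarray, max_iters: int, damping: float
) -> tuple[np.ndarray, bool, np.ndarray]:
    """One synchronous max-product run from initial messages ``M0``.

    ``M[i, j]`` is the scalar message from node i to node j: minus the b-th
    best competing score among i's other options.  Node i keeps the b partners
    with the highest ``weight + incoming message`` belief; mutual selections
    become edges.  Returns (adjacency, converged, final edge beliefs).
    """
    n = W.shape[0]
    M = M0.copy()
    rows = np.repeat(np.arange(n), b)
    prev = None
    stable = 0
    converged = False
    adjacency = np.zeros((n, n), dtype=np.int8)
    for _ in range(max_iters):
        A = W + M.T  # A[i, k] = W[i, k] + message k -> i
        part = np.partition(A, (n - b - 1, n - b), axis=1)
        bth = part[:, n - b]        # b-th largest of row i
        b1th = part[:, n - b - 1]   # (b+1)-th largest of row i
        # b-th largest of row i with column j removed
        competing = np.where(A >= bth[:, None], b1th[:, None], bth[:, None])
        M_new = -competing
        np.fill_diagonal(M_new, 0.0)
        M = damping * M + (1.0 - damping) * M_new

        belief = W + M.T
        top_b = np.argpartition(belief, n - b, axis=1)[:, n - b:]
        sel = np.zeros((n, n), dtype=bool)
        sel[rows, top_b.ravel()] = True
        adjacency = (sel & sel.T).astype(np.int8)
        np.fill_diagonal(adjacency, 0)
        if prev is not None and np.array_equal(adjacency, prev):
            stable += 1
            if stable >= 20:
                converged = True
                break
        else:
            stable = 0
        prev = adjacency
    return adjacency, converged, W + M + M.T


def _complete_deficits(adjacency: np.ndarray, b: int, belief: np.ndarray) -> np.ndarray:
    """Greedily join degree-deficient node pairs in descending belief order.

    Mutual selection can leave pairs of nodes one edge short of b even when
    the missing edge is clearly optimal; this closes such gaps without ever
    pushing a node above degree b.
    """
    adjacency = adjacency.copy()
    while True:
        deficient = np.flatnonzero(adjacency.sum(axis=1) < b)
        candidates = [
            (belief[i, j], i, j)
            for ai, i in enumerate(deficient)
            for j in deficient[ai + 1:]
            if not adjacency[i, j] and np.isfinite(belief[i, j])
        ]
        if not candidates:
            return adjacency
        _, i, j = max(candidates)
        adjacency[i, j] = adjacency[j, i] = 1


def _two_exchange_polish(
    adjacency: np.ndarray, W: np.ndarray, max_passes: int = 50
) -> np.ndarray:
    """Degree-preserving 2-exchange hill climb on the edge set.

    Replaces edge pairs (a,b),(c,d) with (a,c),(b,d) or (a,d),(b,c) whenever
    that raises total weight.  Quadratic in edge count, so callers restrict it
    to small instances.
    """
    adjacency = adjacency.copy()
    for _ in range(max_passes):
        improved = False
        iu, ju = np.nonzero(np.triu(adjacency, 1))
        edges = list(zip(iu.tolist(), ju.tolist()))
        for e1 in range(len(edges)):
            a, c = edges[e1]
            if not adjacency[a, c]:
                continue
            for e2 in range(e1 + 1, len(edges)):
                u, v = edges[e2]
                if not adjacency[u, v] or len({a, c, u, v}) < 4:
                    continue
                w0 = W[a, c] + W[u, v]
                for p, q, r, s in ((a, u, c, v), (a, v, c, u)):
                    if not adjacency[p, q] and not adjacency[r, s] and W[p, q] + W[r, s] > w0:
                        adjacency[a, c] = adjacency[c, a] = 0
                        adjacency[u, v] = adjacency[v, u] = 0
                        adjacency[p, q] = adjacency[q, p] = 1
                        adjacency[r, s] = adjacency[s, r] = 1
                        improved = True
                        break
                if improved:
                    break
            if improved:
                break
        if not improved:
            return adjacency
    return adjacency


#: 2-exchange polish is skipped above this many nodes (it is quadratic in edges).
POLISH_SIZE_LIMIT = 300


def bmatch_message_passing(
    S: np.ndarray,
    b: int,
    max_iters: int = 500,
    damping: float = 0.7,
    seed: int | np.random.Generator = 0,
    restarts: int = 8,
    item_ids: list[str] | None = None,
) -> ProposalGraph:
    """Approximate maximum-weight b-matching by max-product message passing.

    The core is the synchronous scalar-message scheme of :func:`_mp_iterate`.
    Loopy max-product has multiple fixed points on non-bipartite instances, so
    the solver runs ``restarts`` chains from seeded random initial messages
    (the first from zeros), greedily completes paired degree deficits, applies
    a degree-preserving 2-exchange polish on small instances, and keeps the
    best-scoring result.  Weights are shifted to be positive beforehand —
    every b-regular graph has the same edge count, so the optimum is
    unchanged, but the shift stops the decision rule from favouring missing
    edges — and a seeded symmetric jitter of magnitude 1e-12 breaks ties.

    Degrees of individual nodes can still deviate slightly from b; a
    min/mean/max degree report is attached, and ``converged=False`` marks a
    best-so-far graph whose message iteration never stabilised.
    """
    S = _check_instance(S, b)
    n = S.shape[0]
    if not 0 <= damping < 1:
        raise InvalidArgumentError("damping must lie in [0, 1)")
    if restarts < 1:
        raise InvalidArgumentError("restarts must be >= 1")
    if b == n - 1:
        adjacency = np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8)
        graph = ProposalGraph(adjacency, b, item_ids or _default_ids(n), converged=True)
        graph.degree_report = {"min": b, "mean": float(b), "max": b}
        return graph

    rng = as_rng(seed)
    jitter = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    jitter[iu] = rng.uniform(-1.0, 1.0, len(iu[0])) * 1e-12
    W = S + jitter + jitter.T
    off = ~np.eye(n, dtype=bool)
    span = float(W[off].max() - W[off].min())
    W = W - W[off].min() + 1.0  # positive weights; argmax over b-regular graphs unchanged
    np.fill_diagonal(W, -np.inf)
    W_finite = np.where(np.isfinite(W), W, 0.0)

    dampings = (damping, 0.5, 0.9)
    best_score = -np.inf
    best_adj = None
    best_converged = False
    for r in range(restarts):
        if r == 0:
            M0 = np.zeros((n, n))
        else:
            M0 = rng.standard_normal((n, n)) * (0.1 + 0.2 * (r % 5)) * span
        adjacency, converged, belief = _mp_iterate(W, b, M0, max_iters, dampings[r % 3])
        adjacency = _complete_deficits(
            adjacency, b, np.where(np.isfinite(belief), belief, -np.inf)
        )
        if n <= POLISH_SIZE_LIMIT:
            adjacency = _two_exchange_polish(adjacency, W_finite)
        score = float((np.triu(adjacency, 1) * np.triu(W_finite, 1)).sum())
        if score > best_score:
            best_score, best_adj, best_converged = score, adjacency, converged

    graph = ProposalGraph(best_adj, b, item_ids or _default_ids(n), converged=best_converged)
    degrees = graph.degrees()
    graph.degree_report = {
        "min": int(degrees.min()),
        "mean": float(degrees.mean()),
        "max": int(degrees.max()),
    }
    return graph


def largest_connected_component(graph: ProposalGraph) -> ProposalGraph:
    """Induced subgraph on the largest connected component.

    An approximate matching need not be connected, and the chain should run on
    one component.  Ties between equally large components break toward the one
    containing the smallest original node index.  The returned graph keeps the
    mapping back to the original indices in ``original_indices``.
    """
    components = [sorted(c) for c in nx.connected_components(graph.to_networkx())]
    components.sort(key=lambda c: (-len(c), c[0]))
    keep = components[0]
    if len(keep) == graph.n:
        return graph
    idx = np.asarray(keep, dtype=int)
    sub = ProposalGraph(
        adjacency=graph.adjacency[np.ix_(idx, idx)].copy(),
        b=graph.b,
        item_ids=[graph.item_ids[i] for i in keep],
        converged=graph.converged,
        original_indices=idx,
    )
    degrees = sub.degrees()
    sub.degree_report = {
        "min": int(degrees.min()),
        "mean": float(degrees.mean()),
        "max": int(degrees.max()),
    }
    return sub


@dataclass
class GraphValidationReport:
    """Structural findings for a proposal graph; nothing here raises."""

    symmetric: bool
    asymmetric_pairs: list[tuple[int, int]]
    zero_diagonal: bool
    nonzero_diagonal_nodes: list[int]
    connected: bool
    component_sizes: list[int]
    degree_min: int
    degree_mean: float
    degree_max: int
    regular: bool
    aperiodic_with_jump: bool

    @property
    def ok(self) -> bool:
        return self.symmetric and self.zero_diagonal and self.connected

    def summary(self) -> str:
        lines = [
            f"symmetric: {'yes' if self.symmetric else f'NO {self.asymmetric_pairs[:5]}'}",
            f"zero diagonal: {'yes' if self.zero_diagonal else f'NO {self.nonzero_diagonal_nodes[:5]}'}",
            f"connected: {'yes' if self.connected else 'NO'} (component sizes {self.component_sizes})",
            f"degrees: min={self.degree_min} mean={self.degree_mean:.3f} max={self.degree_max}"
            f" ({'regular' if self.regular else 'irregular'})",
            f"aperiodic (with configured jump): {'yes' if self.aperiodic_with_jump else 'NO'}",
        ]
        return "\n".join(lines)


def validate_graph(graph: ProposalGraph, jump_prob: float = 0.1) -> GraphValidationReport:
    """Check the chain's convergence prerequisites and report all findings.

    The walk converges to the target whenever the proposal chain is
    irreducible and aperiodic; a positive uniform-jump probability guarantees
    both regardless of graph quality (any state reaches any other in one jump,
    and self-return paths of coprime lengths exist).  Without a jump the
    report falls back to graph-level checks: connectivity and non-bipartiteness.
    """
    adjacency = graph.adjacency
    n = graph.n
    asym = np.argwhere(adjacency != adjacency.T)
    asymmetric_pairs = [(int(i), int(j)) for i, j in asym if i < j]
    diag = np.flatnonzero(np.diag(adjacency) != 0)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    sym = np.maximum(adjacency, adjacency.T)
    iu, ju = np.nonzero(np.triu(sym, k=1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    component_sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    connected = len(component_sizes) == 1
    degrees = adjacency.sum(axis=1)
    if jump_prob > 0:
        aperiodic = True
    else:
        aperiodic = connected and not nx.is_bipartite(g)
    return GraphValidationReport(
        symmetric=len(asymmetric_pairs) == 0,
        asymmetric_pairs=asymmetric_pairs,
        zero_diagonal=len(diag) == 0,
        nonzero_diagonal_nodes=[int(i) for i in diag],
        connected=connected,
        component_sizes=component_sizes,
        degree_min=int(degrees.min()),
        degree_mean=float(degrees.mean()),
        degree_max=int(degrees.max()),
        regular=bool(degrees.min() == degrees.max()),
        aperiodic_with_jump=aperiodic,
    )
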