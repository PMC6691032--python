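"""File formats: trial logs, similarity matrices, graphs, stimuli, configs.

Everything is tab-separated UTF-8 text with Unix newlines.  The stimuli in
scope (word lists, image identifiers) are small, and human inspection of a
session log matters in behavioral work, so diffable plain text beats any
binary format here.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .bmatching import ProposalGraph
from .chain import SessionConfig, TrialRecord
from .errors import (
    ConfigError,
    InvalidInputError,
    LogParseError,
    LogValidationError,
)
from .fixtures import StimulusSet, TargetDistribution
from .proposals import ProposalSpec

__all__ = [
    "LOG_COLUMNS",
    "write_log", "read_log",
    "write_similarity", "read_similarity",
    "write_graph", "read_graph",
    "write_stimuli", "read_stimuli",
    "write_target", "read_target",
    "write_config", "read_config",
]

LOG_COLUMNS = (
    "participant_id", "session_index", "trial_index", "trial_type", "chain_id",
    "category", "current_id", "proposal_id", "left_id", "right_id", "chosen_id",
    "correct_id",
)


def write_log(log: Sequence[TrialRecord], path: str | Path) -> None:
    lines = ["\t".join(LOG_COLUMNS)]
    for rec in log:
        rec.validate()
        lines.append("\t".join(str(getattr(rec, col)) for col in LOG_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_log(path: str | Path) -> list[TrialRecord]:
    """Parse and validate a trial log; errors carry the offending line number."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != LOG_COLUMNS:
        raise LogParseError(f"{path}: line 1: bad or missing header")
    log: list[TrialRecord] = []
    last_index: dict[str, int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(LOG_COLUMNS):
            raise LogParseError(
                f"{path}: line {lineno}: expected {len(LOG_COLUMNS)} fields, got {len(parts)}"
            )
        try:
            rec = TrialRecord(
                participant_id=parts[0],
                session_index=int(parts[1]),
                trial_index=int(parts[2]),
                trial_type=parts[3],
                chain_id=parts[4],
                category=parts[5],
                current_id=parts[6],
                proposal_id=parts[7],
                left_id=parts[8],
                right_id=parts[9],
                chosen_id=parts[10],
                correct_id=parts[11],
            )
        except ValueError as exc:
            raise LogParseError(f"{path}: line {lineno}: {exc}") from exc
        try:
            rec.validate()
        except Exception as exc:
            raise LogValidationError(f"{path}: line {lineno}: {exc}") from exc
        prev = last_index.get(rec.participant_id)
        if prev is not None and rec.trial_index <= prev:
            raise LogValidationError(
                f"{path}: line {lineno}: trial_index not strictly increasing "
                f"for participant {rec.participant_id!r}"
            )
        last_index[rec.participant_id] = rec.trial_index
        log.append(rec)
    return log


def write_similarity(S: np.ndarray, item_ids: Sequence[str], path: str | Path) -> None:
    S = np.asarray(S, dtype=float)
    lines = ["\t".join(item_ids)]
    for row in S:
        lines.append("\t".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_similarity(
    path: str | Path, on_asymmetric: str = "error"
) -> tuple[np.ndarray, list[str]]:
    """Load a similarity matrix with its item-id header row.

    Symmetry is validated to 1e-9.  ``on_asymmetric="average"`` instead
    symmetrizes by averaging with the transpose and warns.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise LogParseError(f"{path}: empty file")
    item_ids = lines[0].split("\t")
    n = len(item_ids)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != n:
            raise LogParseError(f"{path}: line {lineno}: expected {n} values, got {len(parts)}")
        try:
            rows.append([float(v) for v in parts])
        except ValueError as exc:
            raise LogParseError(f"{path}: line {lineno}: {exc}") from exc
    S = np.asarray(rows)
    if S.shape != (n, n):
        raise LogParseError(f"{path}: expected {n}x{n} matrix, got {S.shape}")
    if not np.allclose(S, S.T, atol=1e-9):
        if on_asymmetric == "average":
            warnings.warn(f"{path}: matrix not symmetric; symmetrizing by averaging")
            S = 0.5 * (S + S.T)
        else:
            raise InvalidInputError(f"{path}: similarity matrix is not symmetric")
    return S, item_ids


def write_graph(graph: ProposalGraph, path: str | Path) -> None:
    """Serialize as an undirected edge list (ids, i<j) under a ``# n=.. b=..`` header."""
    lines = [f"# n={graph.n}\tb={graph.b}"]
    lines.extend(f"{graph.item_ids[i]}\t{graph.item_ids[j]}" for i, j in graph.edges())
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_graph(path: str | Path, item_ids: Sequence[str] | None = None) -> ProposalGraph:
    """Load an edge-list graph.  Node ids default to the sorted set seen in the file."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("# n="):
        raise LogParseError(f"{path}: line 1: missing '# n=.. b=..' header")
    try:
        fields = dict(kv.split("=") for kv in lines[0][2:].split("\t"))
        n, b = int(fields["n"]), int(fields["b"])
    except (ValueError, KeyError) as exc:
        raise LogParseError(f"{path}: line 1: malformed header") from exc
    edges = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LogParseError(f"{path}: line {lineno}: expected two ids")
        edges.append((parts[0], parts[1]))
        seen.update(parts)
    if item_ids is None:
        item_ids = sorted(seen)
        if len(item_ids) != n:
            raise LogValidationError(
                f"{path}: header says n={n} but {len(item_ids)} distinct ids appear; "
                "pass item_ids explicitly for graphs with isolated nodes"
            )
    elif len(item_ids) != n:
        raise LogValidationError(f"{path}: header n={n} != {len(item_ids)} provided ids")
    index = {item: i for i, item in enumerate(item_ids)}
    adjacency = np.zeros((n, n), dtype=np.int8)
    for a, bb in edges:
        if a not in index or bb not in index:
            raise LogValidationError(f"{path}: edge ({a}, {bb}) names an unknown item")
        i, j = index[a], index[bb]
        if i == j:
            raise LogValidationError(f"{path}: self-edge on {a}")
        adjacency[i, j] = adjacency[j, i] = 1
    graph = ProposalGraph(adjacency=adjacency, b=b, item_ids=list(item_ids))
    degrees = graph.degrees()
    graph.degree_report = {
        "min": int(degrees.min()), "mean": float(degrees.mean()), "max": int(degrees.max()),
    }
    return graph


def write_stimuli(stimuli: StimulusSet, directory: str | Path) -> None:
    """Serialize a stimulus set to a directory: ids.txt, features.tsv, tags.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "ids.txt").write_text("\n".join(stimuli.item_ids) + "\n", encoding="utf-8")
    if stimuli.features is not None:
        lines = ["\t".join(repr(float(v)) for v in row) for row in stimuli.features]
        (directory / "features.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    if stimuli.category_tags is not None:
        lines = [f"{item}\t{stimuli.category_tags[item]}" for item in stimuli.item_ids
                 if item in stimuli.category_tags]
        (directory / "tags.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_stimuli(directory: str | Path) -> StimulusSet:
    directory = Path(directory)
    ids_path = directory / "ids.txt"
    if not ids_path.exists():
        raise InvalidInputError(f"{directory}: missing ids.txt")
    item_ids = [l for l in ids_path.read_text(encoding="utf-8").splitlines() if l.strip()]
    features = None
    feat_path = directory / "features.tsv"
    if feat_path.exists():
        rows = [
            [float(v) for v in line.split("\t")]
            for line in feat_path.read_text(encoding="utf-8").splitlines() if line.strip()
        ]
        features = np.asarray(rows)
    tags = None
    tag_path = directory / "tags.tsv"
    if tag_path.exists():
        tags = {}
        for lineno, line in enumerate(tag_path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LogParseError(f"{tag_path}: line {lineno}: expected 'id<TAB>tag'")
            tags[parts[0]] = parts[1]
    return StimulusSet(item_ids=item_ids, features=features, category_tags=tags)


def write_target(target: TargetDistribution, item_ids: Sequence[str], path: str | Path) -> None:
    lines = [f"# gamma={float(target.gamma)!r}", "item_id\tprob"]
    lines.extend(f"{item}\t{float(p)!r}" for item, p in zip(item_ids, target.probs))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_target(path: str | Path, item_ids: Sequence[str] | None = None) -> TargetDistribution:
    """Load a target distribution, reordering to ``item_ids`` when given."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    gamma = 1.0
    body = []
    for line in lines:
        if line.startswith("# gamma="):
            gamma = float(line.split("=", 1)[1])
        elif line.strip() and line != "item_id\tprob":
            body.append(line)
    probs: dict[str, float] = {}
    for lineno, line in enumerate(body, 1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise LogParseError(f"{path}: entry {lineno}: expected 'id<TAB>prob'")
        probs[parts[0]] = float(parts[1])
    ids = list(item_ids) if item_ids is not None else list(probs)
    missing = [i for i in ids if i not in probs]
    if missing:
        raise InvalidInputError(f"{path}: no probability for items {missing[:5]}")
    return TargetDistribution(
        probs=np.array([probs[i] for i in ids]), gamma=gamma, item_ids=ids
    )


_CONFIG_KEYS = {
    "categories", "chains_per_category", "trials_per_chain", "n_practice",
    "n_catch", "catch_pass_threshold", "seed", "interleave",
    "proposal.kind", "proposal.geom_param", "proposal.jump_prob",
}


def write_config(config: SessionConfig, path: str | Path) -> None:
    lines = [
        f"categories={','.join(config.categories)}",
        f"chains_per_category={config.chains_per_category}",
        f"trials_per_chain={config.trials_per_chain}",
        f"n_practice={config.n_practice}",
        f"n_catch={config.n_catch}",
        f"catch_pass_threshold={config.catch_pass_threshold}",
        f"seed={config.seed}",
        f"interleave={config.interleave}",
        f"proposal.kind={config.proposal.kind}",
        f"proposal.geom_param={config.proposal.geom_param!r}",
        f"proposal.jump_prob={config.proposal.jump_prob!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_config(path: str | Path) -> SessionConfig:
    """Parse a flat key=value session config with dotted proposal keys."""
    values: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}: line {lineno}: expected key=value")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_KEYS:
            raise ConfigError(f"{path}: line {lineno}: unknown key {key!r}")
        values[key] = value.strip()
    try:
        proposal = ProposalSpec(
            kind=values.get("proposal.kind", "uniform_neighbor"),
            geom_param=float(values.get("proposal.geom_param", "0.5")),
            jump_prob=float(values.get("proposal.jump_prob", "0.1")),
        )
        return SessionConfig(
            categories=[c for c in values.get("categories", "").split(",") if c],
            chains_per_category=int(values.get("chains_per_category", "2")),
            trials_per_chain=int(values.get("trials_per_chain", "100")),
            n_practice=int(values.get("n_practice", "12")),
            n_catch=int(values.get("n_catch", "40")),
            catch_pass_threshold=int(values.get("catch_pass_threshold", "27")),
            proposal=proposal,
            seed=int(values.get("seed", "0")),
            interleave=values.get("interleave", "round_robin"),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
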