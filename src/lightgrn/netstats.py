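"""Key-regulator statistics on the light-responsive network.

Outdegree, directed betweenness with min-max normalization, a census of
feed-forward-loop (FFL) roles per node, and a greedy ranking of
regulators by accumulated unique target coverage from which key TFs are
selected at a coverage threshold.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import networkx as nx
import pandas as pd

from .grn_build import GRN

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class FFLTriple:
    """Feed-forward loop: master -> intermediate, master -> target,
    intermediate -> target, over three distinct nodes."""

    master: str
    intermediate: str
    target: str

    def __post_init__(self) -> None:
        if len({self.master, self.intermediate, self.target}) != 3:
            raise ValueError("FFL nodes must be pairwise distinct")


@dataclasses.dataclass(frozen=True)
class NodeMeasures:
    node_id: str
    outdegree: int
    betweenness_raw: float
    betweenness_normalized: float
    ffl_master: int
    ffl_intermediate: int
    ffl_target: int


@dataclasses.dataclass(frozen=True)
class RankedRegulator:
    """One step of the greedy unique-coverage ranking."""

    node_id: str
    new_targets: int
    cumulative_unique: int
    cumulative_fraction: float


def node_outdegrees(grn: GRN) -> dict[str, int]:
    """Distinct outgoing edges per node (self-loops counted)."""
    return {n: d for n, d in grn.graph.out_degree()}


def normalized_betweenness(grn: GRN) -> dict[str, tuple[float, float]]:
    """Directed betweenness B(n) and its min-max normalization.

    B(n) sums sigma_ij(n)/sigma_ij over ordered pairs i != j != n with at
    least one directed shortest path; endpoints are excluded. Normalized
    scores are (B - min B) / (max B - min B); if every node has the same
    raw score all normalized scores are 0.
    """
    if len(grn.graph) == 0:
        return {}
    raw = nx.betweenness_centrality(grn.graph, normalized=False)
    values = list(raw.values())
    lo, hi = min(values), max(values)
    if hi == lo:
        return {n: (b, 0.0) for n, b in raw.items()}
    return {n: (b, (b - lo) / (hi - lo)) for n, b in raw.items()}


def enumerate_ffls(grn: GRN) -> tuple[list[FFLTriple], dict[str, dict[str, int]]]:
    """All feed-forward loops and per-node role counts.

    A triple (x, y, z) of pairwise-distinct nodes is an FFL iff edges
    x->y, x->z and y->z all exist. Self-loops never contribute. Role
    counts are returned as node -> {master, intermediate, target}.
    """
    g = grn.graph
    succ = {n: set(g.successors(n)) - {n} for n in g.nodes}
    triples: list[FFLTriple] = []
    counts = {n: {"master": 0, "intermediate": 0, "target": 0} for n in g.nodes}
    for x in g.nodes:
        sx = succ[x]
        for y in sx:
            for z in sx & succ[y]:
                if z == x:
                    continue
                triples.append(FFLTriple(master=x, intermediate=y, target=z))
                counts[x]["master"] += 1
                counts[y]["intermediate"] += 1
                counts[z]["target"] += 1
    return triples, counts


def greedy_coverage_ranking(
    grn: GRN, candidates: Iterable[str] | None = None
) -> list[RankedRegulator]:
    """Rank regulators by accumulated unique direct-target coverage.

    At each step the candidate adding the most not-yet-covered targets is
    selected; ties break by larger total outdegree, then lexicographic id.
    Targets are out-neighbors (a self-loop covers the node itself).
    ``cumulative_fraction`` is covered nodes over all network nodes. Every
    candidate is ranked.
    """
    g = grn.graph
    if candidates is None:
        cand = sorted(n for n in g.nodes if g.out_degree(n) >= 1)
    else:
        cand = sorted(set(candidates))
    targets = {c: set(g.successors(c)) for c in cand}
    n_nodes = g.number_of_nodes()
    covered: set[str] = set()
    remaining = list(cand)
    ranking: list[RankedRegulator] = []
    while remaining:
        best = min(
            remaining,
            key=lambda c: (-len(targets[c] - covered), -len(targets[c]), c),
        )
        gain = len(targets[best] - covered)
        covered |= targets[best]
        remaining.remove(best)
        ranking.append(
            RankedRegulator(
                node_id=best,
                new_targets=gain,
                cumulative_unique=len(covered),
                cumulative_fraction=len(covered) / n_nodes if n_nodes else 0.0,
            )
        )
    return ranking


def select_key_tfs(
    ranking: list[RankedRegulator], coverage_threshold: float = 0.9
) -> list[str]:
    """Shortest ranking prefix whose cumulative coverage reaches the threshold.

    Returns the full ranking with a warning if the threshold is never
    reached; errors on an empty ranking.
    """
    if not ranking:
        raise ValueError("select_key_tfs requires a non-empty ranking")
    for i, step in enumerate(ranking):
        if step.cumulative_fraction >= coverage_threshold:
            return [s.node_id for s in ranking[: i + 1]]
    logger.warning(
        "coverage threshold %.3g never reached (max %.3g); returning full ranking",
        coverage_threshold,
        ranking[-1].cumulative_fraction,
    )
    return [s.node_id for s in ranking]


def compute_node_measures(grn: GRN) -> list[NodeMeasures]:
    """All per-node measures used for key-regulator identification."""
    outdeg = node_outdegrees(grn)
    btw = normalized_betweenness(grn)
    _, roles = enumerate_ffls(grn)
    return [
        NodeMeasures(
            node_id=n,
            outdegree=outdeg[n],
            betweenness_raw=btw[n][0],
            betweenness_normalized=btw[n][1],
            ffl_master=roles[n]["master"],
            ffl_intermediate=roles[n]["intermediate"],
            ffl_target=roles[n]["target"],
        )
        for n in sorted(grn.graph.nodes)
    ]


def write_measures_table(measures: list[NodeMeasures], grn: GRN, path) -> None:
    """Measures TSV mirroring the published per-TF table columns."""
    rows = []
    for m in measures:
        rows.append(
            {
                "node_id": m.node_id,
                "outdegree": m.outdegree,
                "master": m.ffl_master,
                "intermediate": m.ffl_intermediate,
                "target": m.ffl_target,
                "betweenness_raw": m.betweenness_raw,
                "betweenness_normalized": round(m.betweenness_normalized, 6),
                "deg_direction": grn.direction_of(m.node_id) or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
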