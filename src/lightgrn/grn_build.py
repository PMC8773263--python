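"""Collapse binding-site hits into a genome-scale directed regulatory network."""

from __future__ import annotations

import dataclasses
import math
import statistics
from typing import Iterable

import networkx as nx


@dataclasses.dataclass(frozen=True)
class Interaction:
    """One regulator -> target edge, collapsed over motifs and sites."""

    tf_id: str
    target_gene_id: str
    site_count: int = 1
    best_pvalue: float = math.nan

    def __post_init__(self) -> None:
        if self.site_count < 1:
            raise ValueError("site_count must be >= 1")


class GRN:
    """Directed regulator -> target network.

    Thin wrapper around a :class:`networkx.DiGraph`; edges may carry
    ``site_count``, ``best_pvalue`` and ``sign`` attributes, nodes a
    ``direction`` (DEG up/down) annotation. A node is a regulator iff it
    has at least one outgoing edge; self-loops are permitted.
    """

    def __init__(self, graph: nx.DiGraph | None = None) -> None:
        self.graph = graph if graph is not None else nx.DiGraph()

    @classmethod
    def from_interactions(cls, interactions: Iterable[Interaction]) -> "GRN":
        grn = cls()
        for it in interactions:
            grn.graph.add_edge(
                it.tf_id,
                it.target_gene_id,
                site_count=it.site_count,
                best_pvalue=it.best_pvalue,
            )
        return grn

    # -- basic views --------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    @property
    def regulators(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) >= 1}

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def direction_of(self, node: str) -> str | None:
        return self.graph.nodes[node].get("direction")

    def set_directions(self, directions: dict[str, str]) -> None:
        for node, d in directions.items():
            if node in self.graph:
                self.graph.nodes[node]["direction"] = d

    def copy(self) -> "GRN":
        return GRN(self.graph.copy())

    # -- summary ------------------------------------------------------------

    def summary(self) -> dict:
        """Node/edge counts plus outdegree statistics over regulators only.

        Mean/median outdegree are computed over nodes with outdegree >= 1;
        self-loops are reported separately so either counting convention
        is recoverable.
        """
        outdeg = [d for _, d in self.graph.out_degree() if d >= 1]
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "n_self_loops": sum(1 for u, v in self.graph.edges if u == v),
            "n_regulators": len(outdeg),
            "mean_outdegree": statistics.fmean(outdeg) if outdeg else 0.0,
            "median_outdegree": statistics.median(outdeg) if outdeg else 0.0,
        }


def hits_to_interactions(hits) -> list[Interaction]:
    """Collapse binding-site hits to one interaction per (tf, target) pair.

    Hits from different motifs of the same TF merge; ``site_count`` is the
    number of contributing hits and ``best_pvalue`` their minimum. Order
    follows first appearance in the hit list.
    """
    grouped: dict[tuple[str, str], list] = {}
    for h in hits:
        grouped.setdefault((h.tf_id, h.gene_id), []).append(h)
    return [
        Interaction(
            tf_id=tf,
            target_gene_id=gene,
            site_count=len(group),
            best_pvalue=min(h.pvalue for h in group),
        )
        for (tf, gene), group in grouped.items()
    ]


def build_grn(interactions: Iterable[Interaction]) -> GRN:
    """Assemble the genome-scale GRN from collapsed interactions."""
    return GRN.from_interactions(interactions)
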