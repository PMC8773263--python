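"""DEG-induced subnetwork extraction, edge-sign annotation, pathway
sub-networks, and reciprocal-best-hit ortholog filtering."""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import pandas as pd

from .grn_build import GRN


@dataclasses.dataclass(frozen=True)
class OrthologHit:
    """One row of a tabular pairwise-alignment summary."""

    query_id: str
    subject_id: str
    evalue: float
    percent_identity: float
    percent_coverage: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        for name in ("percent_identity", "percent_coverage"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be within [0, 100]")


def extract_light_grn(grn: GRN, degs: Mapping[str, str] | Iterable[str]) -> GRN:
    """Induced subgraph on DEG nodes, isolated nodes removed.

    ``degs`` maps gene id -> direction (up/down); a bare iterable of ids is
    accepted (directions left unset). Nodes with total degree 0 inside the
    induced subgraph are dropped; a self-loop counts as connectivity.
    Directions are attached to every surviving node.
    """
    directions = dict(degs) if isinstance(degs, Mapping) else {g: None for g in degs}
    keep = set(directions) & grn.nodes
    sub = grn.graph.subgraph(keep).copy()
    isolated = [n for n in sub.nodes if sub.degree(n) == 0]
    sub.remove_nodes_from(isolated)
    out = GRN(sub)
    for n in sub.nodes:
        if directions.get(n) is not None:
            sub.nodes[n]["direction"] = directions[n]
    return out


def annotate_edge_signs(light_grn: GRN) -> GRN:
    """Label every edge with its target node's DEG direction.

    The sign is an annotation reproducing the convention that a TF
    "up-regulates" a target whose expression goes up, not a mechanistic
    claim. Errors if a target lacks a direction.
    """
    out = light_grn.copy()
    for u, v in out.graph.edges:
        direction = out.graph.nodes[v].get("direction")
        if direction is None:
            raise ValueError(f"target node {v!r} has no DEG direction")
        out.graph.edges[u, v]["sign"] = direction
    return out


def extract_pathway_subnetwork(light_grn: GRN, gene_list: Iterable[str]) -> GRN:
    """Sub-network of listed genes plus their direct parent regulators.

    Nodes are (gene_list ∩ network) plus every direct parent of those
    genes; edges are all parent -> list-gene edges plus the edges among
    the included parents themselves.
    """
    wanted = set(gene_list) & light_grn.nodes
    g = light_grn.graph
    parents = {u for v in wanted for u in g.predecessors(v)}
    sub = GRN()
    sub.graph.add_nodes_from(
        (n, dict(g.nodes[n])) for n in wanted | parents
    )
    for v in wanted:
        for u in g.predecessors(v):
            sub.graph.add_edge(u, v, **g.edges[u, v])
    for u in parents:
        for v in g.successors(u):
            if v in parents:
                sub.graph.add_edge(u, v, **g.edges[u, v])
    return sub


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------


def _best_hits(
    hits: list[OrthologHit],
    max_evalue: float,
    min_identity: float,
    min_coverage: float,
) -> dict[str, str]:
    """Best surviving subject per query: max bitscore, then min evalue, then id."""
    best: dict[str, OrthologHit] = {}
    for h in hits:
        if h.evalue > max_evalue or h.percent_identity < min_identity:
            continue
        if h.percent_coverage < min_coverage:
            continue
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.bitscore > cur.bitscore
            or (h.bitscore == cur.bitscore and h.evalue < cur.evalue)
            or (
                h.bitscore == cur.bitscore
                and h.evalue == cur.evalue
                and h.subject_id < cur.subject_id
            )
        ):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def rbh_ortholog_filter(
    forward: list[OrthologHit],
    reverse: list[OrthologHit],
    max_evalue: float = 1e-10,
    min_identity: float = 60.0,
    min_coverage: float = 40.0,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit pairs after thresholding both hit tables.

    Hits failing evalue <= max_evalue, identity >= min_identity or
    coverage >= min_coverage (all inclusive) are dropped; (q, s) is kept
    iff s is q's best surviving forward hit and q is s's best surviving
    reverse hit. Pairs are returned sorted.
    """
    fwd = _best_hits(forward, max_evalue, min_identity, min_coverage)
    rev = _best_hits(reverse, max_evalue, min_identity, min_coverage)
    return sorted((q, s) for q, s in fwd.items() if rev.get(s) == q)


def read_ortholog_hits(path) -> list[OrthologHit]:
    """TSV with columns query_id, subject_id, evalue, percent_identity,
    percent_coverage, bitscore (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t")
    required = [
        "query_id",
        "subject_id",
        "evalue",
        "percent_identity",
        "percent_coverage",
        "bitscore",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: ortholog table missing columns {missing}")
    return [
        OrthologHit(
            query_id=str(row.query_id),
            subject_id=str(row.subject_id),
            evalue=float(row.evalue),
            percent_identity=float(row.percent_identity),
            percent_coverage=float(row.percent_coverage),
            bitscore=float(row.bitscore),
        )
        for row in df.itertuples()
    ]
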