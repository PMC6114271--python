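"""Construction of the compound-target (CT) bipartite network, drug-target
and disease-gene PPI networks, and their intersection.

Graphs are undirected, unweighted :class:`networkx.Graph` objects.  Nodes
carry a ``partition`` attribute: ``compound``/``target`` in a CT network,
and ``drug-only``/``disease-only``/``shared`` in the merged drug-disease
graph.  Compound ids and gene symbols live in disjoint namespaces (the
``C##`` id convention plus a validation pass at build time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .errors import ValidationError

logger = logging.getLogger("herbnet")


def build_ct_network(pairs: Sequence[tuple[str, str]]) -> nx.Graph:
    """Build the bipartite compound-target network from (compound, target)
    pairs.

    Target symbols are upper-cased; compound ids kept verbatim.  Duplicate
    pairs collapse; a name appearing on both sides raises
    :class:`ValidationError` (bipartite violation).  A compound's degree
    is its number of distinct targets.
    """
    if not pairs:
        raise ValidationError("empty compound-target pair list")
    g = nx.Graph(name="ct")
    compounds: set[str] = set()
    targets: set[str] = set()
    for c, t in pairs:
        c, t = c.strip(), t.strip().upper()
        compounds.add(c)
        targets.add(t)
    offenders = compounds & targets
    if offenders:
        raise ValidationError(
            f"node(s) appear as both compound and target: {sorted(offenders)[:5]}"
        )
    for c in compounds:
        g.add_node(c, partition="compound")
    for t in targets:
        g.add_node(t, partition="target")
    for c, t in pairs:
        g.add_edge(c.strip(), t.strip().upper())
    return g


def ct_degree_table(g: nx.Graph) -> dict[str, int]:
    """Per-compound target counts of a CT network (comparable to a
    published compound/Degree table)."""
    return {
        n: g.degree(n) for n, d in g.nodes(data=True) if d.get("partition") == "compound"
    }


def ct_targets(g: nx.Graph) -> set[str]:
    return {n for n, d in g.nodes(data=True) if d.get("partition") == "target"}


def build_ppi_network(
    edges: Iterable[tuple[str, str]], nodes: Iterable[str] | None = None, name: str = "ppi"
) -> nx.Graph:
    """Build an undirected protein-protein interaction graph among drug
    targets.  ``nodes`` optionally lists proteins to retain even when
    isolated.  Self-loops are dropped with a logged count."""
    g = nx.Graph(name=name)
    n_loops = 0
    for a, b in edges:
        a, b = a.strip().upper(), b.strip().upper()
        if a == b:
            n_loops += 1
            continue
        g.add_edge(a, b)
    if nodes is not None:
        g.add_nodes_from(n.strip().upper() for n in nodes)
    if n_loops:
        logger.info("%s: dropped %d self-loop(s)", name, n_loops)
    return g


def build_disease_network(
    edges: Iterable[tuple[str, str]], nodes: Iterable[str] | None = None
) -> nx.Graph:
    """PPI graph among disease-associated genes."""
    return build_ppi_network(edges, nodes=nodes, name="disease")


@dataclass
class OverlapReport:
    """Intersection of a drug-target network with a disease-gene network.

    ``shared`` is the node-set intersection of the two gene namespaces
    (compound nodes excluded); ``merged_graph`` is the union of both
    graphs with per-node provenance in {drug-only, disease-only, shared}.
    """

    drug_targets: frozenset[str]
    disease_genes: frozenset[str]
    shared: frozenset[str]
    merged_graph: nx.Graph

    def __post_init__(self) -> None:
        if self.shared != self.drug_targets & self.disease_genes:
            raise ValidationError("shared set inconsistent with its operands")


def _gene_nodes(g: nx.Graph) -> set[str]:
    return {
        n
        for n, d in g.nodes(data=True)
        if d.get("partition") not in {"compound"}
    }


def map_overlap(drug_net: nx.Graph, disease_net: nx.Graph) -> OverlapReport:
    """Map a drug-target network onto a disease-gene network.

    The shared genes — candidates for therapeutically relevant targets —
    are computed by node-name intersection.  An empty intersection is a
    valid (loudly logged) outcome, not an error.
    """
    drug_genes = frozenset(_gene_nodes(drug_net))
    disease_genes = frozenset(_gene_nodes(disease_net))
    shared = drug_genes & disease_genes
    if not shared:
        logger.warning(
            "no overlap between %d drug targets and %d disease genes",
            len(drug_genes),
            len(disease_genes),
        )
    merged = nx.Graph(name="drug-disease")
    merged.add_edges_from(drug_net.subgraph(drug_genes).edges())
    merged.add_edges_from(disease_net.subgraph(disease_genes).edges())
    merged.add_nodes_from(drug_genes | disease_genes)
    for n in merged.nodes:
        if n in shared:
            merged.nodes[n]["partition"] = "shared"
        elif n in drug_genes:
            merged.nodes[n]["partition"] = "drug-only"
        else:
            merged.nodes[n]["partition"] = "disease-only"
    return OverlapReport(
        drug_targets=drug_genes,
        disease_genes=disease_genes,
        shared=shared,
        merged_graph=merged,
    )
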