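"""Network statistics and the twice-the-median hub rule.

Degree is the number of incident edges; betweenness is standard
unnormalized shortest-path betweenness (pair counts); radius/diameter
come from per-node eccentricities over unweighted shortest paths; the
characteristic path length is the mean shortest-path length over
connected unordered node pairs.

Hubs are nodes whose degree strictly exceeds twice the median degree of
their scope.  On a bipartite compound-target network the natural scope
is the partition (compound medians and target medians differ by an order
of magnitude); on a monopartite PPI graph the scope is the whole node
set.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .errors import ValidationError

logger = logging.getLogger("herbnet")


def degree_map(g: nx.Graph) -> dict[str, int]:
    """Node -> incident edge count."""
    return dict(g.degree())


def betweenness_map(g: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Node -> shortest-path betweenness.

    Unnormalized by default: the value for a node is the number of
    unordered node pairs whose shortest paths pass through it (fractional
    when shortest paths tie).
    """
    return nx.betweenness_centrality(g, normalized=normalized)


@dataclass
class TopologySummary:
    """Global path statistics of a connected (component of a) graph."""

    n_nodes: int
    n_edges: int
    radius: int
    diameter: int
    characteristic_path_length: float | None
    degree: dict[str, int]
    betweenness: dict[str, float]
    eccentricity: dict[str, int] = field(default_factory=dict)
    on_largest_component: bool = False

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "radius": self.radius,
            "diameter": self.diameter,
            "characteristic_path_length": self.characteristic_path_length,
            "on_largest_component": self.on_largest_component,
        }


def path_statistics(g: nx.Graph) -> TopologySummary:
    """Radius, diameter and characteristic path length of ``g``.

    Disconnected input is reduced to its largest connected component with
    a logged warning.  A singleton graph has radius = diameter = 0 and an
    undefined (``None``) characteristic path length; an empty graph is an
    error.
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("path statistics of an empty graph are undefined")
    reduced = False
    if not nx.is_connected(g):
        comp = max(nx.connected_components(g), key=len)
        logger.warning(
            "graph %s is disconnected; statistics computed on the largest "
            "component (%d of %d nodes)",
            g.name or "?",
            len(comp),
            g.number_of_nodes(),
        )
        g = g.subgraph(comp).copy()
        reduced = True
    ecc = nx.eccentricity(g)
    if g.number_of_nodes() == 1:
        cpl: float | None = None
    else:
        cpl = nx.average_shortest_path_length(g)
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        radius=min(ecc.values()),
        diameter=max(ecc.values()),
        characteristic_path_length=cpl,
        degree=degree_map(g),
        betweenness=betweenness_map(g),
        eccentricity=dict(ecc),
        on_largest_component=reduced,
    )


@dataclass
class HubSelection:
    """Result of the twice-the-median hub rule.

    ``thresholds`` maps scope label ("all" for whole-graph scope, else the
    partition name) to 2 x median degree within that scope; ``hubs`` are
    the nodes whose degree strictly exceeds their scope's threshold,
    sorted by degree descending (ties broken by node name for
    determinism).
    """

    scope: str
    thresholds: dict[str, float]
    hubs: list[str]
    degrees: dict[str, int]

    def hubs_in_partition(self, g: nx.Graph, partition: str) -> list[str]:
        return [h for h in self.hubs if g.nodes[h].get("partition") == partition]


def select_hubs_from_degrees(degrees: Mapping[str, int]) -> tuple[float, list[str]]:
    """Apply the hub rule to a plain degree table.

    Returns (threshold, hubs) where threshold = 2 x median degree (even
    count -> mean of the two middle values) and hubs have degree strictly
    greater than the threshold, sorted by degree descending.
    """
    if not degrees:
        raise ValidationError("empty degree table")
    threshold = 2.0 * statistics.median(degrees.values())
    hubs = sorted(
        (n for n, d in degrees.items() if d > threshold),
        key=lambda n: (-degrees[n], n),
    )
    return threshold, hubs


def select_hubs(g: nx.Graph, scope: str = "all_nodes") -> HubSelection:
    """Select hub nodes: degree strictly greater than twice the median.

    Parameters
    ----------
    g : graph
    scope : {"all_nodes", "per_partition"}
        With ``per_partition`` the median is taken separately within each
        ``partition`` node-attribute value (required on every node);
        this is the appropriate scope for bipartite CT networks.
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot select hubs in an empty graph")
    deg = degree_map(g)
    if scope == "all_nodes":
        threshold, hubs = select_hubs_from_degrees(deg)
        return HubSelection("all_nodes", {"all": threshold}, hubs, deg)
    if scope != "per_partition":
        raise ValueError(f"scope must be 'all_nodes' or 'per_partition', got {scope!r}")
    partitions: dict[str, dict[str, int]] = {}
    for n, d in g.nodes(data=True):
        part = d.get("partition")
        if part is None:
            raise ValidationError(f"node {n!r} lacks a partition label")
        partitions.setdefault(part, {})[n] = deg[n]
    thresholds: dict[str, float] = {}
    hubs: list[str] = []
    for part, part_deg in sorted(partitions.items()):
        if not part_deg:
            raise ValidationError(f"empty partition {part!r}")
        thr, part_hubs = select_hubs_from_degrees(part_deg)
        thresholds[part] = thr
        hubs.extend(part_hubs)
    hubs.sort(key=lambda n: (-deg[n], n))
    return HubSelection("per_partition", thresholds, hubs, deg)
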