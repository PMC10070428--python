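"""Day-specific co-administration networks and medication-combination rankings.

A co-administration network for day *d* has one node per medication active
in at least one patient on that day (node weight = number of such patients)
and an edge between two medications weighted by the number of patients with
both active on day *d*. Edge weights can never exceed either incident node
weight. Combination rankings count a patient toward a pair only when both
medications are active *simultaneously* on some day, either a specific day
or anywhere in a window.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import networkx as nx

from .exposure import DailyExposure


@dataclass
class CoAdminNetwork:
    """Weighted co-administration graph for a single post-injury day."""

    day: int
    nodes: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    min_edge_weight: int = 1

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(day=self.day, min_edge_weight=self.min_edge_weight)
        for med, w in self.nodes.items():
            g.add_node(med, weight=w)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def summary(self) -> dict:
        return {
            "day": self.day,
            "n_nodes": len(self.nodes),
            "n_edges": len(self.edges),
            "max_node_weight": max(self.nodes.values(), default=0),
            "max_edge_weight": max(self.edges.values(), default=0),
            "min_edge_weight_threshold": self.min_edge_weight,
        }


def build_coadmin_network(
    daily_by_patient: Mapping[str, DailyExposure],
    day: int,
    min_edge_weight: int = 1,
) -> CoAdminNetwork:
    """Build the day-*d* network from per-patient daily exposure.

    Node weight is the number of patients with the medication active on that
    day; edge weight the number of patients with both medications active.
    Edges below ``min_edge_weight`` are removed; zero-weight nodes are
    absent. Pair keys are stored in lexicographic order.
    """
    if min_edge_weight < 1:
        raise ValueError("min_edge_weight must be >= 1")
    horizons = {d.horizon_days for d in daily_by_patient.values()}
    if horizons and not 1 <= day <= max(horizons):
        raise ValueError(f"day {day} outside horizon")
    nodes: dict[str, int] = {}
    edges: dict[tuple[str, str], int] = {}
    for exp in daily_by_patient.values():
        active = sorted(exp.active.get(day, ()))
        for med in active:
            nodes[med] = nodes.get(med, 0) + 1
        for a, b in combinations(active, 2):
            edges[(a, b)] = edges.get((a, b), 0) + 1
    edges = {pair: w for pair, w in edges.items() if w >= min_edge_weight}
    return CoAdminNetwork(day=day, nodes=nodes, edges=edges, min_edge_weight=min_edge_weight)


def rank_combinations(
    daily_by_patient: Mapping[str, DailyExposure],
    k: int,
    day: int | None = None,
    window: int | None = None,
) -> list[tuple[tuple[str, str], int]]:
    """Top-``k`` medication pairs by number of co-exposed patients.

    Exactly one of ``day`` (a specific post-injury day) or ``window`` (any
    day in [1, window]) must be given. Under the window scope a patient
    counts once for a pair if both medications are simultaneously active on
    at least one day; exposures on disjoint days never pair. Ties break by
    lexicographic pair; pairs never co-active are not listed. If ``k``
    exceeds the number of co-active pairs, all pairs are returned.
    """
    if (day is None) == (window is None):
        raise ValueError("give exactly one of day= or window=")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[tuple[str, str], int] = {}
    for exp in daily_by_patient.values():
        if day is not None:
            pairs = set(combinations(sorted(exp.active.get(day, ())), 2))
        else:
            pairs = set()
            for d in range(1, min(window, exp.horizon_days) + 1):
                pairs.update(combinations(sorted(exp.active.get(d, ())), 2))
        for pair in pairs:
            counts[pair] = counts.get(pair, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def export_network(network: CoAdminNetwork, path: str | Path, format: str = "edgelist") -> None:
    """Write a network as a TSV edge list or GraphML (with node weights)."""
    path = Path(path)
    if format == "edgelist":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["med_a", "med_b", "weight"])
            for (a, b), w in sorted(network.edges.items()):
                writer.writerow([a, b, w])
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown network export format {format!r}")


def import_network(path: str | Path, format: str = "graphml") -> CoAdminNetwork:
    """Re-read an exported network; round-trips weights exactly.

    Edge lists carry no node weights, so only GraphML restores the full
    network; ``format="edgelist"`` returns a network whose node weights are
    absent (0 placeholders are not invented — nodes come back weightless
    only via their edges).
    """
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = {str(n): int(d["weight"]) for n, d in g.nodes(data=True)}
        edges = {
            tuple(sorted((str(a), str(b)))): int(d["weight"])
            for a, b, d in g.edges(data=True)
        }
        return CoAdminNetwork(
            day=int(g.graph.get("day", 0)),
            nodes=nodes,
            edges=edges,
            min_edge_weight=int(g.graph.get("min_edge_weight", 1)),
        )
    if format == "edgelist":
        edges: dict[tuple[str, str], int] = {}
        with path.open() as fh:
            reader = csv.reader(fh, delimiter="\t")
            next(reader, None)
            for a, b, w in reader:
                edges[tuple(sorted((a, b)))] = int(w)
        return CoAdminNetwork(day=0, nodes={}, edges=edges)
    raise ValueError(f"unknown network import format {format!r}")
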