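"""Differential-subnetwork assembly, hub ranking, and network export.

The differential subnetwork is built from the extracted (high-ΔECv) edges by
taking the basal network's induced subgraph on their endpoint genes: the
extracted edges themselves plus every basal edge connecting two extracted
genes ("basal fill"). Hubs are the top-degree nodes; components are weak
(direction-blind) connectivity classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .structure import BasalNetwork

ORIGIN_EXTRACTED = "delta_extracted"
ORIGIN_FILL = "basal_fill"


@dataclass
class Subnetwork:
    """Extracted differential edges plus basal-fill connections."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]  # (parent, child, origin)
    delta: dict = field(default_factory=dict)  # (parent, child) -> {group: ΔECv}
    frequency: dict = field(default_factory=dict)  # (parent, child) -> basal freq

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen = set()
        for p, c, origin in self.edges:
            if (p, c) in seen:
                raise ValueError(f"duplicate edge {p}->{c}")
            seen.add((p, c))
            if p not in node_set or c not in node_set:
                raise ValueError(f"edge {p}->{c} endpoint outside node set")
            if origin not in (ORIGIN_EXTRACTED, ORIGIN_FILL):
                raise ValueError(f"unknown edge origin {origin!r}")

    @property
    def n_extracted(self) -> int:
        return sum(1 for *_, o in self.edges if o == ORIGIN_EXTRACTED)

    @property
    def n_fill(self) -> int:
        return sum(1 for *_, o in self.edges if o == ORIGIN_FILL)

    def degree(self) -> dict[str, int]:
        """Total (in + out) degree per node."""
        deg = {g: 0 for g in self.nodes}
        for p, c, _ in self.edges:
            deg[p] += 1
            deg[c] += 1
        return deg

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for p, c, origin in self.edges:
            g.add_edge(p, c, origin=origin)
        return g


def build_subnetwork(basal: BasalNetwork, extracted, delta: dict | None = None) -> Subnetwork:
    """Induced basal subgraph on the endpoints of the extracted edges.

    ``extracted`` is an iterable of (parent, child) pairs, each of which must
    be a basal edge; ``delta`` optionally carries per-group ΔECv annotations
    keyed by edge.
    """
    extracted = [tuple(e) for e in extracted]
    basal_set = set(basal.edges)
    for e in extracted:
        if e not in basal_set:
            raise ValueError(f"extracted edge {e[0]}->{e[1]} absent from basal network")
    nodes = tuple(sorted({g for e in extracted for g in e}))
    node_set = set(nodes)
    extracted_set = set(extracted)
    edges = [(p, c, ORIGIN_EXTRACTED) for p, c in sorted(extracted_set)]
    for p, c in sorted(basal_set - extracted_set):
        if p in node_set and c in node_set:
            edges.append((p, c, ORIGIN_FILL))
    freq = {e[:2]: basal.edge_freq[e[:2]] for e in edges if e[:2] in basal.edge_freq}
    return Subnetwork(nodes=nodes, edges=tuple(edges),
                      delta=dict(delta or {}), frequency=freq)


def hub_nodes(net: Subnetwork, fraction: float = 0.05) -> list[str]:
    """Top-degree genes: the ceil(fraction * n) highest total-degree nodes,
    extended to include every node tied with the cutoff degree."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    deg = net.degree()
    if not deg:
        return []
    ranked = sorted(deg, key=lambda g: (-deg[g], g))
    k = math.ceil(fraction * len(ranked))
    cutoff = deg[ranked[k - 1]]
    return [g for g in ranked if deg[g] >= cutoff]


def components(net: Subnetwork) -> list[set[str]]:
    """Weakly connected components, largest first (ties: smallest member)."""
    g = net.to_digraph()
    comps = [set(c) for c in nx.weakly_connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


# ---------------------------------------------------------------------------
# export


def write_subnetwork_sif(net: Subnetwork, path) -> None:
    with open(path, "w") as fh:
        for p, c, origin in sorted(net.edges):
            fh.write(f"{p}\t{origin}\t{c}\n")


def write_subnetwork_tsv(net: Subnetwork, path) -> None:
    group_names = sorted({g for d in net.delta.values() for g in d})
    rows = []
    for p, c, origin in sorted(net.edges):
        row = {"parent": p, "child": c, "origin": origin,
               "frequency": net.frequency.get((p, c), "")}
        for gname in group_names:
            row[f"delta_ecv_{gname}"] = net.delta.get((p, c), {}).get(gname, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_subnetwork_graphml(net: Subnetwork, path, hub_fraction: float = 0.05) -> None:
    """GraphML with origin/ΔECv/frequency edge attributes and degree/hub node
    attributes, consumable by standard network viewers."""
    g = net.to_digraph()
    deg = net.degree()
    hubs = set(hub_nodes(net, hub_fraction)) if net.nodes else set()
    for node in g.nodes:
        g.nodes[node]["degree"] = deg[node]
        g.nodes[node]["hub"] = node in hubs
    for p, c in g.edges:
        if (p, c) in net.frequency:
            g.edges[p, c]["frequency"] = float(net.frequency[(p, c)])
        for gname, val in net.delta.get((p, c), {}).items():
            g.edges[p, c][f"delta_ecv_{gname}"] = float(val)
    nx.write_graphml(g, path)
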