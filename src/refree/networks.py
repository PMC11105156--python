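"""Functional genotype networks and shortest-path statistics.

Nodes are variants predicted functional under a fitted model (by default:
strong activator on at least one RE; a flag switches to weak-or-strong),
labeled ERE-specific, SRE-specific, or promiscuous.  Edges connect variants
one mutational step apart under an :class:`~refree.sequence_space.AdjacencyRule`;
with the genetic-code rule the serine codon groups are split into S/Z nodes.
Because nonfunctional variants are removed, network distances can exceed the
number of sites even under hamming adjacency.

Path statistics between two nodes summarize how many shortest paths exist and
how distinct they are.  With S the number of genotypes along one shortest
path, G_u the unique genotypes on any shortest path, and E the unique edges on
any shortest path, the effective path counts are ``P_g = (G_u - 2)/(S - 1)``
and ``P_e = E/S``, and the path distinctiveness is ``D = P_g**2 / P_e``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model import CoefficientTable, predict_landscape_classes
from .sequence_space import (
    AdjacencyRule,
    Genotype,
    InputError,
    SERINE_SPLIT_ALPHABET,
    serine_collapse,
    serine_expand,
)

PHENOTYPES = ("ERE-specific", "SRE-specific", "promiscuous")


def build_network(
    coeffs: CoefficientTable,
    rule: AdjacencyRule | None = None,
    functional_def: str = "strong",
) -> nx.Graph:
    """Graph of functional variants with phenotype labels.

    ``functional_def`` is ``"strong"`` (strong on >= 1 RE; the default) or
    ``"weak-or-strong"``.  Node labels use the same binding predicate:
    ERE-specific nodes bind ERE and not SRE, SRE-specific the reverse,
    promiscuous both.  Nodes are genotype strings; with a serine-split rule
    each functional sequence contributes all of its S/Z split versions, and
    every node also records its 20-letter ``sequence``.
    """
    if functional_def not in ("strong", "weak-or-strong"):
        raise InputError(f"unknown functional definition {functional_def!r}")
    cutoff = 2 if functional_def == "strong" else 1
    rule = rule or AdjacencyRule("hamming")
    cls_e, cls_s = predict_landscape_classes(coeffs)
    bound_e = cls_e >= cutoff
    bound_s = cls_s >= cutoff
    functional = np.flatnonzero(bound_e | bound_s)
    space = coeffs.space
    if len(functional) == 0:
        warnings.warn("no functional genotypes; returning an empty network")
        return nx.Graph()

    split = rule.mode == "genetic_code" and rule.serine_split
    net = nx.Graph()
    label_of: dict[str, str] = {}
    for idx in functional:
        g = space.decode(int(idx))
        if bound_e[idx] and bound_s[idx]:
            label = "promiscuous"
        elif bound_e[idx]:
            label = "ERE-specific"
        else:
            label = "SRE-specific"
        nodes = serine_expand(g) if split else [g]
        for node in nodes:
            name = str(node)
            net.add_node(name, phenotype=label, sequence=str(g))
            label_of[name] = label

    adj = rule.state_adjacency()
    alphabet = (
        SERINE_SPLIT_ALPHABET if split else space.alphabet
    )
    for name in list(net.nodes):
        states = tuple(name)
        for site, current in enumerate(states):
            for other in alphabet:
                if other == current:
                    continue
                if adj is not None and other not in adj.get(current, ()):
                    continue
                nbr = "".join(
                    states[:site] + (other,) + states[site + 1 :]
                )
                if nbr in label_of:
                    net.add_edge(name, nbr)
    return net


def components(net: nx.Graph) -> list[int]:
    """Connected-component sizes, largest first."""
    return sorted(
        (len(c) for c in nx.connected_components(net)), reverse=True
    )


def _node_name(node):
    return str(node) if isinstance(node, Genotype) else node


def min_distance_to_label(
    net: nx.Graph, start, target_label: str
) -> float:
    """Shortest-path distance from ``start`` to the nearest node with
    ``target_label``; ``inf`` if none is reachable."""
    start = _node_name(start)
    if start not in net:
        raise InputError(f"start node {start!r} not in network")
    lengths = nx.single_source_shortest_path_length(net, start)
    best = math.inf
    for node, d in lengths.items():
        if net.nodes[node].get("phenotype") == target_label and d < best:
            best = d
    return best


def _bfs_levels(net: nx.Graph, source: str) -> tuple[dict, dict]:
    """Distances and shortest-path counts from ``source`` (layered DP)."""
    dist = {source: 0}
    count = {source: 1}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in net[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    count[v] = count[u]
                    nxt.append(v)
                elif dist[v] == dist[u] + 1:
                    count[v] += count[u]
        frontier = nxt
    return dist, count


def count_shortest_paths(net: nx.Graph, a, b) -> int:
    """Number of distinct shortest paths between two nodes (two paths are
    distinct if they differ in at least one genotype); 0 if unreachable."""
    a, b = _node_name(a), _node_name(b)
    dist, count = _bfs_levels(net, a)
    return count.get(b, 0)


@dataclass
class PathSetSummary:
    """Shortest-path-set statistics between two genotypes."""

    s: int  # genotypes along one shortest path
    g_unique: int  # unique genotypes on any shortest path
    e_unique: int  # unique edges on any shortest path
    n_paths: int
    p_g: float
    p_e: float
    d: float
    degenerate: bool  # direct edge (S == 2)


def path_distinctiveness(net: nx.Graph, a, b) -> PathSetSummary:
    """S, G_u, E, P_g, P_e and D for the shortest paths between two nodes.

    A node lies on some shortest path iff its distances from both endpoints
    sum to d(a, b); an edge (u, v) iff it advances one layer on such a path.
    """
    a, b = _node_name(a), _node_name(b)
    if a == b:
        raise InputError("endpoints must differ")
    dist_a, count_a = _bfs_levels(net, a)
    if b not in dist_a:
        raise InputError(f"{b!r} is unreachable from {a!r}")
    dist_b, count_b = _bfs_levels(net, b)
    d_ab = dist_a[b]
    on_path = [
        v
        for v in dist_a
        if v in dist_b and dist_a[v] + dist_b[v] == d_ab
    ]
    edges = set()
    for u in on_path:
        for v in net[u]:
            if (
                v in dist_b
                and dist_a.get(u, -1) + 1 + dist_b[v] == d_ab
            ):
                edges.add(frozenset((u, v)))
    s = d_ab + 1
    g_u = len(on_path)
    e = len(edges)
    p_g = (g_u - 2) / (s - 1)
    p_e = e / s
    return PathSetSummary(
        s=s,
        g_unique=g_u,
        e_unique=e,
        n_paths=count_a[b],
        p_g=p_g,
        p_e=p_e,
        d=p_g**2 / p_e,
        degenerate=(s == 2),
    )


def collapse_serine_nodes(net: nx.Graph) -> nx.Graph:
    """Merge S/Z split nodes back to 20-letter sequences for reporting."""
    out = nx.Graph()
    for name, data in net.nodes(data=True):
        seq = str(serine_collapse(name))
        out.add_node(seq, phenotype=data.get("phenotype"))
    for u, v in net.edges:
        cu, cv = str(serine_collapse(u)), str(serine_collapse(v))
        if cu != cv:
            out.add_edge(cu, cv)
    return out


def nodes_with_label(net: nx.Graph, label: str) -> list[str]:
    return [
        n for n, d in net.nodes(data=True) if d.get("phenotype") == label
    ]
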