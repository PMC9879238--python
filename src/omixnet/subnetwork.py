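"""Seed-centered subnetwork extraction from an inferred GGM."""

from __future__ import annotations

import difflib

import networkx as nx

from .errors import AnalysisError


def resolve_seeds(network: nx.Graph, seeds: list[str]) -> list[str]:
    """Map seed names to node ids: exact match first, then a
    case-insensitive fallback that errors on ambiguity. Unknown seeds raise
    with close-match suggestions."""
    nodes = list(network.nodes)
    lower = {}
    for n in nodes:
        lower.setdefault(str(n).lower(), []).append(n)
    resolved = []
    for seed in seeds:
        if seed in network:
            resolved.append(seed)
            continue
        candidates = lower.get(str(seed).lower(), [])
        if len(candidates) == 1:
            resolved.append(candidates[0])
        elif len(candidates) > 1:
            raise AnalysisError(
                f"seed {seed!r} is ambiguous (case-insensitive matches: {candidates})"
            )
        else:
            near = difflib.get_close_matches(str(seed), [str(n) for n in nodes], n=5)
            raise AnalysisError(f"unknown seed {seed!r}; close matches: {near}")
    return resolved


def neighborhood(network: nx.Graph, seeds: list[str], max_depth: int = 2) -> set:
    """Nodes within ``max_depth`` unweighted hops of at least one seed.

    Seeds themselves are included (distance 0). Edge weights are ignored.
    """
    if max_depth < 0:
        raise AnalysisError("max_depth must be >= 0")
    resolved = resolve_seeds(network, seeds)
    out: set = set()
    for seed in resolved:
        out.update(nx.single_source_shortest_path_length(network, seed, cutoff=max_depth))
    return out


def induced_subgraph(network: nx.Graph, nodes) -> nx.Graph:
    """Subnetwork on ``nodes`` keeping exactly the edges with both
    endpoints inside; node and edge attributes are preserved."""
    missing = set(nodes) - set(network.nodes)
    if missing:
        raise AnalysisError(f"nodes not in network: {sorted(missing)[:5]}")
    sub = network.subgraph(nodes).copy()
    sub.graph.update(network.graph)
    return sub


def extract_subnetwork(
    network: nx.Graph, seeds: list[str], max_depth: int = 2
) -> nx.Graph:
    """Convenience: induced subgraph on the seed neighborhood."""
    return induced_subgraph(network, neighborhood(network, seeds, max_depth))
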