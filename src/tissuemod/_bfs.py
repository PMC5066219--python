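"""Breadth-first-search primitives shared by the network statistics.

All distances are unweighted hop counts on an undirected graph. The
helpers operate on a plain adjacency dict (node -> tuple of neighbors),
which is much faster to traverse repeatedly than a networkx view when a
randomization null evaluates the same statistic thousands of times.
"""

from __future__ import annotations

from collections import deque
from typing import Hashable, Iterable, Mapping

import networkx as nx

Adjacency = Mapping[Hashable, tuple]


def adjacency(g: nx.Graph) -> dict:
    """Freeze a networkx graph into an adjacency dict of tuples."""
    return {node: tuple(g.adj[node]) for node in g.nodes}


def multi_source_distances(adj: Adjacency, sources: Iterable) -> dict:
    """Hop distance from every reachable node to the nearest source."""
    dist = {s: 0 for s in sources if s in adj}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        du = dist[u] + 1
        for v in adj[u]:
            if v not in dist:
                dist[v] = du
                queue.append(v)
    return dist


def nearest_member_distance(adj: Adjacency, members: frozenset | set, source) -> int | None:
    """Distance from ``source`` to the nearest *other* member of ``members``.

    BFS terminates as soon as another member is found; returns None when no
    other member is reachable.
    """
    seen = {source}
    queue = deque([(source, 0)])
    while queue:
        u, du = queue.popleft()
        for v in adj[u]:
            if v in seen:
                continue
            if v in members:
                return du + 1
            seen.add(v)
            queue.append((v, du + 1))
    return None


def largest_component(adj: Adjacency, members: set) -> int:
    """Size of the largest connected component of the subgraph induced by
    ``members`` (restricting both nodes and traversal to the member set)."""
    unvisited = set(members)
    best = 0
    while unvisited:
        start = unvisited.pop()
        size = 1
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v in unvisited:
                    unvisited.discard(v)
                    size += 1
                    queue.append(v)
        if size > best:
            best = size
    return best
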