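"""Independent brute-force oracles used to validate the centrality code.

The betweenness oracle enumerates every shortest path explicitly (BFS
distance layering + recursive path reconstruction) and accumulates
fractional pass-through counts.  It shares no code path with the
library's Brandes-based implementation.
"""

import itertools
from collections import deque


def _bfs_dist(adj, s):
    dist = {s: 0}
    q = deque([s])
    while q:
        v = q.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                q.append(u)
    return dist


def all_shortest_paths(adj, s, t):
    """Every shortest s–t path as a node list, by explicit enumeration."""
    dist = _bfs_dist(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(v, suffix):
        if v == s:
            paths.append([s] + suffix)
            return
        for u in adj[v]:
            if u in dist and dist[u] == dist[v] - 1:
                back(u, [v] + suffix)

    back(t, [])
    return paths


def brute_force_betweenness(graph):
    """Unnormalized betweenness by summing path shares over all pairs."""
    adj = {v: set(graph[v]) for v in graph}
    bet = {v: 0.0 for v in adj}
    for s, t in itertools.combinations(sorted(adj), 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for path in paths:
            for v in path[1:-1]:
                bet[v] += 1.0 / sigma
    return bet
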