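"""Node centralities and Freeman network centralization.

Four metrics are supported, all on unweighted simple graphs (the edge
confidence is used only for thresholding, never as a path weight):

* ``betweenness`` — shortest-path betweenness, g(v) = Σ_{s≠v≠t}
  σ_st(v)/σ_st over unordered pairs, endpoints excluded; disconnected
  pairs contribute nothing.
* ``degree`` — number of neighbours.
* ``closeness`` — (number of other reachable nodes) / (sum of shortest
  distances to them); an isolated node scores 0.
* ``flow_betweenness`` — current-flow (random-walk) betweenness via the
  Laplacian formulation, computed independently on each connected
  component of size >= 2; singletons score 0.  Counts contributions from
  all paths, not only the shortest.

Centralization is the Freeman index Σ_v (c_max − c_v) / (n − 1) on
normalized centralities: 1 for a star under betweenness, 0 for any
vertex-transitive graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph import PPINetwork

METRICS = ("betweenness", "degree", "closeness", "flow_betweenness")

#: solver tolerance for the current-flow linear systems
FLOW_SOLVER_TOL = 1e-10


@dataclass
class CentralityVector:
    """Per-node scores for one metric, with connected-component attribution."""

    metric: str
    values: dict[str, float]
    component_id: dict[str, int]
    normalized: bool = False

    def component_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for cid in self.component_id.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        return sizes


def _components(g: nx.Graph) -> dict[str, int]:
    comp: dict[str, int] = {}
    # sort components by (-size, min node) for a stable, reproducible numbering
    parts = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    for cid, nodes in enumerate(parts):
        for v in nodes:
            comp[v] = cid
    return comp


def _pair_norm(nc: int) -> float:
    """Number of unordered non-endpoint pairs in a component of size nc."""
    return (nc - 1) * (nc - 2) / 2.0


def betweenness(network: PPINetwork, normalized: bool = False) -> CentralityVector:
    """Shortest-path betweenness (Brandes); normalization is per component size."""
    g = network.g
    comp = _components(g)
    raw = nx.betweenness_centrality(g, normalized=False)
    if normalized:
        sizes = {}
        for v, cid in comp.items():
            sizes[cid] = sizes.get(cid, 0) + 1
        raw = {
            v: (raw[v] / _pair_norm(sizes[comp[v]]) if sizes[comp[v]] > 2 else 0.0)
            for v in g
        }
    return CentralityVector("betweenness", {v: float(raw[v]) for v in g}, comp, normalized)


def degree_centrality(network: PPINetwork, normalized: bool = False) -> CentralityVector:
    g = network.g
    n = g.number_of_nodes()
    div = (n - 1) if (normalized and n > 1) else 1
    vals = {v: g.degree(v) / div for v in g}
    return CentralityVector("degree", vals, _components(g), normalized)


def closeness(network: PPINetwork) -> CentralityVector:
    """Reachable-only closeness: k / Σ d(v, u) over the k reachable nodes u."""
    vals = nx.closeness_centrality(network.g, wf_improved=False)
    return CentralityVector(
        "closeness", {v: float(vals[v]) for v in network.g}, _components(network.g), True
    )


def flow_betweenness(network: PPINetwork) -> CentralityVector:
    """Current-flow betweenness per connected component, endpoints excluded."""
    g = network.g
    comp = _components(g)
    vals: dict[str, float] = {v: 0.0 for v in g}
    for nodes in nx.connected_components(g):
        if len(nodes) < 2:
            continue
        sub = g.subgraph(sorted(nodes))
        try:
            cf = nx.current_flow_betweenness_centrality(sub, normalized=False)
        except Exception as exc:  # pragma: no cover - solver failure path
            cid = comp[min(nodes)]
            raise RuntimeError(f"current-flow solve failed on component {cid}") from exc
        for v, x in cf.items():
            # clip the tiny negative round-off the solver can produce
            vals[v] = max(float(x), 0.0)
    return CentralityVector("flow_betweenness", vals, comp, False)


def compute(network: PPINetwork, metric: str, normalized: bool = False) -> CentralityVector:
    """Dispatch by metric name (one of :data:`METRICS`)."""
    if metric == "betweenness":
        return betweenness(network, normalized=normalized)
    if metric == "degree":
        return degree_centrality(network, normalized=normalized)
    if metric == "closeness":
        return closeness(network)
    if metric == "flow_betweenness":
        return flow_betweenness(network)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _convention_normalize(vector: CentralityVector) -> dict[str, float]:
    """Normalize raw scores by the metric's conventional divisor."""
    if vector.normalized:
        return vector.values
    sizes = vector.component_sizes()
    out = {}
    n = len(vector.values)
    for v, x in vector.values.items():
        nc = sizes[vector.component_id[v]]
        if vector.metric == "degree":
            out[v] = x / (n - 1) if n > 1 else 0.0
        elif vector.metric in ("betweenness", "flow_betweenness"):
            out[v] = x / _pair_norm(nc) if nc > 2 else 0.0
        else:
            out[v] = x
    return out


def centralization(vector: CentralityVector, mode: str = "relative") -> float:
    """Freeman-style centralization: how concentrated the centrality is.

    The default ``relative`` mode computes Σ_v (c_max − c_v) / ((n − 1)
    c_max): it is invariant to positive rescaling of the scores, lies in
    [0, 1] for any non-negative vector, equals 1.0 for a star under
    betweenness and 0.0 for any vertex-transitive graph.  ``freeman``
    instead applies Σ_v (c_max − c_v) / (n − 1) to convention-normalized
    scores.  The two agree whenever c_max attains the normalized maximum
    of 1 (as in a star).  Requires n >= 3.
    """
    n = len(vector.values)
    if n < 3:
        raise ValueError(f"centralization undefined for n={n} < 3 nodes")
    if mode == "relative":
        cmax = max(vector.values.values())
        if cmax == 0:
            return 0.0
        return sum(cmax - x for x in vector.values.values()) / ((n - 1) * cmax)
    if mode == "freeman":
        c = _convention_normalize(vector)
        cmax = max(c.values())
        return sum(cmax - x for x in c.values()) / (n - 1)
    raise ValueError(f"unknown centralization mode {mode!r}")
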