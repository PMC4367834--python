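"""Graph data model and I/O for protein-interaction networks.

The central container is :class:`PPINetwork`, a thin wrapper around an
undirected simple :class:`networkx.Graph` whose nodes are gene symbols and
whose edges carry a confidence score in [0, 1].  Nodes additionally carry

* ``origin`` — ``"seed"`` or ``"expanded"`` (how the node entered a
  disease network), and
* ``label`` — ``"damaged"`` or ``"intact"`` (variant-evidence status),

both ``None`` until assigned.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

log = logging.getLogger(__name__)

SEED = "seed"
EXPANDED = "expanded"
DAMAGED = "damaged"
INTACT = "intact"


class PPINetwork:
    """Undirected simple gene-interaction graph.

    Parameters
    ----------
    graph
        Underlying :class:`networkx.Graph`.  Self-loops are rejected.
    name
        Human-readable network name (disease or module).
    """

    def __init__(self, graph: nx.Graph | None = None, name: str = ""):
        self.g = graph if graph is not None else nx.Graph()
        if any(u == v for u, v in nx.selfloop_edges(self.g)):
            raise ValueError("PPINetwork must not contain self-loops")
        self.name = name
        #: seed symbols that were requested but absent from the background
        self.unmapped_seeds: list[str] = []

    # -- basic views ---------------------------------------------------
    @property
    def nodes(self):
        return self.g.nodes

    @property
    def edges(self):
        return self.g.edges

    def number_of_nodes(self) -> int:
        return self.g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.g.number_of_edges()

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.g

    def __len__(self) -> int:
        return self.g.number_of_nodes()

    # -- attributes ----------------------------------------------------
    def origins(self) -> dict[str, str | None]:
        return {v: self.g.nodes[v].get("origin") for v in self.g}

    def labels(self) -> dict[str, str | None]:
        return {v: self.g.nodes[v].get("label") for v in self.g}

    def set_labels(self, labels: dict[str, str]) -> None:
        """Assign damaged/intact labels from a gene → label mapping."""
        for v in self.g:
            lab = labels.get(v)
            if lab is not None and lab not in (DAMAGED, INTACT):
                raise ValueError(f"invalid label {lab!r} for node {v}")
            self.g.nodes[v]["label"] = lab
        missing = [v for v in self.g if self.g.nodes[v].get("label") is None]
        if missing:
            log.warning("%d network genes left unlabelled", len(missing))

    def damaged_nodes(self) -> list[str]:
        return [v for v in self.g if self.g.nodes[v].get("label") == DAMAGED]

    def intact_nodes(self) -> list[str]:
        return [v for v in self.g if self.g.nodes[v].get("label") == INTACT]

    def copy(self) -> "PPINetwork":
        out = PPINetwork(self.g.copy(), self.name)
        out.unmapped_seeds = list(self.unmapped_seeds)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PPINetwork(name={self.name!r}, nodes={self.number_of_nodes()}, "
            f"edges={self.number_of_edges()})"
        )


def load_interactions(
    path: str | Path,
    score_threshold: float = 0.7,
    score_scale: str = "auto",
    name: str = "",
) -> PPINetwork:
    """Read a STRING-style edge table and threshold on confidence.

    The file holds one interaction per line: two gene identifiers and a
    numeric confidence, whitespace- or tab-delimited.  A header line and
    ``#`` comments are tolerated.  Confidence may be on the unit scale
    ([0, 1]) or STRING's combined-score scale (0–1000); with
    ``score_scale="auto"`` the thousand scale is assumed as soon as any
    score exceeds 1.  Duplicate and reversed pairs collapse to one
    undirected edge keeping the maximum confidence; self-interactions are
    dropped (counted in a warning).  Only edges with confidence >=
    ``score_threshold`` are retained, and only nodes incident to a
    retained edge appear in the result.

    Raises
    ------
    ValueError
        For a threshold outside [0, 1], an unknown ``score_scale``, or a
        non-numeric score (the message names the offending line).
    OSError
        If the file cannot be read.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError(f"score_threshold must be in [0, 1], got {score_threshold}")
    if score_scale not in ("auto", "unit", "thousand"):
        raise ValueError(f"unknown score_scale {score_scale!r}")

    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = float(raw)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(f"{path}: line {lineno}: non-numeric score {raw!r}") from None
            rows.append((a, b, score))

    if not rows:
        log.warning("%s: empty edge file, returning empty network", path)
        return PPINetwork(name=name)

    if score_scale == "auto":
        score_scale = "thousand" if any(r[2] > 1.0 for r in rows) else "unit"
    divisor = 1000.0 if score_scale == "thousand" else 1.0

    best: dict[tuple[str, str], float] = {}
    n_self = 0
    for a, b, score in rows:
        a, b = a.strip(), b.strip()
        if a == b:
            n_self += 1
            continue
        conf = score / divisor
        key = (a, b) if a < b else (b, a)
        if conf > best.get(key, -1.0):
            best[key] = conf
    if n_self:
        log.warning("%s: dropped %d self-interaction rows", path, n_self)

    g = nx.Graph()
    for (a, b), conf in best.items():
        if conf >= score_threshold:
            g.add_edge(a, b, confidence=conf)
    return PPINetwork(g, name=name or str(Path(path).stem))


def load_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line, ``#`` comments allowed."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                genes.append(sym)
    return genes


def _damaged_incident(net: PPINetwork, u: str, v: str) -> bool:
    lab = net.g.nodes
    return lab[u].get("label") == DAMAGED or lab[v].get("label") == DAMAGED


def write_network(net: PPINetwork, path: str | Path, format: str = "graphml") -> None:
    """Write a network to GraphML or a plain edge TSV.

    GraphML carries per-node ``origin``, ``label`` and unnormalized
    ``betweenness`` attributes plus a per-edge ``damaged_incident`` flag
    (true when at least one endpoint is damaged), matching the style of
    network figures where damage-touching edges are highlighted.  The
    edge TSV keeps only ``protein1 protein2 combined_score``.
    """
    if format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("protein1\tprotein2\tcombined_score\n")
            for u, v in sorted(map(sorted, net.g.edges())):
                conf = net.g.edges[u, v].get("confidence", 1.0)
                fh.write(f"{u}\t{v}\t{conf:g}\n")
        return
    if format != "graphml":
        raise ValueError(f"unknown format {format!r}")

    from .centrality import betweenness  # local import avoids a cycle

    g = nx.Graph()
    g.graph["name"] = net.name
    bc = betweenness(net).values if net.number_of_nodes() else {}
    for v in net.g:
        attrs = net.g.nodes[v]
        g.add_node(
            v,
            origin=attrs.get("origin") or "",
            label=attrs.get("label") or "",
            betweenness=float(bc.get(v, 0.0)),
        )
    for u, v in net.g.edges():
        g.add_edge(
            u,
            v,
            confidence=float(net.g.edges[u, v].get("confidence", 1.0)),
            damaged_incident=_damaged_incident(net, u, v),
        )
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> PPINetwork:
    """Read back a network written by :func:`write_network` (GraphML)."""
    raw = nx.read_graphml(path)
    g = nx.Graph()
    for v, attrs in raw.nodes(data=True):
        g.add_node(
            v,
            origin=attrs.get("origin") or None,
            label=attrs.get("label") or None,
        )
    for u, v, attrs in raw.edges(data=True):
        g.add_edge(u, v, confidence=float(attrs.get("confidence", 1.0)))
    return PPINetwork(g, name=raw.graph.get("name", ""))
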