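"""Construct disease/process networks from seed genes.

A disease network is grown from a set of seed genes (e.g. genes with a
reported causative relationship to the disorder) mapped onto a thresholded
background interaction network, then expanded by their neighbours at
distance one.  The result is the full *induced* subgraph on that node set:
edges among expanded neighbours are retained, not only seed–neighbour
edges.  Pathway modules are instead cut out directly as induced subgraphs
on an explicit member list, with no expansion.
"""

from __future__ import annotations

import logging

import networkx as nx

from .graph import EXPANDED, SEED, PPINetwork

log = logging.getLogger(__name__)


def build_disease_network(
    background: PPINetwork,
    seeds: list[str],
    name: str = "",
    radius: int = 1,
) -> PPINetwork:
    """Grow a disease network: seeds plus neighbours within ``radius`` hops.

    Node set = (seeds found in the background) ∪ (nodes within ``radius``
    of any seed); edge set = the background subgraph induced on it.  Each
    node's ``origin`` attribute records whether it was a seed or entered
    through expansion.  Seeds absent from the background are recorded on
    the returned network's ``unmapped_seeds`` (and logged), never silently
    dropped.

    Raises
    ------
    ValueError
        If ``seeds`` is empty or no seed maps into the background.
    """
    if not seeds:
        raise ValueError("seed list is empty")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    seeds = [s.strip() for s in seeds]
    present = [s for s in dict.fromkeys(seeds) if s in background.g]
    missing = [s for s in dict.fromkeys(seeds) if s not in background.g]
    if not present:
        raise ValueError(f"no seed gene maps into the background network: {missing}")
    if missing:
        log.warning("%d seed genes not in background: %s", len(missing), missing)

    keep: set[str] = set(present)
    frontier = set(present)
    for _ in range(radius):
        frontier = {n for v in frontier for n in background.g.neighbors(v)} - keep
        keep |= frontier

    sub = nx.Graph(background.g.subgraph(keep))
    seed_set = set(present)
    for v in sub:
        sub.nodes[v]["origin"] = SEED if v in seed_set else EXPANDED
    net = PPINetwork(sub, name=name)
    net.unmapped_seeds = missing
    return net


def subset_module(background: PPINetwork, member_genes: list[str], name: str = "") -> PPINetwork:
    """Induced subgraph on an explicit gene list, with no expansion.

    All retained nodes get ``origin="seed"``.  Raises ``ValueError`` when
    the member list is empty or none of its genes occur in the background.
    """
    if not member_genes:
        raise ValueError("member gene list is empty")
    members = [m.strip() for m in dict.fromkeys(member_genes)]
    present = [m for m in members if m in background.g]
    if not present:
        raise ValueError(f"no member gene maps into the background network: {members}")
    missing = [m for m in members if m not in background.g]
    if missing:
        log.warning("%d module genes not in background: %s", len(missing), missing)
    sub = nx.Graph(background.g.subgraph(present))
    for v in sub:
        sub.nodes[v]["origin"] = SEED
    net = PPINetwork(sub, name=name)
    net.unmapped_seeds = missing
    return net
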