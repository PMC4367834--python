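"""Cell-line suitability scoring: the BC-ratio μ and its permutation null.

The suitability of a cell line for modelling a disease network is scored
by the fraction of total node centrality carried by the damaged genes,

    μ = Σ_{v damaged} c(v) / Σ_v c(v),          μ ∈ [0, 1],

with c(v) shortest-path betweenness by default (the *BC-ratio*); degree,
closeness and current-flow betweenness are drop-in alternatives.  A high
μ means the cell line's mutations sit on the network's information
bottlenecks; a low μ means the damage is peripheral.

Significance is assessed by a label permutation test: the topology and
the damaged/intact counts are held fixed, the label assignment is
shuffled, and p_BC is the probability that a shuffled labeling yields a
strictly higher μ than observed.  p_BC > 0.05 means the damaged genes do
not preferentially occupy central positions — evidence that the cell line
is an acceptable genetic background for that disease network.

Centralities depend only on topology, so they are computed once per
network and only the label sums change across permutations (an exact
optimization, not an approximation).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import centrality as _cent
from .damage import DamageLabeling
from .graph import DAMAGED, INTACT, SEED, PPINetwork

log = logging.getLogger(__name__)


@dataclass
class SuitabilityScore:
    """Result of scoring one network with one centrality metric."""

    network_name: str
    metric: str
    mu: float
    p_value: float | None
    p_display: str | None  # "<1/n" style string when the count is 0
    p_conservative: float | None  # (count+1)/(n+1) variant
    n_permutations: int
    n_damaged: int
    n_intact: int
    rng_seed: int | None
    scope: str = "whole_graph"  # or "largest_component"

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0 + 1e-12:
            raise ValueError(f"mu={self.mu} outside [0, 1]")


def _labels_from(network: PPINetwork, labeling: DamageLabeling | None) -> dict[str, str]:
    if labeling is not None:
        labeling.apply(network)
    labels = network.labels()
    missing = sorted(v for v, lab in labels.items() if lab not in (DAMAGED, INTACT))
    if missing:
        raise ValueError(f"unlabelled nodes: {missing}")
    return labels  # type: ignore[return-value]


def suitability_ratio(vector: _cent.CentralityVector, labels: dict[str, str]) -> float:
    """μ = centrality mass on damaged nodes / total centrality mass.

    ``labels`` maps every node of the vector to "damaged"/"intact".  When
    the total mass is zero (e.g. an edgeless graph under betweenness) the
    ratio is defined as 0 with a warning.
    """
    missing = sorted(v for v in vector.values if labels.get(v) not in (DAMAGED, INTACT))
    if missing:
        raise ValueError(f"unlabelled nodes: {missing}")
    total = sum(vector.values.values())
    if total == 0:
        log.warning("total %s mass is zero; ratio defined as 0", vector.metric)
        return 0.0
    dam = sum(x for v, x in vector.values.items() if labels[v] == DAMAGED)
    return dam / total


def _scope_vector(network: PPINetwork, metric: str) -> tuple[_cent.CentralityVector, str]:
    """Compute the metric's vector and its scoring scope.

    Shortest-path metrics are scored on the whole (possibly disconnected)
    graph.  Flow betweenness is only well defined within a component; on a
    disconnected graph it is scored on the largest connected component and
    the scope is flagged.
    """
    vec = _cent.compute(network, metric)
    import networkx as nx

    if metric == "flow_betweenness" and nx.number_connected_components(network.g) > 1:
        keep = {v for v, cid in vec.component_id.items() if cid == 0}  # component 0 is largest
        vec = _cent.CentralityVector(
            vec.metric,
            {v: x for v, x in vec.values.items() if v in keep},
            {v: 0 for v in keep},
            vec.normalized,
        )
        return vec, "largest_component"
    return vec, "whole_graph"


def permutation_test(
    network: PPINetwork,
    labeling: DamageLabeling | None = None,
    metric: str = "betweenness",
    n: int = 1000,
    seed: int | None = None,
) -> SuitabilityScore:
    """Score a labelled network and attach the permutation p-value p_BC.

    ``n`` random reassignments of the damaged/intact labels are drawn
    (topology and label counts fixed) and p_BC = #{μ_perm > μ_obs} / n,
    the probability of a strictly higher ratio under random damage
    placement.  A zero count is additionally reported as "<1/n".  A
    degenerate labeling (no damaged or no intact nodes in scope) makes
    every permutation identical, and p is reported as 1.0 with a warning.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    labels = _labels_from(network, labeling)
    vec, scope = _scope_vector(network, metric)
    scoped_labels = {v: labels[v] for v in vec.values}

    mu = suitability_ratio(vec, scoped_labels)
    nodes = sorted(vec.values)
    values = np.array([vec.values[v] for v in nodes], dtype=float)
    k = sum(1 for v in nodes if scoped_labels[v] == DAMAGED)
    n_nodes = len(nodes)

    if k == 0 or k == n_nodes:
        log.warning(
            "%s: degenerate labeling (%d damaged of %d): permutation test is uninformative",
            network.name, k, n_nodes,
        )
        return SuitabilityScore(
            network.name, metric, mu, 1.0, None, None, n, k, n_nodes - k, seed, scope
        )

    rng = np.random.default_rng(seed)
    total = values.sum()
    if total == 0:
        perm_mu = np.zeros(n)
    else:
        # one argpartition per permutation: indices of k randomly chosen nodes
        draws = rng.random((n, n_nodes))
        idx = np.argpartition(draws, k - 1, axis=1)[:, :k]
        perm_mu = values[idx].sum(axis=1) / total

    count = int((perm_mu > mu + 1e-15).sum())
    p = count / n
    p_display = f"<1/{n}" if count == 0 else None
    if count == 0 and float(np.ptp(perm_mu)) < 1e-15:
        log.warning("%s: permutation statistic is constant (symmetric network?)", network.name)
    return SuitabilityScore(
        network.name, metric, mu, p, p_display, (count + 1) / (n + 1),
        n, k, n_nodes - k, seed, scope,
    )


def exact_permutation_p(
    network: PPINetwork,
    labeling: DamageLabeling | None = None,
    metric: str = "betweenness",
) -> float:
    """p_BC by exhaustive enumeration of all label placements.

    Feasible for small networks (C(n, k) placements).  Reference
    implementation for validating the Monte-Carlo test.
    """
    labels = _labels_from(network, labeling)
    vec, _ = _scope_vector(network, metric)
    scoped = {v: labels[v] for v in vec.values}
    mu = suitability_ratio(vec, scoped)
    nodes = sorted(vec.values)
    values = [vec.values[v] for v in nodes]
    k = sum(1 for v in nodes if scoped[v] == DAMAGED)
    total = sum(values)
    if total == 0:
        return 0.0
    count = 0
    n_comb = 0
    for combo in itertools.combinations(range(len(nodes)), k):
        n_comb += 1
        if sum(values[i] for i in combo) / total > mu + 1e-15:
            count += 1
    return count / n_comb


def seed_only_labeling(network: PPINetwork) -> DamageLabeling:
    """Damage labeling under the assumption that only seed genes are mutated."""
    origins = network.origins()
    if any(o is None for o in origins.values()):
        raise ValueError("network nodes lack seed/expanded origins")
    labels = {v: (DAMAGED if o == SEED else INTACT) for v, o in origins.items()}
    prov = {v: ["seed_only"] for v, lab in labels.items() if lab == DAMAGED}
    return DamageLabeling(labels, prov)


def score_seed_only(
    network: PPINetwork,
    metric: str = "betweenness",
    n: int = 1000,
    seed: int | None = None,
) -> SuitabilityScore:
    """Permutation-test scoring with damaged := seed genes, intact := expansion."""
    return permutation_test(network, seed_only_labeling(network), metric, n, seed)


def metric_correlation(
    networks: list[PPINetwork], method: str = "pearson"
) -> pd.DataFrame:
    """Per-node correlation between centrality metrics, averaged over networks.

    For each network the four per-node centrality vectors are correlated
    pairwise (Pearson by default, Spearman by flag); entries are then
    averaged across networks with equal weight.  A constant vector makes a
    pair undefined for that network; such entries are excluded from the
    average with a warning.
    """
    if not networks:
        raise ValueError("need at least one network")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    metrics = list(_cent.METRICS)
    sums = pd.DataFrame(0.0, index=metrics, columns=metrics)
    counts = pd.DataFrame(0, index=metrics, columns=metrics)
    for net in networks:
        if net.number_of_nodes() < 3:
            raise ValueError(f"network {net.name!r} has < 3 nodes")
        nodes = sorted(net.g.nodes)
        vecs = {
            m: np.array([_cent.compute(net, m).values[v] for v in nodes]) for m in metrics
        }
        for i, mi in enumerate(metrics):
            for mj in metrics[i:]:
                xi, xj = vecs[mi], vecs[mj]
                if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                    if mi != mj:
                        log.warning(
                            "%s: constant %s/%s vector, pair excluded", net.name, mi, mj
                        )
                        continue
                    r = 1.0
                elif mi == mj:
                    r = 1.0
                elif method == "pearson":
                    r = float(stats.pearsonr(xi, xj).statistic)
                else:
                    r = float(stats.spearmanr(xi, xj).statistic)
                sums.loc[mi, mj] += r
                sums.loc[mj, mi] += 0.0 if mi == mj else r
                counts.loc[mi, mj] += 1
                counts.loc[mj, mi] += 0 if mi == mj else 1
    with np.errstate(invalid="ignore"):
        out = sums / counts
    for m in metrics:
        out.loc[m, m] = 1.0
    return out


def rank_genes(network: PPINetwork, top: int | None = None) -> pd.DataFrame:
    """Rank genes under each centrality metric (rank 1 = most central).

    Ties are broken lexicographically by gene symbol; rows are ordered by
    the betweenness rank.  ``top`` truncates to the k best genes.
    """
    nodes = sorted(network.g.nodes)
    df = pd.DataFrame(index=pd.Index(nodes, name="gene"))
    for m in _cent.METRICS:
        vals = _cent.compute(network, m).values
        order = sorted(nodes, key=lambda v: (-vals[v], v))
        ranks = {v: i + 1 for i, v in enumerate(order)}
        df[f"rank_{m}"] = [ranks[v] for v in nodes]
    df = df.sort_values(["rank_betweenness", "gene"]).reset_index()
    if top is not None:
        df = df.head(top)
    return df


SUMMARY_COLUMNS = [
    "network", "nodes_total", "nodes_damaged", "nodes_intact", "edges",
    "centralization_betweenness", "ratio_degree", "ratio_closeness",
    "bc_ratio", "ratio_flow_bc", "flow_bc_scope_flag", "p_bc",
]


def summarize(
    networks: list[PPINetwork],
    labelings: list[DamageLabeling | None],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """One summary row per network: counts, centralization, all four ratios, p_BC.

    The flow-betweenness ratio of a disconnected network is computed on
    its largest connected component and flagged with ``*`` in
    ``flow_bc_scope_flag``.  p_BC refers to the betweenness-based ratio.
    """
    if len(networks) != len(labelings):
        raise ValueError("networks and labelings must align")
    rows = []
    for i, (net, labeling) in enumerate(zip(networks, labelings)):
        sub_seed = None if seed is None else (seed + i) % (2**31)
        labels = _labels_from(net, labeling)
        bc_score = permutation_test(net, None, "betweenness", n_permutations, sub_seed)
        ratios: dict[str, float] = {}
        flag = ""
        for metric in ("degree", "closeness", "flow_betweenness"):
            vec, scope = _scope_vector(net, metric)
            ratios[metric] = suitability_ratio(vec, {v: labels[v] for v in vec.values})
            if metric == "flow_betweenness" and scope == "largest_component":
                flag = "*"
        rows.append(
            {
                "network": net.name,
                "nodes_total": net.number_of_nodes(),
                "nodes_damaged": bc_score.n_damaged,
                "nodes_intact": bc_score.n_intact,
                "edges": net.number_of_edges(),
                "centralization_betweenness": _cent.centralization(_cent.betweenness(net))
                if net.number_of_nodes() >= 3
                else math.nan,
                "ratio_degree": ratios["degree"],
                "ratio_closeness": ratios["closeness"],
                "bc_ratio": bc_score.mu,
                "ratio_flow_bc": ratios["flow_betweenness"],
                "flow_bc_scope_flag": flag,
                "p_bc": bc_score.p_value,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
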