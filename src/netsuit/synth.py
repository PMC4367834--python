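"""Synthetic fixtures: parametric graphs, labelings and variant tables.

Everything here is deterministic for a fixed seed and produces inputs in
exactly the formats the readers consume, with a known ground truth, so
the whole pipeline is testable without any external database download.

Synthetic gene models are laid out non-overlapping on one artificial
chromosome (``chrS``): 1 kb genes separated by 1 kb gaps, which makes
interval-overlap outcomes unambiguous.  "Rare" planted variant
frequencies are drawn in [0, 0.05) (or omitted entirely — private
variants); "common" decoys in [0.05, 0.5], straddling the 5% rarity rule.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from . import centrality as _cent
from .damage import (
    RULE_CNV,
    RULE_SMALL_VARIANT,
    RULE_SV,
    DamageLabeling,
    GeneModel,
    IntervalEvent,
    SmallVariant,
)
from .graph import DAMAGED, INTACT, PPINetwork

GRAPH_KINDS = ("star", "path", "cycle", "tree", "erdos_renyi", "barabasi_albert")

GENE_LEN = 1000
GENE_GAP = 1000
CHROM = "chrS"


def _symbols(n: int) -> list[str]:
    return [f"G{i:03d}" for i in range(n)]


def make_graph(
    kind: str,
    n: int,
    p: float | None = None,
    m: int | None = None,
    seed: int | None = 0,
    name: str = "",
) -> PPINetwork:
    """Generate a named graph family as a :class:`PPINetwork`.

    ``p`` is the edge probability (erdos_renyi); ``m`` the attachment
    count (barabasi_albert).  Edge confidences are set to 1.0.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "cycle":
        g = nx.cycle_graph(n)
    elif kind == "tree":
        g = nx.random_labeled_tree(n, seed=seed)
    elif kind == "erdos_renyi":
        if p is None or not 0.0 <= p <= 1.0:
            raise ValueError("erdos_renyi requires edge probability p in [0, 1]")
        g = nx.erdos_renyi_graph(n, p, seed=seed)
    elif kind == "barabasi_albert":
        if m is None or not 1 <= m < n:
            raise ValueError("barabasi_albert requires attachment count 1 <= m < n")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    else:
        raise ValueError(f"unknown graph kind {kind!r}; choose from {GRAPH_KINDS}")
    syms = _symbols(n)
    g = nx.relabel_nodes(g, dict(enumerate(syms)))
    nx.set_edge_attributes(g, 1.0, "confidence")
    return PPINetwork(g, name=name or f"{kind}{n}")


def make_labeling(
    network: PPINetwork,
    n_damaged: int,
    mode: str = "uniform",
    seed: int | None = 0,
) -> DamageLabeling:
    """Label exactly ``n_damaged`` nodes damaged, by placement strategy.

    ``uniform`` draws them at random; ``top_betweenness`` damages the
    highest-betweenness nodes (central damage — the high-μ regime);
    ``periphery`` the lowest (peripheral damage — the low-μ regime).
    Betweenness ties break lexicographically.
    """
    nodes = sorted(network.g.nodes)
    if not 0 <= n_damaged <= len(nodes):
        raise ValueError(f"n_damaged={n_damaged} outside [0, {len(nodes)}]")
    if mode in ("top_betweenness", "periphery"):
        bc = _cent.betweenness(network).values
        order = sorted(nodes, key=lambda v: (-bc[v], v))
        chosen = order[:n_damaged] if mode == "top_betweenness" else order[::-1][:n_damaged]
    elif mode == "uniform":
        rng = np.random.default_rng(seed)
        chosen = list(rng.choice(nodes, size=n_damaged, replace=False))
    else:
        raise ValueError(f"unknown labeling mode {mode!r}")
    chosen_set = set(chosen)
    labels = {v: (DAMAGED if v in chosen_set else INTACT) for v in nodes}
    return DamageLabeling(labels, {v: [mode] for v in chosen_set})


def make_gene_models(n_genes: int) -> list[GeneModel]:
    """Non-overlapping 1 kb gene spans with 1 kb gaps on one chromosome."""
    out = []
    for i, sym in enumerate(_symbols(n_genes)):
        start = i * (GENE_LEN + GENE_GAP)
        out.append(GeneModel(sym, CHROM, start, start + GENE_LEN, "+" if i % 2 == 0 else "-"))
    return out


def make_variant_tables(
    n_genes: int,
    damaged_fraction: float,
    rule_mix: tuple[str, ...] = (RULE_SMALL_VARIANT, RULE_CNV, RULE_SV),
    seed: int | None = 0,
):
    """Plant damage evidence with known truth.

    Returns ``(gene_models, variants, events, truth)`` where running the
    damage annotator on the tables recovers ``truth`` exactly, including
    per-gene provenance.  Damaged genes receive evidence for one rule each
    (cycled through ``rule_mix``); intact genes receive only
    non-qualifying decoys — synonymous rare variants, common
    protein-altering variants, diploid copy-number segments and SVs
    present in the baseline set.
    """
    if not 0.0 <= damaged_fraction <= 1.0:
        raise ValueError("damaged_fraction must be in [0, 1]")
    bad = [r for r in rule_mix if r not in (RULE_SMALL_VARIANT, RULE_CNV, RULE_SV)]
    if bad or not rule_mix:
        raise ValueError(f"invalid rule_mix {rule_mix!r}")

    rng = np.random.default_rng(seed)
    genes = make_gene_models(n_genes)
    n_damaged = round(n_genes * damaged_fraction)
    damaged_idx = sorted(rng.choice(n_genes, size=n_damaged, replace=False))
    damaged_set = {genes[i].symbol for i in damaged_idx}

    variants: list[SmallVariant] = []
    events: list[IntervalEvent] = []
    provenance: dict[str, list[str]] = {}

    def rare_freqs():
        # a private variant (no panel observations) about a third of the time
        if rng.random() < 1 / 3:
            return {}
        return {
            src: float(rng.uniform(0.0, 0.049))
            for src in ("KG1000", "ESP6500", "CGBaseline")
            if rng.random() < 0.8
        }

    def common_freqs():
        return {"KG1000": float(rng.uniform(0.05, 0.5)), "ESP6500": float(rng.uniform(0.05, 0.5))}

    for j, i in enumerate(damaged_idx):
        gene = genes[i]
        rule = rule_mix[j % len(rule_mix)]
        provenance[gene.symbol] = [rule]
        pos1 = gene.start + int(rng.integers(0, GENE_LEN)) + 1  # 1-based
        if rule == RULE_SMALL_VARIANT:
            effect = str(rng.choice(["nonsynonymous", "splice_site", "frameshift_indel",
                                     "block_substitution", "stopgain"]))
            variants.append(
                SmallVariant(CHROM, pos1, "A", "G", effect, [gene.symbol],
                             rare_freqs(), str(rng.choice(["het", "hom"])))
            )
        elif rule == RULE_CNV:
            cn = int(rng.choice([0, 1, 3, 4]))
            events.append(IntervalEvent(CHROM, gene.start + 100, gene.end - 100, "cnv",
                                        copy_number=cn))
        else:  # rare SV, never seen in the baseline set
            sv_type = str(rng.choice(["deletion", "duplication", "inversion"]))
            events.append(IntervalEvent(CHROM, gene.start + 50, gene.end + 200, "sv",
                                        sv_type=sv_type, baseline_count=0))

    for i, gene in enumerate(genes):
        if gene.symbol in damaged_set:
            continue
        decoy = rng.random()
        pos1 = gene.start + int(rng.integers(0, GENE_LEN)) + 1
        if decoy < 0.3:  # rare but synonymous
            variants.append(SmallVariant(CHROM, pos1, "C", "T", "synonymous",
                                         [gene.symbol], rare_freqs(), "het"))
        elif decoy < 0.6:  # protein-altering but common
            variants.append(SmallVariant(CHROM, pos1, "G", "A", "nonsynonymous",
                                         [gene.symbol], common_freqs(), "het"))
        elif decoy < 0.8:  # diploid segment
            events.append(IntervalEvent(CHROM, gene.start, gene.end, "cnv", copy_number=2))
        else:  # SV present in the baseline set
            events.append(IntervalEvent(CHROM, gene.start, gene.end, "sv",
                                        sv_type="deletion", baseline_count=int(rng.integers(1, 9))))

    labels = {g.symbol: (DAMAGED if g.symbol in damaged_set else INTACT) for g in genes}
    truth = DamageLabeling(labels, provenance)
    return genes, variants, events, truth


# ----------------------------------------------------------------------
# Writers (inverse of the damage-module readers)
# ----------------------------------------------------------------------

def write_gene_models(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsymbol\tstrand\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t{g.strand}\n")


def write_variant_table(variants: list[SmallVariant], path) -> None:
    cols = "chrom\tpos\tref\talt\teffect\tgenes\tkg1000_af\tesp6500_af\tcgbaseline_af\tzygosity\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for v in variants:
            afs = [
                f"{v.freqs[s]:.17g}" if s in v.freqs else ""
                for s in ("KG1000", "ESP6500", "CGBaseline")
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.effect}\t"
                f"{','.join(v.gene_symbols)}\t{afs[0]}\t{afs[1]}\t{afs[2]}\t{v.zygosity}\n"
            )


def write_event_table(events: list[IntervalEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tkind\tvalue\n")
        for e in events:
            value = str(e.copy_number) if e.kind == "cnv" else f"{e.baseline_count}:{e.sv_type}"
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.kind}\t{value}\n")


def write_gene_list(genes: list[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
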