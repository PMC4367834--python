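"""Derive damaged/intact gene labels from variant, CNV and SV evidence.

A gene counts as *damaged* when any of three rules fires:

``rare_small_variant``
    it carries a protein-altering small variant (non-synonymous,
    splice-site, stop gain/loss, indel or block substitution) whose allele
    frequency is below 5% in every population panel in which it was
    observed (1000 Genomes, ESP6500, CG 69 baseline genomes); a variant
    reported in no panel — a private variant — is rare by definition;
``cnv``
    its span overlaps, by at least 1 bp, a copy-number segment called at a
    copy number different from the diploid baseline (gains and losses both
    count);
``rare_sv``
    its span overlaps a structural-variant event never observed in the
    baseline genome set (``baseline_count == 0``).

All other genes are intact.  Intervals are 0-based half-open throughout;
1-based inputs must be converted by the reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .graph import DAMAGED, INTACT, PPINetwork

log = logging.getLogger(__name__)

#: effect classes that qualify under the small-variant rule
DAMAGING_EFFECTS = frozenset(
    {
        "nonsynonymous",
        "splice_site",
        "stopgain",
        "stoploss",
        "frameshift_indel",
        "nonframeshift_indel",
        "block_substitution",
    }
)

FREQ_SOURCES = ("KG1000", "ESP6500", "CGBaseline")

RULE_SMALL_VARIANT = "rare_small_variant"
RULE_CNV = "cnv"
RULE_SV = "rare_sv"
RULE_EXTERNAL = "external_list"


@dataclass
class SmallVariant:
    """One SNV / indel / block substitution with population frequencies."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    effect: str
    gene_symbols: list[str]
    freqs: dict[str, float] = field(default_factory=dict)
    zygosity: str = "unknown"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for src, f in self.freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for {src} outside [0, 1]")


@dataclass
class IntervalEvent:
    """A CNV segment or SV event on 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    kind: str  # "cnv" | "sv"
    copy_number: int | None = None
    sv_type: str | None = None
    baseline_count: int | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"degenerate interval [{self.start}, {self.end})")
        if self.kind == "cnv" and self.copy_number is None:
            raise ValueError("cnv event requires copy_number")
        if self.kind == "sv" and self.baseline_count is None:
            raise ValueError("sv event requires baseline_count")


@dataclass
class GeneModel:
    """Merged genomic span of one gene (0-based half-open)."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"degenerate gene span for {self.symbol}")


@dataclass
class DamageLabeling:
    """Gene → damaged/intact map with the rules that fired per gene."""

    labels: dict[str, str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def damaged(self) -> set[str]:
        return {g for g, lab in self.labels.items() if lab == DAMAGED}

    def apply(self, network: PPINetwork, missing: str = "lenient") -> None:
        """Label every network node; unknown genes are intact (lenient) or an error (strict)."""
        unknown = [v for v in network.g if v not in self.labels]
        if unknown and missing == "strict":
            raise KeyError(f"network genes absent from labeling: {sorted(unknown)}")
        if unknown:
            log.warning("%d network genes not in labeling, marked intact", len(unknown))
        network.set_labels({v: self.labels.get(v, INTACT) for v in network.g})


def is_rare(variant: SmallVariant, threshold: float = 0.05) -> bool:
    """True iff the variant is below ``threshold`` in every panel that reports it.

    A variant absent from all panels (private) is rare.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return all(f < threshold for f in variant.freqs.values())


def label_genes(
    genes: list[GeneModel],
    variants: list[SmallVariant],
    events: list[IntervalEvent],
    rarity_threshold: float = 0.05,
    ploidy: int = 2,
) -> DamageLabeling:
    """Apply the three damage rules and return labels with provenance.

    Variants map to genes through their annotated ``gene_symbols``; CNV and
    SV events map through >= 1 bp interval overlap with the gene span.  The
    result is independent of input row order.
    """
    symbols = [g.symbol for g in genes]
    if len(set(symbols)) != len(symbols):
        raise ValueError("duplicate gene symbols in gene-model table")

    fired: dict[str, set[str]] = {g.symbol: set() for g in genes}

    for var in variants:
        if var.effect in DAMAGING_EFFECTS and is_rare(var, rarity_threshold):
            for sym in var.gene_symbols:
                if sym in fired:
                    fired[sym].add(RULE_SMALL_VARIANT)

    trees: dict[str, IntervalTree] = {}
    for i, ev in enumerate(events):
        trees.setdefault(ev.chrom, IntervalTree()).addi(ev.start, ev.end, ev)
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(gene.start, gene.end):
            ev = hit.data
            if ev.kind == "cnv" and ev.copy_number != ploidy:
                fired[gene.symbol].add(RULE_CNV)
            elif ev.kind == "sv" and ev.baseline_count == 0:
                fired[gene.symbol].add(RULE_SV)

    labels = {s: (DAMAGED if fired[s] else INTACT) for s in fired}
    provenance = {s: sorted(r) for s, r in fired.items() if r}
    return DamageLabeling(labels, provenance)


def load_damaged_list(path: str | Path) -> DamageLabeling:
    """Load a precomputed damaged-gene list (one symbol per line).

    Listed genes are damaged with provenance ``external_list``; any other
    gene becomes intact when the labeling is applied to a network.
    """
    from .graph import load_gene_list

    genes = load_gene_list(path)
    if not genes:
        log.warning("%s: empty damaged-gene list, all genes will be intact", path)
    labels = {g: DAMAGED for g in genes}
    return DamageLabeling(labels, {g: [RULE_EXTERNAL] for g in genes})


# ----------------------------------------------------------------------
# Readers for the plain-text tables
# ----------------------------------------------------------------------

_VARIANT_COLS = [
    "chrom", "pos", "ref", "alt", "effect", "genes",
    "kg1000_af", "esp6500_af", "cgbaseline_af", "zygosity",
]


def load_variant_table(path: str | Path) -> list[SmallVariant]:
    """Read the 10-column small-variant TSV (empty AF cell = not observed)."""
    out: list[SmallVariant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "chrom":  # header
                continue
            if len(parts) != len(_VARIANT_COLS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(_VARIANT_COLS)} columns, got {len(parts)}"
                )
            row = dict(zip(_VARIANT_COLS, parts))
            freqs = {}
            for src, col in zip(FREQ_SOURCES, ("kg1000_af", "esp6500_af", "cgbaseline_af")):
                if row[col] != "":
                    freqs[src] = float(row[col])
            out.append(
                SmallVariant(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    effect=row["effect"],
                    gene_symbols=[s for s in row["genes"].split(",") if s],
                    freqs=freqs,
                    zygosity=row["zygosity"] or "unknown",
                )
            )
    return out


def load_event_table(path: str | Path) -> list[IntervalEvent]:
    """Read the BED-like CNV/SV table: ``chrom start end kind value``.

    ``value`` is the copy number for CNVs, or ``baseline_count:sv_type``
    for SVs.
    """
    out: list[IntervalEvent] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns, got {len(parts)}")
            chrom, start, end, kind, value = parts
            if kind == "cnv":
                out.append(IntervalEvent(chrom, int(start), int(end), "cnv", copy_number=int(value)))
            elif kind == "sv":
                count, sv_type = value.split(":", 1)
                out.append(
                    IntervalEvent(chrom, int(start), int(end), "sv",
                                  sv_type=sv_type, baseline_count=int(count))
                )
            else:
                raise ValueError(f"{path}: line {lineno}: unknown event kind {kind!r}")
    return out


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the BED-like gene-model table: ``chrom start end symbol strand``."""
    out: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns, got {len(parts)}")
            chrom, start, end, symbol, strand = parts
            out.append(GeneModel(symbol=symbol, chrom=chrom, start=int(start), end=int(end), strand=strand))
    return out
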