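# Methods

## Model

A disease or process is represented as an undirected, unweighted,
simple graph whose nodes are genes and whose edges are protein–protein
interactions. The cell line's genomic state enters as a binary partition
of the nodes into *damaged* and *intact*. The suitability statistic is
the centrality ratio

μ = Σ_{v damaged} c(v) / Σ_v c(v),

with c shortest-path betweenness by default. μ is a ratio of sums, so it
is invariant to any positive rescaling of c (normalized and raw
centralities give the same μ), monotone under flipping intact → damaged,
and confined to [0, 1]. When the total centrality mass is zero (e.g.
betweenness on a graph with no interior vertices) μ is defined as 0 with
a warning. The null model holds the topology and the damaged count k
fixed and places the k damaged labels uniformly at random;
p_BC = P(μ_perm > μ_obs) with a *strict* inequality — the probability
that random damage placement would be more central than the observed
one. Because the statistic under permutation depends only on which nodes
are damaged, centralities are computed once per network and only label
sums change across permutations; this is exact, not an approximation.

### Assumptions

* Interaction confidence is used only to threshold edges (default
  ≥ 0.7 on the unit scale); paths are never weighted.
* Damage is binary. The metric deliberately does not interpret
  functional direction (gain vs. loss of function) or zygosity.
* Identifiers are assumed pre-harmonized; no protein→gene mapping layer.

## Network construction

Disease networks: seed genes are intersected with the background
(seeds that do not map are reported, never silently dropped), expanded
by their neighbours at distance one, and the *full induced subgraph* on
that node set is returned — edges among expanded nodes are retained.
The expansion radius defaults to 1 (background PPI networks have high
average degree, so one hop already produces dense neighbourhoods) but is
exposed as a parameter. Module networks are induced subgraphs on an
explicit member list with no expansion.

## Damage rules

A gene is damaged iff at least one rule fires (all fired rules are kept
as provenance):

* **rare_small_variant** — a variant with effect in {nonsynonymous,
  splice_site, stopgain, stoploss, frameshift_indel,
  nonframeshift_indel, block_substitution} whose allele frequency is
  strictly below 0.05 in *every* population panel in which it was
  observed (1000 Genomes, ESP6500, CG 69 baseline). A variant observed
  in no panel (private) is rare. Stop gain/loss are included as a
  superset of "non-synonymous". The 0.05 threshold is configurable.
* **cnv** — ≥ 1 bp overlap between the gene span and a segment called at
  copy number ≠ 2. Gains and losses both count; no frequency filter is
  applied to CNVs (only SVs carry a baseline-rarity criterion). The
  diploid baseline is configurable for aneuploid contexts.
* **rare_sv** — ≥ 1 bp overlap with a structural variant with
  `baseline_count == 0`, i.e. never observed in the baseline genome set.

All intervals are 0-based half-open (BED convention); 1-based variant
positions are converted on read. Effect classes are taken from the
upstream annotation as given; no re-annotation is attempted. Network
genes missing from the gene-model table are intact-with-warning by
default (`missing="strict"` raises instead).

## Centralities and centralization

Shortest-path betweenness (Brandes), degree, and reachable-only
closeness (k reachable nodes / sum of distances to them; isolated nodes
score 0) are computed on the whole, possibly disconnected graph;
disconnected pairs contribute nothing to betweenness. Current-flow
(random-walk) betweenness uses the Laplacian formulation with endpoints
excluded and is computed independently within each connected component
(solver tolerance 1e-10, deterministic node ordering); singleton
components score 0. On trees it coincides exactly with shortest-path
betweenness (the unique path carries all current) — a property the test
suite exploits as an oracle. When betweenness is normalized the divisor
is (n−1)(n−2)/2 with n the *component* size.

Network centralization summarizes how concentrated a centrality vector
is. The default is the relative Freeman form
Σ_v (c_max − c_v) / ((n−1)·c_max): 1.0 for a star under betweenness,
0.0 for any vertex-transitive graph, bounded in [0, 1] for any
non-negative vector, and invariant to rescaling of the scores. The
classical convention-normalized form Σ_v (c_max − c_v) / (n−1) on
normalized scores is available via `mode="freeman"`; the two agree
whenever the maximum normalized score is 1 (e.g. a star). The choice was
genuinely open — published tables using this statistic do not pin down
the normalization constant — so the scale-invariant form was preferred
because it satisfies all the properties the package guarantees, and the
alternative is kept a flag away. Centralization requires n ≥ 3.

## Scoring scope and outputs

Shortest-path-based ratios are computed on the whole graph. The
flow-betweenness ratio of a disconnected network is computed on the
largest connected component only (flow betweenness is undefined across
components) and the summary row flags it with `*`. The permutation
count defaults to 1000; a zero exceedance count is reported both as the
numeric 0 and as the string `<1/n`, and a conservative
(count+1)/(n+1) variant is always included. The strict-inequality count
without the +1 floor is the primary value because the test is a plain
Monte-Carlo tail probability of the fixed-topology label null; both
numbers are in every `SuitabilityScore`. Degenerate labelings (no
damaged or no intact nodes) make the test uninformative and report
p = 1.0 with a warning. Seed-only scoring re-labels seed-origin nodes as
damaged and everything else intact, then runs the identical test.
Cross-metric correlation is Pearson by default (Spearman by flag),
computed per network over per-node values and averaged across networks
with equal weight; constant vectors make a pair undefined and are
excluded from the average with a warning. Gene rankings break ties
lexicographically by symbol for determinism. One seeded NumPy generator
drives each run; the seed is recorded in every score object and output
header, and identical seed + inputs reproduce results bitwise.

## Synthetic data

The fixture module generates (a) parametric graphs — star, path, cycle,
random tree, Erdős–Rényi, Barabási–Albert — with unit edge confidence;
(b) labelings placing k damaged nodes uniformly, on the top-betweenness
nodes (central damage, the high-μ regime) or on the periphery (low-μ);
and (c) variant/CNV/SV/gene-model tables with planted truth: damaged
genes receive evidence for exactly the assigned rule, intact genes
receive only non-qualifying decoys (synonymous rare variants, common
protein-altering variants, diploid segments, baseline-observed SVs).
Gene models are non-overlapping 1 kb spans with 1 kb gaps on one
synthetic chromosome so overlap outcomes are unambiguous; "rare"
frequencies are drawn in [0, 0.05) or omitted (private), "common" in
[0.05, 0.5], straddling the 5% rule.

What the generator does *not* emulate: realistic allele-frequency
spectra, linkage between variants, overlapping isoforms, multi-gene
CNV segments spanning many genes, or the degree distribution of a real
interaction database beyond the Barabási–Albert option. Passing tests
therefore demonstrate correctness of the rules and statistics, not
biological realism of any particular score.

## Problem sizes and numerical choices

The verification suite runs on small graphs by design: the betweenness
oracle check covers every isomorphism class of connected graphs on up to
7 nodes (the graph atlas) plus 30 seeded random graphs up to 12 nodes —
enumeration of all shortest paths is only tractable there, and the
algorithms under test are size-independent. Monte-Carlo/exact agreement
uses 50,000 permutations on ≤ 10-node fixtures (≤ 4 damaged labels keeps
exhaustive enumeration ≤ 210 placements); null calibration uses 200
replicates on a 12-node graph with 3 damaged labels (220-placement
grid). Strictly-greater comparisons in the permutation count use a
1e-15 guard against floating-point ties; current-flow values are clipped
at 0 to absorb solver round-off.

## Known limitations

* Exact betweenness only; no sampling approximation for very large
  networks (the intended networks are a few hundred nodes).
* p_BC is a tail probability on a discrete grid: on highly symmetric
  networks the statistic can be constant and p degenerates (reported as
  `<1/n` with a warning).
* No multiple-testing correction across networks is applied; scores for
  different diseases are reported side by side as-is.
* CNV damage has no rarity filter, so common copy-number polymorphisms
  count as damage if present in the input segments.
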