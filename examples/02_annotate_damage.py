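"""Label genes damaged or intact from small-variant, CNV and SV evidence.

Synthetic tables with a planted ground truth are generated, then passed
through the annotator.  A gene is damaged when it carries a rare
(<5% in every population panel) protein-altering small variant, overlaps
a non-diploid copy-number segment, or overlaps a structural variant never
seen in the baseline genome set.
"""

from collections import Counter

from netsuit import label_genes
from netsuit.synth import make_variant_tables

genes, variants, events, truth = make_variant_tables(
    n_genes=40, damaged_fraction=0.3, seed=7
)
labeling = label_genes(genes, variants, events)

print(f"{len(genes)} genes, {len(variants)} small variants, {len(events)} CNV/SV events")
print(f"damaged: {len(labeling.damaged())} (planted: {len(truth.damaged())})")
rules = Counter(r for prov in labeling.provenance.values() for r in prov)
print(f"rules fired: {dict(rules)}")
print(f"recovered the planted truth exactly: {labeling.labels == truth.labels}")

# Provenance records which rule(s) fired per damaged gene, so downstream
# reports can say whether damage came from point mutations or dosage changes.
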