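"""Classify called enhancers into genomic feature categories.

Builds the feature catalog (repeats with TE subclasses, TSS-proximal
windows, UTRs, introns, exons) from the simulated annotation, assigns each
planted enhancer one category by the repeat-first priority rule, computes
relative enrichment over genomic background, and bins nearest genes by
expression.
"""

from collections import Counter

from starrkit import SimConfig, expression_bin, feature_enrichment, nearest_gene
from starrkit.annotation import build_catalog, classify_all
from starrkit.simulate import simulate_expression, simulate_genome

config = SimConfig(seed=1)
genome = simulate_genome(config)
fpkm = simulate_expression(genome.genes, config.seed)

catalog = build_catalog(genome.genes, genome.repeats, assembly=genome.assembly)
enhancers = [t.interval for t in genome.truth]
assignments = classify_all(enhancers, catalog)

print("category distribution (single category per enhancer):")
for cat, n in Counter(c for c, _ in assignments).most_common():
    print(f"  {cat:12s} {n:3d} ({100 * n / len(enhancers):.1f}%)")

print("\nTE subclasses among repeat-resident enhancers:")
for sub, n in Counter(s for _, s in assignments if s).most_common():
    fc = feature_enrichment([s for _, s in assignments], sub,
                            catalog.te_subclasses[sub], genome.assembly)
    print(f"  {sub:6s} {n:3d}  relative enrichment FC={fc:.2f}")

print("\nnearest-gene expression bins (silent: FPKM=0; low: <=1; "
      "medium: <=10; high: >10):")
bins = Counter(
    expression_bin(fpkm[nearest_gene(e, genome.genes)[0]]).value for e in enhancers
)
for name in ("silent", "low", "medium", "high"):
    print(f"  {name:7s} {bins.get(name, 0)}")
print()
print("FC > 1 means the subclass hosts more enhancers than its genomic "
      "share predicts; the priority rule guarantees categories sum to the total.")
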