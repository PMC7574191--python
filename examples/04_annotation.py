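"""Annotating results: nearest gene, state overlap, composition, enrichment.

Runs a small synthetic search and walks its results through each
annotation: the gene whose TSS is closest to the root region, overlap
counts against a labelled segmentation track, counts per matched-track
combination, and a hypergeometric over-representation test of the nearest
genes against a gene→term table.
"""

from patternscan import (
    PlantSpec, Region, Track, annotate_nearest_genes,
    annotation_overlap_summary, benchmark_pattern, functional_annotation_stub,
    generate_instance, search_pattern, subpattern_composition,
)
from patternscan.core import SearchParams

pattern = benchmark_pattern(min_score=0.5)
spec = PlantSpec(pattern=pattern, n_occurrences=20, jitter=300,
                 background_density=20.0, seed=7)
tracks, truth = generate_instance(spec)
results = search_pattern(pattern, tracks, SearchParams(min_score=0.5))
print(f"{len(results)} matchings found\n")

# nearest gene: decoy TSS track with genes every ~500 kb
tss = Track("TSS")
for i, pos in enumerate(range(100_000, 10_000_000, 500_000)):
    tss.add(Region("chrS", pos, pos + 1, name=f"gene{i:02d}"))
tss.sort()
annotate_nearest_genes(results, tss)
m = results[0]
print(f"top matching chrS:{m.span[0]}-{m.span[1]} -> nearest gene "
      f"{m.nearest_gene} ({m.gene_distance:,} bp from the root region)")

# overlap against a labelled segmentation (everything 'Enh' here)
ann = Track("states")
ann.add(Region("chrS", 0, 10_000_000, name="Enh"))
summary = annotation_overlap_summary(results, ann)
print(f"state overlap: {summary.label_counts} over "
      f"{summary.matching_count} matchings")

# which co-factor combinations co-occur?
comp = subpattern_composition(results)
print("matched-track combinations (count desc):")
for combo, n in comp.ranked():
    print(f"  {n:3d}  {','.join(combo)}")

# over-representation of the nearest genes in a toy gene->term table
genes = [m.nearest_gene for m in results if m.nearest_gene]
gene_terms = {f"gene{i:02d}": (["regulation"] if i < 10 else ["other"])
              for i in range(20)}
df = functional_annotation_stub(genes, gene_terms)
print("\nenrichment (hypergeometric + BH):")
print(df.to_string(index=False))
print("\nk of n result genes carry the term, K of N universe genes do; a")
print("small p means the result genes carry the term more than chance.")
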