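"""Biotype-prioritized read counting on a toy annotation.

Small-RNA annotations overlap (a miRNA inside a lncRNA intron, a tRF in a
pseudogene).  Each read is assigned to exactly one feature by biotype
priority (miRNA > tRNA > rRNA > mRNA > pseudogene > snRNA > snoRNA >
piRNA > lncRNA > miscRNA), then largest overlap, then smallest id.
"""

from evbiomark import (
    AlignmentRecord,
    FeatureAnnotation,
    SimulationConfig,
    assign_read,
    build_toy_annotation,
    count_matrix_from_alignments,
    simulate_alignments,
)

# a read inside a miRNA/lncRNA overlap goes to the miRNA
mir = FeatureAnnotation("mir-x", "miRNA", "chr1", 100, 122, "+")
lnc = FeatureAnnotation("lnc-host", "lncRNA", "chr1", 0, 2000, "+")
read = AlignmentRecord("r1", "chr1", 103, 121, "+")
print(f"read in miRNA/lncRNA overlap -> assigned to {assign_read(read, [lnc, mir])}")

# full counting run against the generator's per-read truth
config = SimulationConfig(seed=0, n_features_per_biotype=10, n_reads_per_sample=2000)
annotation = build_toy_annotation(config)
alignments, truth_counts = simulate_alignments(config, annotation)
cm, unassigned = count_matrix_from_alignments(alignments, annotation)

print(f"\n{len(annotation)} features, {sum(len(v) for v in alignments.values())} reads")
print("counts equal the generator's truth assignment:", cm.counts.equals(truth_counts))
for s in cm.sample_ids:
    total = len(alignments[s])
    print(f"  {s}: {total - unassigned[s]} assigned + {unassigned[s]} unassigned = {total} reads")
# Exact agreement with the truth labels shows the interval-indexed counter
# implements the same priority rule as the brute-force resolver.
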