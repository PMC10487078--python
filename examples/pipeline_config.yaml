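# Example pipeline configuration for `evbiomark run --config`.
# Configure exactly one input route: counts, alignments, or simulate.

outdir: evbiomark_out

# Route 1: precomputed counts (feature x sample TSV with a biotype column)
# counts: counts.tsv
# sample_sheet: samples.tsv

# Route 2: alignments + annotations (quantify stage runs first)
# annotation: [annotation.gtf, pirna_catalog.bed]
# alignments: {sampleA: sampleA.sam, sampleB: sampleB.sam}
# sample_sheet: samples.tsv

# Route 3: synthetic cohort from the generator (ground truth written too)
simulate: true
sim_overrides: {}

# Analysis parameters (defaults shown)
alpha: 0.05            # adjusted-p threshold for significance calls
min_abs_lfc: 1.0       # |log2FC| must strictly exceed this
prior_df: 10.0         # dispersion / quasi-dispersion shrinkage prior df
prior_count: 2.0       # prior count for log2FC on normalized means
detection_threshold: 1 # raw reads needed to call a marker "detected"
paired: true           # subject blocking for the PreOp-vs-PostOp contrast
bh_per_biotype: true   # BH within each biotype's test family
her2_rule: "3"         # HER2-positive = IHC 3 ("2+3" to include IHC 2)
criterion: aic         # backward-elimination criterion (aic | wald)
clinical_variables: [ER, HER2_IHC]
seed: 0
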