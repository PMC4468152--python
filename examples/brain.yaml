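# Default classification thresholds for a frontal-cortex analysis.
# Pass to `tissuespec classify --config examples/brain.yaml`; CLI flags
# override file values.
target_tissue: frontal cortex
detection_threshold: 1.0       # FPKM; ~1 transcript per average cell
high_expression_threshold: 10.0
enrichment_fold: 5.0
high_enrichment_fold: 50.0
group_size_min: 2
group_size_max: 7
enhanced_denominator: all_tissues
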