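# Default simulation + analysis configuration for `ripersist run-all`.
# Every value shown here is also the built-in default.

seed: 42

# simulation
n_genes: 4
isoforms_per_gene: 2
introns_per_transcript: [2, 4]
exon_length: [80, 200]
intron_length: [100, 400]
rho_values: [0.0, 0.25, 0.5]
pre_mrna_fraction: 0.0
partial_fraction: 0.0
reads_per_transcript: 20
coverage_depth: 5.0
coverage_decay: 0.0

# persistence
min_reads: 5
persistent_threshold: 0.1
mean_denominator: assigned
end_tolerance: 50

# benchmarking
thresholds: "0.1:0.9:0.1"
min_tools: 3
window_width: 300
window_step: 100
window_max: 4300
profile_bins: 1000
profile: default
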