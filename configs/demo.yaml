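# Bundled demo configuration: pure simulation, runs end to end in seconds.
# Analysis parameters default to the published constants (150 bp overlap
# window, 1 kb hotspot window, +/-500 kb domains, fold 3 / TPM 5 / alpha 0.05).
seed: 0
out_dir: demo_run
n_chroms: 2
chrom_len: 400000
n_genes: 60
n_anchors: 40
n_specific: 40
jitter_sd: 50.0
accessible_fraction: 0.15
n_matched_sets: 5
n_random_gene_lists: 20
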