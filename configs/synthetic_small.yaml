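# Small synthetic dataset for end-to-end runs and examples.
seed: 11
genome:
  - [chr1, 800000]
  - [chr2, 600000]
n_promoters: 40
total_tags_per_sample: 20000
n_genes: 40
n_tra: 12
n_housekeeping: 12
n_tissues: 16
noise_tags_per_kb: 0.02
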