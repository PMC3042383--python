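# Example pipeline configuration.
seed: 11
replicates: 2
outdir: example_output/pipeline

genomes:
  n_genomes: 4
  genome_length: 60000
  gene_length: [900, 360, 2400]       # bp: mean, min, max
  intergenic_length: [400, 160, 1200]
  gc: 0.5
  codon_bias_strength: 0.6

benchmark:
  read_lengths: [100, 300]
  n_per_type: 150

predictors:
  - {name: m1, kind: mock, sens: 0.8, spec: 0.8, coord_noise_sd: 4}
  - {name: m2, kind: mock, sens: 0.8, spec: 0.8, coord_noise_sd: 4}
  - {name: m3, kind: mock, sens: 0.8, spec: 0.8, coord_noise_sd: 4}
  - {name: logodds, kind: baseline, score_threshold: 0.1, min_orf_len: 60}
  # ingest an external predictor's converted output with:
  # - {name: genemark, kind: file, path: genemark.tsv, format: tsv}

combinations:
  - {op: CONSENSUS, members: [m1, m2, m3]}
  - {op: AND, members: [m1, m2]}
  - {op: OR, members: [m1, m2, m3]}

report:
  per_type: true
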