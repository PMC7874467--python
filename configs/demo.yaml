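# Demo experiment for `l1ripseq run-all --config configs/demo.yaml --out out/`.
# Simulation parameters omitted here fall back to the package defaults
# (60 LINE-1 loci at 2% divergence, rRNA-dominated libraries, LINE-1 at
# ~0.05% of input reads, log-normal gene pulldown enrichments with median
# ~10x and histone-like genes fixed at 1x).
simulate:
  seed: 7
  n_reads_input: 200000
  n_reads_ip: 200000
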