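{
  "outdir": "results/demo",
  "seed": 42,
  "simulate": {
    "n_genes": 12,
    "seed": 42,
    "n_replicates": 2,
    "reads_per_gene": 30,
    "substitution_error_rate": 0.005,
    "frac_csro": 0.25,
    "frac_alt3tss": 0.25,
    "frac_null": 0.25
  }
}
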