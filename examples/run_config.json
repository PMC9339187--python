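{
  "seed": 42,
  "simulate": {
    "n_proteins": 400,
    "noise_sd_log2": 0.1
  },
  "dep_calling": {
    "correction": "none",
    "alpha": 0.05
  },
  "enrichment": {
    "n_terms": 30,
    "enriched_terms": 5,
    "odds_ratio": 10.0
  }
}
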