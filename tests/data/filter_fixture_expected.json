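{
  "n_variants": 50,
  "removed_abundance_lt5": 12,
  "kept_abundance_ge5": 38,
  "removed_abundance_lt25": 35,
  "removed_short_at_ab25": 3,
  "kept_ab25_len280": 12,
  "removed_short_at_ab5": 4
}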