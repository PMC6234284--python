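{
  "out_dir": "scratch/smoke_run",
  "seed": 7,
  "simulate": {
    "n_taxa": 50,
    "n_transitions": 2,
    "transition_divergences": [0.02, 0.15],
    "n_marine_samples": 6,
    "n_freshwater_samples": 6,
    "library_size_range": [2000, 4000]
  },
  "rarefaction_depth": 1500,
  "n_nulls": 100,
  "n_permutations": 199,
  "n_orderings": 25,
  "min_sequences": 50,
  "weighted": true
}
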