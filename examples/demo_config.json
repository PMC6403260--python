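{
  "out_dir": "runs/demo",
  "simulate": true,
  "experiments": ["1", "3"],
  "n_subjects": 6,
  "seed": 0,
  "trials_csv": {},
  "fit_thresholds": true,
  "stats": true,
  "n_perm": 1000,
  "n_boot": 0,
  "fit_model": true,
  "variant_full": "predictive",
  "compare": true,
  "n_starts": 4,
  "quad_n_grid": 96,
  "quad_trunc_sd": 8.0
}
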