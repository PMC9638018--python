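# Bundled synthetic fixture configuration for the end-to-end pipeline test.
seed: 11
stages: [simulate, mid_correct, flux, signature, cytokine]
simulate:
  tracer_samples: 3
  tracer:
    noise_cv: 0.01
  flux_wells: 2
  flux:
    noise_sd: 1.5
  counts:
    n_genes: 100
  elisa:
    noise_sd: 0.01
pseudocount: 1.0
reference_count: 200000
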