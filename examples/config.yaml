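# Full default configuration for the serscyto pipeline.
# Every value below is the shipped default; edit and pass with --config.
seed: 0
axis:
  start: 250.0        # cm^-1
  stop: 3000.0        # cm^-1
  step: 7.0           # cm^-1 (acquisition resolution)
preprocess:
  enabled: true
  n_segments: 4       # equal-width baseline segments
  degree: 3           # polynomial degree per segment
  n_iterations: 50    # peeling iterations per segment
  boxcar_window: 5    # points (35 cm^-1); must be odd
  floor_at_zero: true # clip negative corrected intensities
references:
  source: simulate    # or a path to a five-column reference spectrum table
panel:
  designs:            # mixing ratios in reporter order DTDC,SiNC,BHQ3,QXL680,QSY21
    - [1, 1, 1, 1, 1]
    - [1, 1, 1, 6, 1] # QXL680-dominant 1:6:1:1:1 validation mix
    - [6, 1, 1, 1, 1]
    - [1, 6, 1, 1, 1]
    - [1, 1, 6, 1, 1]
    - [1, 1, 1, 1, 6]
    - [2, 1, 4, 1, 2]
    - [5, 3, 1, 0, 1]
  noise_sd: 0.015     # additive Gaussian SD, fraction of library peak
population:
  n_per_line: 300
  sd: 0.06            # per-marker SD of the weight factors
  bounds: [0.0, 0.79] # truncation range of the weight factors
  noise_sd: 0.015
  baseline_amp: 0.02  # smooth random baseline, fraction of library peak
  means: null         # null -> built-in per-line marker means
unmix:
  mode: nnls          # or ols
classifier:
  train_fraction: 0.7
  n_iterations: 200
  n_trees: 100
  max_depth: null     # unlimited
mixed_population:
  n_per_line: 150     # 450-cell mixed prediction set
embedding:
  enabled: true
  perplexities: [5, 10, 20, 30, 45, 60, 90, 120, 150, 200, 250, 300]
  n_replicates: 5
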