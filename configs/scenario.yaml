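# 50% edge contraction on a moderately structured landscape, with the
# default 2,200- and 13,800-generation reporting horizons.
landscape:
  rows: 10
  cols: 10
params:
  theta: 1.0e-4
  deme_size: 1000
  target_fst: 0.3
scenario:
  scenario: edge_contraction
  loss_fraction: 0.5
horizons:
  medium: 2200
  long: 13800
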