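# Equilibrium solve: 10x10 landscape, theta = 1e-4, migration tuned to
# a target mean pairwise F_ST.
landscape:
  rows: 10
  cols: 10
params:
  theta: 1.0e-4
  deme_size: 1000
  target_fst: 0.3
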