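# Reduced-diameter maze (same topology as the full 560 um case).
case: maze
geometry:
  diameter: 160
  spacing: 5
schedule:
  n_substeps_nominal: 500
  output_every: 25
output_dir: out/maze
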