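# Directional growth: central colony, nutrient patch in one corner.
case: cube_directional
schedule:
  n_substeps_nominal: 1000
  output_every: 25
output_dir: out/cube
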