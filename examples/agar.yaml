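# Biofilm on a nutrient plate: c = 1 on the whole bottom face.
case: agar
schedule:
  n_substeps_nominal: 1000
  output_every: 10
output_dir: out/agar
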