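# Baseline: synaptic variant on the 6 x 6 mm sheet with the central
# 0.3 mm excitation disk; all parameters at their table defaults.
model:
  variant: 2
run:
  total_time: 300.0
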