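# Narrow computational domain for front-speed scans: a 6 x 0.6 mm strip
# (same dx and disk size as the standard sheet) with the excitation disk
# at one end; speed is measured along the long axis.
model:
  variant: 2
domain:
  width: 6.0
  height: 0.6
  nx: 80
  ny: 8
  excitation_center: [0.3, 0.3]
  probes:
    - [S1, 0.3, 0.3]
    - [S2, 2.3, 0.3]
run:
  total_time: 250.0
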