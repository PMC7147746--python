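# A straight 3 mm connectivity cut (phi = 0 on the segment) to the right
# of the excitation disk.  The discharge cannot cross the cut and travels
# around it; potassium still diffuses through in the combined variant.
model:
  variant: 2
lesion:
  kind: partial_segment
  start: [4.0, 1.5]
  end: [4.0, 4.5]
run:
  total_time: 300.0
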