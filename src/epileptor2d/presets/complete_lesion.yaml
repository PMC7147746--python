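# Full-width connectivity cut with conditions tuned to potassium-mediated
# crossing: fast potassium clearance (tau_K = 10 s), strong potassium
# sensitivity (gK_leak/gL = 3), reduced peripheral bath (4 mM against 7 mM
# in the excitation zone), spatially independent noise, and the free-
# electrolyte diffusion coefficient (2e-5 cm^2/s).  Probes sit in the
# excitation centre (S1), the near periphery (S2) and behind the cut (S3).
# Noise amplitude: in this configuration the excitation centre fires
# tonically (its potassium stall sits far above threshold), so discharge
# generation needs no noise; the peripheral quiescent margin is only
# ~7 mV, so the standard 25 mV amplitude would ignite the periphery by
# itself and mask the diffusion contrast.  5 mV keeps the periphery
# metastable while leaving the recruitment dynamics intact.
model:
  variant: 3
parameters:
  tau_K: 10.0
  "g_K,leak/g_L": 3.0
  D_K: 2.0e-5
  "sigma/g_L": 5.0
noise:
  mode: inhomogeneous
domain:
  Kbath_center: 7.0
  Kbath_periphery: 4.0
  probes:
    - [S1, 3.0, 3.0]
    - [S2, 1.0, 3.0]
    - [S3, 5.0, 3.0]
lesion:
  kind: complete_line
  axis: x
  position: 4.0
  blocks_diffusion: false
run:
  total_time: 150.0
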