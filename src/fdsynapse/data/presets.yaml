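# Fitted FD-map constants. Times in ms, rates in 1/ms; calcium rescaled by
# the control per-spike influx. Muscarine differs only in p_max and delta.
control:
  K: 0.2
  k_min: 0.0017
  k_max: 0.0517
  K_r: 0.1
  tau_ca: 1.5
  p_max: 0.85
  delta: 1.0
muscarine:
  K: 0.2
  k_min: 0.0017
  k_max: 0.0517
  K_r: 0.1
  tau_ca: 1.5
  p_max: 0.27
  delta: 0.17
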