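{
  "name": "young_rat_visual_cortex",
  "description": "Unified STDP rule constants fitted to frequency- and timing-dependent plasticity of layer-5 pyramidal cell pairs in young rat visual cortex.",
  "d_minus": 0.00389,
  "tau_y_minus_ms": 12.5,
  "d_plus": 0.002483,
  "tau_y_plus_ms": 417.8,
  "c_plus": 0.013706,
  "tau_x_plus_ms": 48.6,
  "alpha": 0.075,
  "stp": {"D_ms": 200.0, "F_ms": 50.0}
}
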