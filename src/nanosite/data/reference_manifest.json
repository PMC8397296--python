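{
  "parameters": {
    "zn_zn_cutoff": 0.5,
    "o_zn_cutoff": 0.25,
    "zn_water_cutoff": 0.2,
    "water_o3_cutoff": 0.25,
    "dt_ps": 5.0,
    "quantiles": [5, 25, 50, 75, 95]
  }
}
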