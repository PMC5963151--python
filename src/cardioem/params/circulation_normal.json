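{
  "r_mi": 0.005,
  "r_ao": 0.008,
  "r_sa": 1.7,
  "r_sv": 0.08,
  "r_tr": 0.008363,
  "r_pu": 0.007587,
  "r_pa": 0.006718,
  "r_pv": 0.012423,
  "c_la": 3.154005,
  "c_sa": 2.2,
  "c_sv": 21.745868,
  "c_ra": 12.0,
  "c_pa": 2.0,
  "c_pv": 3.557978,
  "total_volume_ml": 615.04622,
  "lvad_flow_lpm": 0.0,
  "lv": {
    "e_es": 2.845272,
    "v0": 10.0,
    "edp_a": 0.010155,
    "edp_b": 0.054855,
    "t_act_ref": 114.16621,
    "act_exponent": 2.0
  },
  "rv": {
    "e_es": 0.168736,
    "v0": 20.0,
    "edp_a": 0.034575,
    "edp_b": 0.039102,
    "t_act_ref": 66.425478,
    "act_exponent": 2.0
  }
}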