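{
 "heart_rate_bpm": 69.0,
 "dt_s": 0.001,
 "compartments": [
  {
   "name": "PV",
   "elastance_mmhg_per_l": 125.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.3,
   "volume_l": 0.364
  },
  {
   "name": "LA",
   "elastance_mmhg_per_l": null,
   "elastance_profile": {
    "ees_mmhg_per_l": 300.0,
    "ed_mmhg_per_l": 150.0,
    "rise_frac": 0.11,
    "decay_frac": 0.18,
    "m1": 1.9,
    "m2": 13.0,
    "offset_frac": 0.75
   },
   "unstressed_volume_l": 0.03,
   "volume_l": 0.073333
  },
  {
   "name": "LV",
   "elastance_mmhg_per_l": null,
   "elastance_profile": {
    "ees_mmhg_per_l": 3000.0,
    "ed_mmhg_per_l": 60.0,
    "rise_frac": 0.269,
    "decay_frac": 0.452,
    "m1": 1.32,
    "m2": 21.9,
    "offset_frac": 0.0
   },
   "unstressed_volume_l": 0.04,
   "volume_l": 0.173333
  },
  {
   "name": "AA",
   "elastance_mmhg_per_l": 1667.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.05,
   "volume_l": 0.09949
  },
  {
   "name": "AD",
   "elastance_mmhg_per_l": 1000.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.12,
   "volume_l": 0.2022
  },
  {
   "name": "UB",
   "elastance_mmhg_per_l": 50.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.4,
   "volume_l": 1.2
  },
  {
   "name": "LB",
   "elastance_mmhg_per_l": 50.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.4,
   "volume_l": 1.2
  },
  {
   "name": "AR",
   "elastance_mmhg_per_l": 10000.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.015,
   "volume_l": 0.0228
  },
  {
   "name": "GL",
   "elastance_mmhg_per_l": 20000.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.01,
   "volume_l": 0.01268
  },
  {
   "name": "TU",
   "elastance_mmhg_per_l": 20000.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.01,
   "volume_l": 0.0107
  },
  {
   "name": "VR",
   "elastance_mmhg_per_l": 5000.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.05,
   "volume_l": 0.0514
  },
  {
   "name": "UA",
   "elastance_mmhg_per_l": 20000.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.01,
   "volume_l": 0.0135
  },
  {
   "name": "SA",
   "elastance_mmhg_per_l": 20000.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.01,
   "volume_l": 0.012
  },
  {
   "name": "PL",
   "elastance_mmhg_per_l": 3333.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.15,
   "volume_l": 0.1545
  },
  {
   "name": "UV",
   "elastance_mmhg_per_l": 5000.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.05,
   "volume_l": 0.0512
  },
  {
   "name": "VC",
   "elastance_mmhg_per_l": 8.0,
   "elastance_profile": null,
   "unstressed_volume_l": 1.8,
   "volume_l": 2.275
  },
  {
   "name": "RA",
   "elastance_mmhg_per_l": null,
   "elastance_profile": {
    "ees_mmhg_per_l": 150.0,
    "ed_mmhg_per_l": 80.0,
    "rise_frac": 0.11,
    "decay_frac": 0.18,
    "m1": 1.9,
    "m2": 13.0,
    "offset_frac": 0.75
   },
   "unstressed_volume_l": 0.03,
   "volume_l": 0.07
  },
  {
   "name": "RV",
   "elastance_mmhg_per_l": null,
   "elastance_profile": {
    "ees_mmhg_per_l": 600.0,
    "ed_mmhg_per_l": 35.0,
    "rise_frac": 0.269,
    "decay_frac": 0.452,
    "m1": 1.32,
    "m2": 21.9,
    "offset_frac": 0.0
   },
   "unstressed_volume_l": 0.04,
   "volume_l": 0.154286
  },
  {
   "name": "PA",
   "elastance_mmhg_per_l": 250.0,
   "elastance_profile": null,
   "unstressed_volume_l": 0.08,
   "volume_l": 0.14
  }
 ],
 "connectors": [
  {
   "name": "PV_LA",
   "source": "PV",
   "target": "LA",
   "resistance_mmhg_s_per_l": 15.5172,
   "valve": false
  },
  {
   "name": "LA_LV",
   "source": "LA",
   "target": "LV",
   "resistance_mmhg_s_per_l": 12.0,
   "valve": true
  },
  {
   "name": "LV_AA",
   "source": "LV",
   "target": "AA",
   "resistance_mmhg_s_per_l": 12.0,
   "valve": true
  },
  {
   "name": "AA_AD",
   "source": "AA",
   "target": "AD",
   "resistance_mmhg_s_per_l": 5.0,
   "valve": false
  },
  {
   "name": "AA_UB",
   "source": "AA",
   "target": "UB",
   "resistance_mmhg_s_per_l": 1159.0909,
   "valve": false
  },
  {
   "name": "AD_LB",
   "source": "AD",
   "target": "LB",
   "resistance_mmhg_s_per_l": 1012.8,
   "valve": false
  },
  {
   "name": "AD_AR",
   "source": "AD",
   "target": "AR",
   "resistance_mmhg_s_per_l": 252.0,
   "valve": false
  },
  {
   "name": "AR_GL",
   "source": "AR",
   "target": "GL",
   "resistance_mmhg_s_per_l": 1460.9246,
   "valve": false
  },
  {
   "name": "GL_VR",
   "source": "GL",
   "target": "VR",
   "resistance_mmhg_s_per_l": 3289.1603,
   "valve": false
  },
  {
   "name": "GL_TU",
   "source": "GL",
   "target": "TU",
   "resistance_mmhg_s_per_l": 15966.9493,
   "valve": false
  },
  {
   "name": "TU_VR",
   "source": "TU",
   "target": "VR",
   "resistance_mmhg_s_per_l": 2818.7919,
   "valve": false
  },
  {
   "name": "VR_VC",
   "source": "VR",
   "target": "VC",
   "resistance_mmhg_s_per_l": 192.0,
   "valve": false
  },
  {
   "name": "AD_UA",
   "source": "AD",
   "target": "UA",
   "resistance_mmhg_s_per_l": 7320.0,
   "valve": false
  },
  {
   "name": "UA_SA",
   "source": "UA",
   "target": "SA",
   "resistance_mmhg_s_per_l": 18000.0,
   "valve": false
  },
  {
   "name": "SA_PL",
   "source": "SA",
   "target": "PL",
   "resistance_mmhg_s_per_l": 15000.0,
   "valve": false
  },
  {
   "name": "PL_UV",
   "source": "PL",
   "target": "UV",
   "resistance_mmhg_s_per_l": 5400.0,
   "valve": false
  },
  {
   "name": "UV_VC",
   "source": "UV",
   "target": "VC",
   "resistance_mmhg_s_per_l": 1320.0,
   "valve": false
  },
  {
   "name": "UB_VC",
   "source": "UB",
   "target": "VC",
   "resistance_mmhg_s_per_l": 987.2727,
   "valve": false
  },
  {
   "name": "LB_VC",
   "source": "LB",
   "target": "VC",
   "resistance_mmhg_s_per_l": 868.8,
   "valve": false
  },
  {
   "name": "VC_RA",
   "source": "VC",
   "target": "RA",
   "resistance_mmhg_s_per_l": 6.0,
   "valve": false
  },
  {
   "name": "RA_RV",
   "source": "RA",
   "target": "RV",
   "resistance_mmhg_s_per_l": 10.0,
   "valve": true
  },
  {
   "name": "RV_PA",
   "source": "RV",
   "target": "PA",
   "resistance_mmhg_s_per_l": 10.0,
   "valve": true
  },
  {
   "name": "PA_PV",
   "source": "PA",
   "target": "PV",
   "resistance_mmhg_s_per_l": 72.4138,
   "valve": false
  }
 ],
 "autoregulation": {
  "mode": "mr+tgf",
  "mr": {
   "p0_mmhg": 80.0,
   "p1_mmhg": 180.0,
   "q0_l_per_s": 0.018,
   "k": 0.5,
   "delta1_s": 0.3,
   "delta2_s": 1.2,
   "tau1_s": 4.0,
   "tau2_s": 5.3,
   "gain": 1.0,
   "tau_convention": "physiological",
   "resistance_floor_frac": 0.05
  },
  "tgf": {
   "op_gfr_ml_min": 149.0,
   "th_gfr_ml_min": 144.0,
   "sa_gfr_ml_min": 333.0,
   "delta3_s": 18.0,
   "tau3_s": 15.0,
   "tau4_s": 33.0,
   "gain_mmhg_s_per_l_per_l_min": 200.0
  }
 },
 "calibration": {
  "map_mmhg": 82.5,
  "co_l_min": 5.8,
  "co_range_l_min": [
   5.7,
   6.0
  ],
  "rbf_l_min": 1.0,
  "gfr_l_min": 0.149,
  "renal_pressures_mmhg": null
 }
}
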