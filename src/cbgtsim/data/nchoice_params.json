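{
 "celldefaults": {
  "C": 0.5,
  "Taum": 20.0,
  "V_rest": -70.0,
  "V_thresh": -50.0,
  "V_reset": -55.0,
  "refractory": 2.0,
  "E_ampa": 0.0,
  "E_gaba": -80.0,
  "Mg": 1.0
 },
 "popspecific": {
  "FSI": {
   "Taum": 10.0
  },
  "CxI": {
   "Taum": 10.0
  }
 },
 "receptordefaults": {
  "Tau_AMPA": 2.0,
  "Tau_GABA": 5.0,
  "Tau_NMDA": 100.0,
  "nmda_gamma": 0.062,
  "nmda_beta": 3.57
 },
 "basestim": {
  "Cx": {
   "FreqExt_AMPA": 5.489499999999995,
   "efficacy": 0.015,
   "n_connections": 40
  },
  "CxI": {
   "FreqExt_AMPA": 10.111999999999998,
   "efficacy": 0.015,
   "n_connections": 40
  },
  "dSPN": {
   "FreqExt_AMPA": 1.093499999999999,
   "efficacy": 0.015,
   "n_connections": 40
  },
  "iSPN": {
   "FreqExt_AMPA": 1.1029999999999989,
   "efficacy": 0.015,
   "n_connections": 40
  },
  "FSI": {
   "FreqExt_AMPA": 10.319999999999999,
   "efficacy": 0.015,
   "n_connections": 40
  },
  "GPeP": {
   "FreqExt_AMPA": 6.697000000000006,
   "efficacy": 0.015,
   "n_connections": 40
  },
  "GPeA": {
   "FreqExt_AMPA": 7.8699999999999966,
   "efficacy": 0.015,
   "n_connections": 40
  },
  "STN": {
   "FreqExt_AMPA": 7.674000000000002,
   "efficacy": 0.015,
   "n_connections": 40
  },
  "GPi": {
   "FreqExt_AMPA": 7.526083333333326,
   "efficacy": 0.015,
   "n_connections": 40
  },
  "Th": {
   "FreqExt_AMPA": 8.884199999999995,
   "efficacy": 0.015,
   "n_connections": 40
  }
 },
 "dpmndefaults": {
  "dpmn_tauDOP": 5.0,
  "dpmn_baseline": 0.0
 },
 "dSPNdefaults": {
  "dpmn_alphaw": 39.5,
  "dpmn_wmax": 0.08
 },
 "iSPNdefaults": {
  "dpmn_alphaw": -38.2,
  "dpmn_wmax": 0.06
 },
 "popsizes": {
  "Cx": 40,
  "CxI": 20,
  "dSPN": 20,
  "iSPN": 20,
  "FSI": 10,
  "GPeP": 20,
  "GPeA": 10,
  "STN": 20,
  "GPi": 24,
  "Th": 60
 },
 "stim_scale": 100.0,
 "pathways": [
  [
   "Cx",
   "CxI",
   "AMPA",
   "common",
   0.5,
   0.006,
   false
  ],
  [
   "CxI",
   "Cx",
   "GABA",
   "common",
   0.5,
   0.006,
   false
  ],
  [
   "CxI",
   "CxI",
   "GABA",
   "common",
   0.5,
   0.002,
   false
  ],
  [
   "Cx",
   "dSPN",
   "AMPA",
   "syn",
   0.1,
   0.03,
   true
  ],
  [
   "Cx",
   "dSPN",
   "NMDA",
   "syn",
   0.25,
   0.005,
   true
  ],
  [
   "Cx",
   "iSPN",
   "AMPA",
   "syn",
   0.1,
   0.03,
   true
  ],
  [
   "Cx",
   "iSPN",
   "NMDA",
   "syn",
   0.25,
   0.005,
   true
  ],
  [
   "Cx",
   "FSI",
   "AMPA",
   "common",
   0.5,
   0.002,
   false
  ],
  [
   "Cx",
   "STN",
   "AMPA",
   "syn",
   0.5,
   0.002,
   false
  ],
  [
   "Cx",
   "Th",
   "AMPA",
   "syn",
   0.5,
   0.0005,
   false
  ],
  [
   "FSI",
   "dSPN",
   "GABA",
   "common",
   0.5,
   0.004,
   false
  ],
  [
   "FSI",
   "iSPN",
   "GABA",
   "common",
   0.5,
   0.004,
   false
  ],
  [
   "FSI",
   "FSI",
   "GABA",
   "common",
   0.3,
   0.002,
   false
  ],
  [
   "dSPN",
   "dSPN",
   "GABA",
   "syn",
   0.3,
   0.001,
   false
  ],
  [
   "iSPN",
   "iSPN",
   "GABA",
   "syn",
   0.3,
   0.001,
   false
  ],
  [
   "dSPN",
   "GPi",
   "GABA",
   "syn",
   0.5,
   0.01,
   false
  ],
  [
   "iSPN",
   "GPeP",
   "GABA",
   "syn",
   0.5,
   0.004,
   false
  ],
  [
   "GPeP",
   "STN",
   "GABA",
   "syn",
   0.5,
   0.004,
   false
  ],
  [
   "GPeP",
   "GPi",
   "GABA",
   "syn",
   0.5,
   0.003,
   false
  ],
  [
   "GPeP",
   "GPeA",
   "GABA",
   "syn",
   0.5,
   0.005,
   false
  ],
  [
   "STN",
   "GPeP",
   "AMPA",
   "syn",
   0.5,
   0.004,
   false
  ],
  [
   "STN",
   "GPi",
   "AMPA",
   "common",
   0.5,
   0.004,
   false
  ],
  [
   "STN",
   "GPi",
   "NMDA",
   "common",
   0.5,
   0.0008,
   false
  ],
  [
   "GPi",
   "Th",
   "GABA",
   "syn",
   0.5,
   0.012,
   false
  ],
  [
   "Th",
   "Cx",
   "AMPA",
   "syn",
   0.5,
   0.0005,
   false
  ],
  [
   "Th",
   "dSPN",
   "AMPA",
   "syn",
   0.5,
   0.0003,
   false
  ],
  [
   "Th",
   "iSPN",
   "AMPA",
   "syn",
   0.5,
   0.0003,
   false
  ]
 ]
}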