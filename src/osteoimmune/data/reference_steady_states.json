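{
  "description": "Cluster-wise steady-state abundances of cells (counts) and cytokines (expression units) for the three immune clusters of the TARGET osteosarcoma cohort, extracted as top-tail averages of the deconvolved compositions.",
  "1": {
    "M_N": 6.236e6, "M": 1.977e7, "T_N": 4.926e6, "T_h": 7.092e6,
    "T_r": 3.675e6, "T_c": 2.292e7, "D_N": 4.826e5, "D": 9.865e5,
    "C": 1.343e10, "N": 3.764e8,
    "I_g": 0.868, "mu1": 21.510, "mu2": 2.067, "H": 5.076
  },
  "2": {
    "M_N": 3.248e7, "M": 1.842e7, "T_N": 1.047e7, "T_h": 1.973e6,
    "T_r": 8.673e5, "T_c": 3.155e5, "D_N": 8.927e5, "D": 7.135e5,
    "C": 1.604e10, "N": 4.257e8,
    "I_g": 0.049, "mu1": 20.714, "mu2": 1.611, "H": 4.948
  },
  "3": {
    "M_N": 1.944e7, "M": 2.698e7, "T_N": 1.368e7, "T_h": 1.205e6,
    "T_r": 1.405e6, "T_c": 1.802e6, "D_N": 4.591e5, "D": 3.732e5,
    "C": 1.340e10, "N": 1.544e9,
    "I_g": 0.263, "mu1": 23.663, "mu2": 1.371, "H": 4.453
  }
}
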