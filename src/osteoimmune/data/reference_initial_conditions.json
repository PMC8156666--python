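{
  "description": "Dimensionless initial conditions (ratios to the cluster steady state) of the diagnosed-small-tumor patients chosen per cluster: the smallest tumor in cluster 1 and the closest-matching tumors in clusters 2 and 3.",
  "1": {
    "M_N": 2.367, "M": 1.005, "T_N": 0.019, "T_h": 0.794,
    "T_r": 0.764, "T_c": 0.828, "D_N": 1.122, "D": 0.0,
    "C": 0.020, "N": 0.160,
    "I_g": 2.394, "mu1": 1.104, "mu2": 1.806, "H": 1.059
  },
  "2": {
    "M_N": 0.954, "M": 0.753, "T_N": 1.299, "T_h": 1.451,
    "T_r": 2.313, "T_c": 0.062, "D_N": 0.071, "D": 0.693,
    "C": 0.005, "N": 0.018,
    "I_g": 0.859, "mu1": 1.307, "mu2": 3.259, "H": 0.988
  },
  "3": {
    "M_N": 0.866, "M": 1.104, "T_N": 0.572, "T_h": 0.340,
    "T_r": 0.484, "T_c": 0.0, "D_N": 1.643, "D": 0.0,
    "C": 0.014, "N": 0.0008,
    "I_g": 0.276, "mu1": 1.030, "mu2": 1.296, "H": 1.284
  }
}
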