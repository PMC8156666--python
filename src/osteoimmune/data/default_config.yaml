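# Default configuration: literature-scale fixed rates, the closure
# assumptions that make the steady-state parameter solve square, the
# deconvolution cell-type mapping, and tumor geometry.
#
# Every numeric choice here is a modeling default, overridable per run.
# Rates are per day.  The closure defaults were calibrated once so that
# the fitted three-cluster system reproduces the qualitative progression
# structure reported for the cohort (see docs/methods.md) and are not
# tuned per analysis.

fixed_rates:
  # cytokine decay: half-lives of order hours
  del_mu1:  {value: 8.0,    provenance: "TGF-beta/IL-10 serum half-life ~ 2 h"}
  del_mu2:  {value: 4.0,    provenance: "IL-6 half-life ~ 4 h"}
  del_Ig:   {value: 3.5,    provenance: "IFN-gamma half-life ~ 5 h"}
  del_H:    {value: 10.0,   provenance: "extracellular HMGB1 clearance ~ 2 h"}
  # mature-cell death: lifetimes of weeks to months (slow tissue turnover)
  del_M:    {value: 0.015,  provenance: "tissue macrophage lifespan ~ 2 months"}
  del_Th:   {value: 0.01,   provenance: "tumor-resident CD4 T cell turnover ~ 3 months"}
  del_Tr:   {value: 0.015,  provenance: "regulatory T cell turnover ~ 2 months"}
  del_Tc:   {value: 0.02,   provenance: "CD8/NK effector contraction ~ 7 weeks"}
  del_D:    {value: 0.02,   provenance: "mature dendritic cell lifespan ~ 7 weeks"}
  # naive-cell turnover
  del_MN:   {value: 0.2,    provenance: "monocyte/naive macrophage turnover ~ 5 d"}
  del_TN:   {value: 0.025,  provenance: "naive T cell turnover ~ 6 weeks"}
  del_DN:   {value: 0.02,   provenance: "immature dendritic cell turnover ~ 7 weeks"}
  # clearance of necrotic debris
  del_N:    {value: 0.05,   provenance: "necrotic debris clearance ~ 3 weeks"}
  # cancer cells
  del_C:    {value: 5.0e-4, provenance: "low spontaneous apoptosis of osteosarcoma"}
  lam_C:    {value: 0.02,   provenance: "human osteosarcoma volume doubling time ~ 35 d"}

closure:
  # Quoted steady-state ratio assumptions of the estimation procedure.
  cancer_self_vs_mu1: 40.0        # lam_C = 40 * lam_C_mu1 * mu1_inf
  ifng_kill_vs_apoptosis: 10.0    # del_C_Ig * Ig_inf = 10 * del_C
  # Remaining closure: package defaults in the same style (induced rate at
  # the steady state as a multiple of the natural rate).
  tc_kill_vs_apoptosis: 2.0       # del_C_Tc * Tc_inf = 2 * del_C
  mu2_vs_mu1_growth: 15.0         # lam_C_mu2 * mu2_inf = 15 * lam_C_mu1 * mu1_inf
  m1_m2_ratio: 0.25               # M1/M2 abundance ratio when no cohort is given
  m1_m2_ratio_by_cluster:         # cohort-level defaults (M2 dominates everywhere;
    1: 0.25                       #  cluster 2 most M2-skewed, cluster 3 least)
    2: 0.10
    3: 0.50
  inhibition_vs_natural:          # induced death flux / natural death flux at steady state
    Th_Tr: 1.2
    Th_mu1: 1.2
    Tc_Tr: 1.2
    Tc_mu1: 1.2
    D_C: 1.0
  production_shares:              # share of steady-state production per producer
    mu1: {T_h: 0.1, M: 0.5, C: 0.4}
    mu2: {T_h: 0.2, M: 0.7, C: 0.1}
    I_g: {T_h: 0.35, T_c: 0.65}
    H:   {M: 0.2, D: 0.1, N: 0.7}
  activation_shares:              # share of steady-state activation flux per activator
    T_h: {M: 0.5, D: 0.5}
    T_c: {T_h: 0.3334, M: 0.3333, D: 0.3333}
    D:   {C: 0.5, H: 0.5}

geometry:
  tumor_volume_ml: 275.0
  cell_diameter_um: 35.0

alpha_dim: 1.765e8   # immune-fraction -> cell-count scale; recalibratable

cell_type_mapping:
  M_N: ["Macrophages M0", "Monocytes"]
  M:   ["Macrophages M1", "Macrophages M2"]
  T_N: ["T cells CD4 naive"]
  T_h: ["T cells CD4 memory resting", "T cells CD4 memory activated",
        "T cells follicular helper"]
  T_r: ["T cells regulatory (Tregs)"]
  T_c: ["T cells CD8", "NK cells resting", "NK cells activated"]
  D_N: ["Dendritic cells resting"]
  D:   ["Dendritic cells activated"]

simulate:
  horizon_days: 5000.0
  max_horizon_days: 20000.0
  convergence_eps: 1.0e-3
  convergence_window_days: 200.0

sensitivity:
  neighborhood_rel_width: 0.1
  sparse_grid_level: 2
  weight_bandwidth_decades: 1.0
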