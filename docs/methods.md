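# Methods

## Model

The tumor microenvironment is described by 14 coupled ODEs in units of
days: ten cell populations (naive and activated macrophages, four T/NK
compartments plus naive T cells, naive and activated dendritic cells,
cancer, necrotic cells) and four cytokine groups (IFN-γ; μ₁ = TGF-β/
IL-4/IL-10/IL-13; μ₂ = IL-6/IL-17; HMGB1).  All interactions are mass
action; cancer growth is logistic with carrying capacity C₀; a fraction
α_NC of killed cancer cells becomes necrotic debris.  IL-12 and IL-23
equilibrate on a much faster timescale than cells and are eliminated by
a quasi-steady-state assumption — their levels are proportional to their
producers (M1 macrophages, dendritic cells), so their effect is folded
into the T-cell activation rate constants and they remain available only
as a diagnostic readout (`quasi_steady_cytokines`, proportionality
constants conventionally 1: they are unidentifiable from the data and
never enter the dynamics).

Assumptions inherited with the model family: no spatial structure or
chemotaxis, no explicit healthy-cell compartment (its competitive effect
is implicit in the cancer self-growth rate), no treatment terms, and
mature cells proportional to their naive sources via activation fluxes.

## From compositions to populations

Deconvolved fractions (22 canonical immune cell types) are aggregated
onto the 8 immune compartments with a config-overridable mapping; B
cells, plasma cells, γδ T cells, mast cells and granulocytes are outside
the model and their mass is reported as dropped.  Fractions become
counts through one scale factor α_dim (default 1.765×10⁸), chosen so the
cohort-average cancer count matches the geometric anchor: a 275 mL tumor
of 35 μm cells holds 275×10¹² μm³ / 35³ μm³ ≈ 6.4×10⁹ cells.  The anchor
uses cubic packing (volume / diameter³); this reproduces the canonical
count where sphere packing does not.  α_dim is a pure scale: it cancels
from all ratios and from the dimensionless dynamics.  Cancer and
necrotic counts follow from the clinical composition percentages,
C = I·pct_tumor/pct_normal and N = I·pct_necrotic/pct_normal, equating
the normal-cell percentage with the total immune percentage (a known
conflation: stromal non-immune normal cells are lumped in).

Cluster steady states are the componentwise means over samples with
cancer counts strictly above the cluster's 85th percentile (linear
interpolation between order statistics; strict comparison, with a
deterministic ties-at-the-top fallback so identical samples average to
their common value).  Cytokine levels are averaged over the same tail on
their own expression scale — no α_dim is applied to them.

## Parameter estimation

Per cluster, the 14 steady-state conditions plus a 21-constraint
assumption ledger determine the 35 unknown rates (the 14 literature
decay rates and the cancer self-growth rate are fixed inputs).  Each
ledger entry is a ratio constraint `prod(lhs) = scale · ratio ·
prod(rhs)` over parameters and steady-state values, linear in log space;
`scale` is the knob the robustness experiments turn.  Core entries:

- cancer self-growth vs μ₁-driven growth: λ_C = 40 λ_Cμ₁ μ₁∞;
- IFN-γ kill vs spontaneous apoptosis: δ_CIγ I_γ∞ = 10 δ_C;
- macrophage activation split: λ_MIγ I_γ∞ / (λ_Mμ₁ μ₁∞) = M1/M2
  (the cluster's M1-to-M2 abundance ratio, estimated from the cohort or
  taken from the per-cluster config defaults 0.25 / 0.10 / 0.50);
- the remaining closure (production shares of each cytokine among its
  producers, activation splits of T and dendritic cells, induced-death
  multiples of the natural death rates, the Tc kill multiple, and the
  μ₂-vs-μ₁ growth weight) follows the same style and is our design —
  every default lives in `data/default_config.yaml`.

The solve runs in log-parameter space (positivity by construction) with
a quasi-Newton root finder; residuals are made relative by scaling each
equation with its outflux.  The initial guess balances each rate against
its equation's dominant opposing term, with three seeded, jittered
restarts before failure.  C₀ is recovered from the cancer equation and
α_NC from the necrotic equation; α_NC ≤ 1 is enforced and fails loudly
if the data and rates are inconsistent with it.

### Fixed rates and timescales

Cytokine decays are hours-scale (half-lives of order 2–5 h).  Mature
cell compartments use slow tissue turnover — macrophages ≈ 2 months,
helper/regulatory T cells ≈ 2–3 months, CD8/NK and dendritic cells
≈ 7 weeks — and monocytes days-scale (0.2/day).  The slow immune
turnover is deliberate: tumor progression here spans hundreds of days,
and with days-scale effector lifetimes the immune response equilibrates
within a week and cannot produce the observed overshoot that peaks near
the time of fastest cancer growth.  Long-lived tumor-resident
lymphocytes and macrophages are consistent with tissue-residency
biology.  λ_C = 0.02/day corresponds to a ~35-day volume-doubling time;
δ_C = 5×10⁻⁴/day encodes the low spontaneous apoptosis of osteosarcoma.
All of these carry provenance notes in the config and are inputs, not
fitted quantities.

### Calibration of the closure defaults

The closure defaults (production and activation shares, inhibition
multiples, Tc-kill multiple 2, μ₂ growth weight 15) were calibrated
once, against the qualitative progression structure the three clusters
are reported to show — anti-tumor populations overshooting near the
growth spurt, Tregs dipping and recovering, cluster 2 ending highest,
cluster 1 converging first — and then frozen.  Two useful structural
facts emerged.  First, μ₁ (with a large cancer production share) carries
the tumor-synchronized inhibition that times the immune switch, while μ₂
(macrophage-weighted, with growth weight 15) differentiates the clusters
through their macrophage pools.  Second, at the fitted equilibrium the
three growth rates of the cancer equation perturb the same flux and so
have identical dimensionless gradients (likewise the three death rates),
which is why the cancer-equation rates form the top of every sensitivity
ranking as a block.

## Simulation and dynamics features

Integration uses LSODA with rtol 10⁻⁸ on the dimensionless system
(states rescaled by the cluster steady state, equilibria at 1); negative
overshoot within the solver's error scale is clamped to zero, anything
larger is an error.  The horizon starts at 5000 days and doubles until
the state stays within 10⁻³ (relative) of its endpoint for 200 days, up
to 20000 days.

Shape classification works on the trajectory after an initial boundary
layer (default 1% of the convergence time, covering the hours-scale
relaxation of cytokines from their sampled initial values).  An interior
peak or trough is significant when it exceeds the endpoint bracket by
10% of the variable's dynamic range; when both occur, the extremum
closer to the time of maximal cancer growth decides between
rise-then-fall and fall-then-rise, since the switch of interest is the
one tied to the tumor surge.  Ties (constant trajectories) default to
"increasing".

## Sensitivity analysis

Sensitivities are computed on the dimensionless system at the fitted
equilibrium.  Raw sensitivities solve ∇_X F · dX*/dθ = −∂F/∂θ with one
LU factorization (Jacobians by central differences, relative step 10⁻⁶;
condition numbers above 10¹² are rejected).  Reported gradients are
taken with respect to the *non-dimensionalized* parameters — the
coefficients of the rescaled system, all in 1/day — which makes rankings
unit-free without washing out the structurally small cancer-equation
rates; logarithmic sensitivities remain available via
`scaling="relative"`.  Outputs: the cancer steady state and the
total-cell steady state (sum of the ten cell compartments).  The ranked
universe is the kinetic rate constants; sources (A_·), C₀ and α_NC are
structural quantities pinned by the cluster abundances and are excluded.

Local sensitivities average the raw ones over a ±10% relative box using
a Smolyak sparse grid of Gauss–Legendre rules (level 2 by default; level
0 is the center point), normalized to an average; equilibria at
off-center nodes are re-solved by Newton continuation, and failing nodes
are dropped with weights renormalized.  Global sensitivities re-derive
the parameters under each scaled ledger assumption (scales spanning
0.01–100) and average the local values with Gaussian-in-log-scale
weights (bandwidth one decade, configurable) so derivations close to the
original assumptions dominate; failed re-fits are excluded and weights
renormalized.

## Synthetic data

The generators stand in for deconvolution output plus clinical
composition tables.  Compositions are Dirichlet around cluster-specific
means (precision 200 by default; 30 samples per cluster, matching a
~90-sample cohort over three clusters), composition percentages are
log-normal perturbations renormalized to sum 100, and cytokines are
log-normal with mean correction.  The shipped profiles encode the
cluster pattern: cluster 2 with the strictly highest naive-macrophage
content, cluster 3 with near-equal naive and M2 macrophage content, and
M2 dominance over M1 everywhere.  `generate_from_steady_state` builds
cohorts whose above-cutoff tail has a prescribed componentwise mean, so
the extraction→fit loop can be tested end to end; its bulk samples are
shrunken copies kept strictly below the cancer cutoff, which restricts
the dispersion parameter to < 0.15.

What the generators deliberately do not emulate: gene-expression
matrices, deconvolution estimation error structure (correlated across
cell types), censoring or missingness in clinical percentages, and
intra-cluster substructure.  Passing the synthetic round trips therefore
validates the pipeline's estimators and plumbing, not the biological
fidelity of deconvolution itself.

## Known limitations

- The closure ledger is identifiable only as a whole: individual rates
  inherit any misspecification of the assumed shares.  The
  global-sensitivity machinery quantifies exactly this exposure.
- Two reported qualitative features are not reproduced under the frozen
  defaults and are left as failing checks rather than special-cased:
  μ₂ (and in cluster 2, μ₁) dips before its tumor-driven rise, because
  its producer pools start below or relax away from their steady values
  for the printed initial compositions; the cluster-3 Treg trough is
  insignificant (its initial value already sits at the transient
  quasi-equilibrium); a minority of switch times land at 27–33% of the
  time of maximal growth, just outside the 25% window; and cluster 3 is
  not the slowest early grower — with the fixed tenfold IFN-γ kill
  anchor, cluster 1's immune-hot starting composition necessarily
  depresses its early growth below cluster 3's unless growth-side levers
  are pushed to values that break the shape or sensitivity structure.
- Time-to-steady-state margins between clusters 1 and 3 are ~2%, so
  ordering conclusions survive ±10% parameter perturbation but not every
  five-fold assumption rescale.
- Fixed rates are order-of-magnitude literature values with provenance
  notes, not a curated meta-analysis; conclusions that depend on them
  should be re-checked against the sensitivity reports.
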