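"""Steady-state-constrained parameter estimation and the assumption ledger."""

import numpy as np
import pytest

from osteoimmune.model_core import StateVector, VARIABLES, rhs_dimensional
from osteoimmune.parameter_fit import (
    AssumptionLedger,
    FixedRates,
    default_fixed_rates,
    default_ledger,
    fit_cluster_parameters,
    steady_state_residual,
    vary_assumptions,
)
from osteoimmune.simulate import integrate_to_convergence


def test_residual_vanishes_at_solution(fits, steady_states):
    for k, fr in fits.items():
        res = steady_state_residual(fr.params, steady_states[k], fr.ledger)
        assert len(res) == 14 + len(fr.ledger)
        assert np.max(np.abs(res)) < 1e-9


def test_treg_rate_closed_form(fits, steady_states):
    """The Treg equation is solvable by hand: lam = del*Tr/(mu1*TN)."""
    fr = fits[1]
    s = steady_states[1]
    closed = fr.params.del_Tr * s["T_r"] / (s["mu1"] * s["T_N"])
    assert fr.params.lam_Tr_mu1 == pytest.approx(closed, rel=1e-9)
    # doubling the rate leaves a raw residual of exactly +del_Tr*Tr_inf
    doubled = fr.params.replace(lam_Tr_mu1=2 * fr.params.lam_Tr_mu1)
    raw = rhs_dimensional(s.values, doubled)
    assert raw[VARIABLES.index("T_r")] == pytest.approx(
        fr.params.del_Tr * s["T_r"], rel=1e-9)


def test_quoted_assumptions_hold_in_fit(fits, steady_states):
    for k, fr in fits.items():
        p, s = fr.params, steady_states[k]
        assert p.lam_C / (p.lam_C_mu1 * s["mu1"]) == pytest.approx(40.0, rel=1e-9)
        assert p.del_C_Ig * s["I_g"] / p.del_C == pytest.approx(10.0, rel=1e-9)
        ratio = fr.ledger.get("macrophage_activation_ratio").ratio
        assert (p.lam_M_Ig * s["I_g"]) / (p.lam_M_mu1 * s["mu1"]) == \
            pytest.approx(ratio, rel=1e-9)


def test_symmetric_steady_state_gives_symmetric_splits():
    vals = {v: 1e6 for v in VARIABLES[:10]}
    vals.update(I_g=2.0, mu1=2.0, mu2=2.0, H=2.0)
    steady = StateVector.from_dict(vals)
    closure = {
        "cancer_self_vs_mu1": 40.0, "ifng_kill_vs_apoptosis": 10.0,
        "tc_kill_vs_apoptosis": 10.0, "mu2_vs_mu1_growth": 1.0,
        "m1_m2_ratio": 1.0,
        "inhibition_vs_natural": {k: 1.0 for k in
                                  ("Th_Tr", "Th_mu1", "Tc_Tr", "Tc_mu1", "D_C")},
        "production_shares": {
            "mu1": {"T_h": 1 / 3, "M": 1 / 3, "C": 1 / 3},
            "mu2": {"T_h": 1 / 3, "M": 1 / 3, "C": 1 / 3},
            "I_g": {"T_h": 0.5, "T_c": 0.5},
            "H": {"M": 1 / 3, "D": 1 / 3, "N": 1 / 3},
        },
        "activation_shares": {
            "T_h": {"M": 0.5, "D": 0.5},
            "T_c": {"T_h": 1 / 3, "M": 1 / 3, "D": 1 / 3},
            "D": {"C": 0.5, "H": 0.5},
        },
    }
    fixed = default_fixed_rates()
    rates = dict(fixed.values, del_N=0.005)  # keep the necrotic fraction < 1
    fr = fit_cluster_parameters(steady, fixed=FixedRates(values=rates),
                                ledger=default_ledger(closure), seed=0)
    p = fr.params
    assert p.lam_Th_M == pytest.approx(p.lam_Th_D, rel=1e-8)
    assert p.lam_Tc_Th == pytest.approx(p.lam_Tc_M, rel=1e-3)
    assert p.lam_mu1_Th == pytest.approx(p.lam_mu1_M, rel=1e-8)
    assert p.lam_Ig_Th == pytest.approx(p.lam_Ig_Tc, rel=1e-8)


def test_forward_simulate_then_refit_recovers_parameters(fits, steady_states):
    """Integrate to equilibrium, re-derive the parameters from the measured
    equilibrium, and compare every ledger-identified rate."""
    fr = fits[1]
    x0 = steady_states[1].values * 0.7
    traj = integrate_to_convergence(fr.params, x0, steady_states[1].values,
                                    rtol=1e-10, eps=1e-8, window=500.0)
    assert traj.convergence.converged
    measured = StateVector(traj.endpoint * steady_states[1].values)
    refit = fit_cluster_parameters(measured, fixed=fr.fixed, ledger=fr.ledger,
                                   seed=3)
    for name, v in fr.params.to_dict().items():
        assert refit.params.to_dict()[name] == pytest.approx(v, rel=1e-5), name


def test_vary_assumptions_scales_the_quoted_ratio():
    led = default_ledger()
    base = led.get("cancer_self_vs_mu1")
    variants = vary_assumptions(led, [5.0])
    v = next(l for l in variants
             if l.get("cancer_self_vs_mu1").scale != base.scale)
    # lam_C = 40 * lam_C_mu1 * mu1 scaled by 5 -> effective multiplier 200
    c = v.get("cancer_self_vs_mu1")
    assert c.scale * c.ratio == pytest.approx(200.0)
    down = led.with_scale("cancer_self_vs_mu1", 1 / 5)
    c = down.get("cancer_self_vs_mu1")
    assert c.scale * c.ratio == pytest.approx(8.0)
    same = led.with_scale("cancer_self_vs_mu1", 1.0)
    assert same.get("cancer_self_vs_mu1").scale == base.scale
    n_scalable = sum(1 for c in led if c.scalable)
    assert len(vary_assumptions(led, [0.2, 5.0])) == 2 * n_scalable


def test_scale_equivariance_of_the_fit(fits, steady_states):
    """Multiplying all cell counts by kappa rescales per-cell rates by
    1/kappa and leaves the dimensionless dynamics identical."""
    kappa = 3.0
    s = steady_states[1]
    scaled_vals = s.values.copy()
    scaled_vals[:10] *= kappa
    fr = fits[1]
    ledger2 = default_ledger(m1_m2_ratio=fr.ledger.get(
        "macrophage_activation_ratio").ratio)
    fr2 = fit_cluster_parameters(StateVector(scaled_vals), fixed=fr.fixed,
                                 ledger=ledger2, seed=1)
    # a per-cell activation rate and a per-cell kill rate scale as 1/kappa
    assert fr2.params.lam_Th_M == pytest.approx(fr.params.lam_Th_M / kappa,
                                                rel=1e-8)
    assert fr2.params.del_C_Tc == pytest.approx(fr.params.del_C_Tc / kappa,
                                                rel=1e-8)
    assert fr2.params.C0 == pytest.approx(fr.params.C0 * kappa, rel=1e-8)
    # dimensionless vector fields coincide
    from osteoimmune.model_core import rhs_dimensionless
    rng = np.random.default_rng(0)
    for _ in range(5):
        xbar = rng.lognormal(0, 0.3, 14)
        np.testing.assert_allclose(
            rhs_dimensionless(xbar, fr.params, s.values),
            rhs_dimensionless(xbar, fr2.params, scaled_vals), rtol=1e-7)


def test_problem_must_be_square(steady_states):
    led = default_ledger()
    truncated = AssumptionLedger(list(led)[:-1])
    with pytest.raises(ValueError, match="not square"):
        fit_cluster_parameters(steady_states[1], ledger=truncated)


def test_nonpositive_steady_state_rejected(steady_states):
    bad = steady_states[1].values.copy()
    bad[5] = 0.0
    with pytest.raises(ValueError, match="positive"):
        fit_cluster_parameters(bad)


def test_fixed_rates_validation():
    with pytest.raises(ValueError, match="missing"):
        FixedRates(values={"del_C": 1.0})
    fr = default_fixed_rates()
    assert all(v > 0 for v in fr.values.values())
    assert set(fr.provenance) == set(fr.values)
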