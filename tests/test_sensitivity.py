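"""Implicit-function sensitivities, sparse grids, and global averaging."""

import math

import numpy as np
import pandas as pd
import pytest

from osteoimmune.model_core import VARIABLES
from osteoimmune.sensitivity import (
    CANCER_EQ_PARAMETERS,
    NECROTIC_EQ_PARAMETERS,
    RATE_PARAMETERS,
    global_sensitivity,
    local_sensitivity,
    output_sensitivities,
    rank_and_sign,
    solve_fixed_point,
    sparse_grid,
    steady_state_sensitivity,
)


@pytest.mark.parametrize("dim,level", [(1, 0), (3, 0), (3, 1), (3, 2), (8, 2)])
def test_sparse_grid_weights_normalized_and_odd_exact(dim, level):
    pts, w = sparse_grid(dim, level)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    # odd integrands vanish on the symmetric grid
    assert abs((w[:, None] * pts).sum()) < 1e-12
    if level == 0:
        assert len(w) == 1 and np.all(pts == 0)


def test_sparse_grid_matches_dense_tensor_quadrature():
    """Average of a smooth function over [-1,1]^2: level-2 sparse grid vs a
    dense Gauss-Legendre tensor grid."""
    f = lambda x: 1.3 + 0.7 * x[..., 0] - 0.2 * x[..., 1] \
        + 0.5 * x[..., 0] ** 2 + 0.1 * x[..., 0] * x[..., 1]
    pts, w = sparse_grid(2, 2)
    got = float(np.sum(w * f(pts)))
    gx, gw = np.polynomial.legendre.leggauss(6)
    X, Y = np.meshgrid(gx, gx)
    W = np.outer(gw, gw) / 4.0
    want = float(np.sum(W * f(np.stack([X, Y], axis=-1))))
    assert got == pytest.approx(want, abs=1e-12)


def test_decoupled_cancer_sensitivity_matches_logistic_closed_form(
        fits, steady_states):
    """With the cancer couplings switched off, C* = C0 (1 - del_C/lam_C),
    so dC*/d(del_C) = -C0/lam_C exactly."""
    p = fits[1].params.replace(del_C_Tc=0.0, del_C_Ig=0.0,
                               lam_C_mu1=0.0, lam_C_mu2=0.0)
    xinf = steady_states[1].values
    xbar = solve_fixed_point(p, xinf)
    S = steady_state_sensitivity(p, xinf, ["del_C"], xbar=xbar)
    got = S.loc["C", "del_C"] * xinf[VARIABLES.index("C")]  # back to cells
    assert got == pytest.approx(-p.C0 / p.lam_C, rel=1e-6)


def test_sensitivities_match_refit_finite_difference_oracle(
        fits, steady_states):
    """Dual route: implicit-function columns vs re-solving the equilibrium
    at perturbed parameters and central-differencing."""
    probe = ["lam_C", "del_C", "del_Tr", "lam_Tr_mu1", "lam_M_mu1",
             "del_M", "lam_Th_M", "del_Ig"]
    for k in (1, 3):
        p = fits[k].params
        xinf = steady_states[k].values
        S = steady_state_sensitivity(p, xinf, probe)
        for name in probe:
            theta = getattr(p, name)
            h = 1e-4 * theta
            xp = solve_fixed_point(p.replace(**{name: theta + h}), xinf)
            xm = solve_fixed_point(p.replace(**{name: theta - h}), xinf)
            fd = (xp - xm) / (2 * h)
            scale = np.maximum(np.abs(fd), np.abs(S[name].to_numpy()))
            err = np.abs(S[name].to_numpy() - fd) / np.maximum(scale, 1e-12)
            mask = scale > 1e-10 * np.max(scale)  # skip numerically dead entries
            assert err[mask].max() < 1e-4, (k, name, err[mask].max())


def test_gradient_ties_within_cancer_equation(fits, steady_states):
    """At the fitted equilibrium the three growth rates (and the three
    death rates) of the cancer equation have identical dimensionless
    gradients -- they perturb the same flux."""
    S = steady_state_sensitivity(fits[2].params, steady_states[2])
    out = output_sensitivities(S, fits[2].params, steady_states[2])
    g = out["cancer"]
    assert g["lam_C"] == pytest.approx(g["lam_C_mu1"], rel=1e-6)
    assert g["lam_C"] == pytest.approx(g["lam_C_mu2"], rel=1e-6)
    assert g["del_C"] == pytest.approx(g["del_C_Tc"], rel=1e-6)


def test_local_sensitivity_degenerate_cases(fits, steady_states):
    p, s = fits[1].params, steady_states[1]
    probe = ["lam_C", "del_Tr", "lam_M_mu1"]
    center = local_sensitivity(p, s, probe, rel_width=0.1, level=0)
    S = steady_state_sensitivity(p, s, probe)
    want = output_sensitivities(S, p, s)
    pd.testing.assert_frame_equal(center, want, check_exact=False, rtol=1e-9,
                                  check_frame_type=False)
    zero_width = local_sensitivity(p, s, probe, rel_width=0.0, level=1,
                                   varied=probe)
    pd.testing.assert_frame_equal(zero_width, want, check_exact=False,
                                  rtol=1e-7, check_frame_type=False)


def test_local_sensitivity_level_consistency(fits, steady_states):
    """Averaging over a +-10% box changes little between sparse-grid levels
    for a smooth sensitivity surface."""
    p, s = fits[1].params, steady_states[1]
    probe = ["lam_C", "del_Tr"]
    l1 = local_sensitivity(p, s, probe, rel_width=0.1, level=1, varied=probe)
    l2 = local_sensitivity(p, s, probe, rel_width=0.1, level=2, varied=probe)
    assert np.allclose(l1["cancer"], l2["cancer"], rtol=5e-3)


def test_global_sensitivity_matches_enumeration(fits, steady_states):
    """K=3 scales on one assumption: the weighted average is reproduced by
    direct enumeration with the Gaussian-in-log-scale weights."""
    from osteoimmune.parameter_fit import fit_cluster_parameters
    probe = ["lam_C", "del_Tr", "lam_Tr_mu1"]
    scales = (0.2, 1.0, 5.0)
    got = global_sensitivity(steady_states[1], fits[1].ledger,
                             fits[1].fixed, probe, scales=scales,
                             assumptions=["cancer_self_vs_mu1"],
                             bandwidth=1.0, level=0, seed=1)
    acc, wsum = None, 0.0
    for sc in scales:
        led = fits[1].ledger.with_scale("cancer_self_vs_mu1", sc)
        fr = fit_cluster_parameters(steady_states[1], fits[1].fixed, led, seed=1)
        S = steady_state_sensitivity(fr.params, steady_states[1], probe)
        out = output_sensitivities(S, fr.params, steady_states[1])
        w = math.exp(-(math.log10(sc)) ** 2 / 2.0)
        acc = out * w if acc is None else acc + out * w
        wsum += w
    want = acc / wsum
    pd.testing.assert_frame_equal(got, want, check_exact=False, rtol=1e-9,
                                  check_frame_type=False)
    # single scale 1 degenerates to the local value at the base assumptions
    single = global_sensitivity(steady_states[1], fits[1].ledger,
                                fits[1].fixed, probe, scales=(1.0,),
                                assumptions=["cancer_self_vs_mu1"],
                                level=0, seed=1)
    base = local_sensitivity(fits[1].params, steady_states[1], probe, level=0)
    pd.testing.assert_frame_equal(single, base, check_exact=False, rtol=1e-8,
                                  check_frame_type=False)


def test_rank_and_sign_basics():
    s = pd.Series({"a": 0.0, "b": -3.0, "c": 0.5})
    top = rank_and_sign(s, top_k=2)
    assert list(top.parameter) == ["b", "c"]
    assert list(top.sign) == [-1, 1]
    only = pd.Series({"a": 0.0, "b": 0.0, "c": 0.7})
    assert rank_and_sign(only, top_k=1).parameter.tolist() == ["c"]
    excl = rank_and_sign(s, top_k=2, exclude=("b",))
    assert "b" not in set(excl.parameter)


def test_singular_jacobian_rejected(fits, steady_states):
    # a decay-free decoupled cytokine makes the state Jacobian singular
    p = fits[1].params.replace(del_H=0.0, lam_H_M=0.0, lam_H_D=0.0,
                               lam_H_N=0.0)
    with pytest.raises((RuntimeError, ValueError)):
        S = steady_state_sensitivity(p, steady_states[1])
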