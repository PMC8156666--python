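"""Steady-state sensitivity analysis of the tumor-immune model.

Raw sensitivities dX*/dθ come from the implicit-function theorem: at an
equilibrium F(X*, θ) = 0, differentiating gives
``∇_X F · dX*/dθ = −∂F/∂θ``, a linear solve per parameter.  Local
sensitivities average the raw ones over a relative box around the fitted
parameters with sparse-grid quadrature; global sensitivities re-derive
the parameters under scaled closure assumptions and average the local
values with weights favouring scales near 1.

Everything is computed on the dimensionless system and reported as
relative (logarithmic) sensitivities θ/Y · dY/dθ for the two outputs of
interest: the cancer steady state and the total-cell steady state (the
sum of the ten cell compartments), so rankings are unit-free.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    PARAMETER_NAMES,
    VARIABLES,
    ParameterSet,
    StateVector,
    rhs_dimensionless,
)
from .parameter_fit import (
    AssumptionLedger,
    FixedRates,
    fit_cluster_parameters,
)

__all__ = [
    "RATE_PARAMETERS",
    "CANCER_EQ_PARAMETERS",
    "NECROTIC_EQ_PARAMETERS",
    "solve_fixed_point",
    "steady_state_sensitivity",
    "output_sensitivities",
    "local_sensitivity",
    "global_sensitivity",
    "rank_and_sign",
    "sparse_grid",
    "SensitivityReport",
]

#: Kinetic rate constants ranked by the analysis.  Structural quantities
#: (sources, carrying capacity, necrotic fraction) are determined directly
#: by the cluster abundances and are not part of the ranked universe.
RATE_PARAMETERS: tuple[str, ...] = tuple(
    n for n in PARAMETER_NAMES if n.startswith(("lam_", "del_"))
)

CANCER_EQ_PARAMETERS: tuple[str, ...] = (
    "lam_C", "lam_C_mu1", "lam_C_mu2", "del_C_Tc", "del_C_Ig", "del_C",
)
NECROTIC_EQ_PARAMETERS: tuple[str, ...] = ("del_N",)

_COND_LIMIT = 1e12


def _steady_array(steady) -> np.ndarray:
    return steady.values if isinstance(steady, StateVector) else np.asarray(steady, float)


def solve_fixed_point(params: ParameterSet, steady,
                      x0: np.ndarray | None = None,
                      tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Newton solve of the dimensionless equilibrium F(x̄) = 0.

    ``steady`` supplies the non-dimensionalization scale; ``x0`` the
    starting point (all-ones by default, i.e. the fitted equilibrium).
    """
    xinf = _steady_array(steady)
    x = np.ones(len(VARIABLES)) if x0 is None else np.asarray(x0, float).copy()
    for _ in range(max_iter):
        f = rhs_dimensionless(x, params, xinf, check=False)
        if np.max(np.abs(f)) < tol:
            return x
        J = state_jacobian(params, xinf, x)
        step = np.linalg.solve(J, -f)
        lam = 1.0
        fn0 = np.linalg.norm(f)
        for _ in range(30):  # backtracking; keeps iterates positive
            xn = x + lam * step
            if np.all(xn > 0):
                fn = np.linalg.norm(
                    rhs_dimensionless(xn, params, xinf, check=False))
                if fn < fn0:
                    break
            lam *= 0.5
        else:
            raise RuntimeError("fixed-point Newton line search failed")
        x = xn
    raise RuntimeError(
        f"fixed point did not converge (last residual {np.max(np.abs(f)):.2e})")


def state_jacobian(params: ParameterSet, xinf: np.ndarray, xbar: np.ndarray,
                   rel_step: float = 1e-6) -> np.ndarray:
    """∇_X F by central finite differences on the dimensionless system."""
    n = len(VARIABLES)
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(xbar[j]), 1e-3)
        xp, xm = xbar.copy(), xbar.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (rhs_dimensionless(xp, params, xinf, check=False)
                   - rhs_dimensionless(xm, params, xinf, check=False)) / (2 * h)
    return J


def _param_jacobian(params: ParameterSet, xinf: np.ndarray, xbar: np.ndarray,
                    names: Sequence[str], rel_step: float = 1e-6) -> np.ndarray:
    d = params.to_dict()
    n = len(VARIABLES)
    P = np.empty((n, len(names)))
    for j, name in enumerate(names):
        v = d[name]
        h = rel_step * v if v > 0 else rel_step
        up, dn = dict(d), dict(d)
        up[name] = v + h
        dn[name] = max(v - h, 0.0)
        hh = up[name] - dn[name]
        P[:, j] = (rhs_dimensionless(xbar, ParameterSet.from_dict(up), xinf, check=False)
                   - rhs_dimensionless(xbar, ParameterSet.from_dict(dn), xinf, check=False)) / hh
    return P


def steady_state_sensitivity(params: ParameterSet, steady,
                             parameters: Sequence[str] | None = None,
                             xbar: np.ndarray | None = None,
                             rel_step: float = 1e-6,
                             residual_tol: float = 1e-6) -> pd.DataFrame:
    """Raw equilibrium sensitivities dX̄*/dθ, one column per parameter.

    ``steady`` must hold the non-dimensionalization scale and ``xbar`` the
    dimensionless fixed point (all-ones for freshly fitted parameters).
    Solved as a single LU factorization with many right-hand sides, never
    by explicit inversion.
    """
    xinf = _steady_array(steady)
    names = list(parameters) if parameters is not None else list(RATE_PARAMETERS)
    if xbar is None:
        xbar = np.ones(len(VARIABLES))
    res = np.max(np.abs(rhs_dimensionless(xbar, params, xinf, check=False)))
    if res > residual_tol:
        raise ValueError(
            f"xbar is not a fixed point (residual {res:.2e}); "
            "solve_fixed_point first")
    J = state_jacobian(params, xinf, xbar, rel_step)
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise RuntimeError(
            f"state Jacobian ill-conditioned (condition number {cond:.3e})")
    P = _param_jacobian(params, xinf, xbar, names, rel_step)
    S = np.linalg.solve(J, -P)
    return pd.DataFrame(S, index=list(VARIABLES), columns=names)


#: steady-state factors turning each rate into its dimensionless
#: counterpart (the coefficient it contributes to the rescaled system):
#: production rates scale by producer∞/product∞, activation rates by
#: activator∞ · naive∞ / mature∞, mass-action death rates by the partner's
#: steady abundance, and plain decay rates are already per-day.
_ND_FACTORS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    # name: (numerator steady vars, denominator steady vars)
    "lam_mu1_Th": (("T_h",), ("mu1",)), "lam_mu1_M": (("M",), ("mu1",)),
    "lam_mu1_C": (("C",), ("mu1",)),
    "lam_mu2_Th": (("T_h",), ("mu2",)), "lam_mu2_M": (("M",), ("mu2",)),
    "lam_mu2_C": (("C",), ("mu2",)),
    "lam_Ig_Th": (("T_h",), ("I_g",)), "lam_Ig_Tc": (("T_c",), ("I_g",)),
    "lam_H_M": (("M",), ("H",)), "lam_H_D": (("D",), ("H",)),
    "lam_H_N": (("N",), ("H",)),
    "lam_M_Ig": (("I_g", "M_N"), ("M",)), "lam_M_mu1": (("mu1", "M_N"), ("M",)),
    "lam_Th_M": (("M", "T_N"), ("T_h",)), "lam_Th_D": (("D", "T_N"), ("T_h",)),
    "lam_Tr_mu1": (("mu1", "T_N"), ("T_r",)),
    "lam_Tc_Th": (("T_h", "T_N"), ("T_c",)),
    "lam_Tc_M": (("M", "T_N"), ("T_c",)), "lam_Tc_D": (("D", "T_N"), ("T_c",)),
    "lam_D_C": (("C", "D_N"), ("D",)), "lam_D_H": (("H", "D_N"), ("D",)),
    "del_Th_Tr": (("T_r",), ()), "del_Th_mu1": (("mu1",), ()),
    "del_Tc_Tr": (("T_r",), ()), "del_Tc_mu1": (("mu1",), ()),
    "del_D_C": (("C",), ()),
    "del_C_Tc": (("T_c",), ()), "del_C_Ig": (("I_g",), ()),
    "lam_C_mu1": (("mu1",), ()), "lam_C_mu2": (("mu2",), ()),
    "A_MN": ((), ("M_N",)), "A_TN": ((), ("T_N",)), "A_DN": ((), ("D_N",)),
}


def dimensionless_parameter_values(params: ParameterSet, steady,
                                   names: Sequence[str]) -> np.ndarray:
    """Values of the non-dimensionalized parameters θ̄ (all in 1/day)."""
    xinf = _steady_array(steady)
    sval = dict(zip(VARIABLES, xinf))
    out = np.empty(len(names))
    for j, n in enumerate(names):
        v = float(getattr(params, n))
        num, den = _ND_FACTORS.get(n, ((), ()))
        for s in num:
            v *= sval[s]
        for s in den:
            v /= sval[s]
        out[j] = v
    return out


def output_sensitivities(S: pd.DataFrame, params: ParameterSet, steady,
                         xbar: np.ndarray | None = None,
                         scaling: str = "dimensionless") -> pd.DataFrame:
    """Sensitivities of the cancer and total-cell steady states.

    ``scaling='dimensionless'`` (default) reports the gradient of the
    rescaled outputs with respect to the *non-dimensionalized* parameters
    dȲ*/dθ̄ — the unit-free gradient of the rescaled system.
    ``scaling='relative'`` reports logarithmic sensitivities
    θ/Y·dY/dθ instead.  Rows indexed by parameter.
    """
    xinf = _steady_array(steady)
    if xbar is None:
        xbar = np.ones(len(VARIABLES))
    names = list(S.columns)
    theta = np.array([getattr(params, n) for n in names])
    Sm = S.to_numpy()
    c_idx = VARIABLES.index("C")
    out_c = xbar[c_idx]
    rel_c = theta * Sm[c_idx, :] / out_c
    w = xinf[:10]  # cell compartments, dimensional weights
    total = float(w @ xbar[:10])
    rel_t = theta * (w @ Sm[:10, :]) / total
    if scaling == "relative":
        return pd.DataFrame({"cancer": rel_c, "total_cells": rel_t}, index=names)
    if scaling != "dimensionless":
        raise ValueError("scaling must be 'dimensionless' or 'relative'")
    theta_nd = dimensionless_parameter_values(params, xinf, names)
    safe = np.where(theta_nd > 0, theta_nd, np.inf)
    # rescaled outputs: C̄ and total cells relative to the steady total
    total_bar = total / float(w.sum())
    return pd.DataFrame({"cancer": rel_c * out_c / safe,
                         "total_cells": rel_t * total_bar / safe}, index=names)


# ---------------------------------------------------------------------------
# sparse-grid quadrature (Smolyak combination of Gauss-Legendre rules)

def _gl(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w / 2.0  # normalized: averages over [-1, 1]


def sparse_grid(dim: int, level: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes (in [-1,1]^dim) and weights of a Smolyak sparse grid.

    Built by the combination technique over univariate Gauss-Legendre
    rules with ``k`` points at univariate level ``k``; weights average
    (sum to 1).  Level 0 is the single midpoint.  Exact for constants at
    every level and, by symmetry, for odd (e.g. linear) integrands.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    nodes: dict[tuple[float, ...], float] = {}
    # multi-indices k >= 1 with level - dim + 1 <= |k| - dim <= level
    for excess in range(max(0, level - dim + 1), level + 1):
        coeff = (-1.0) ** (level - excess) * math.comb(dim - 1, level - excess)
        if coeff == 0:
            continue
        # distribute `excess` over at most `excess` coordinates
        for combo in _compositions(excess, dim):
            active = [(i, 1 + e) for i, e in combo]
            rules = [_gl(k) for _, k in active]
            for pts in itertools.product(*(range(k) for _, k in active)):
                node = [0.0] * dim
                w = coeff
                for (i, _), (xs, ws), p in zip(active, rules, pts):
                    node[i] = float(xs[p])
                    w *= float(ws[p])
                key = tuple(node)
                nodes[key] = nodes.get(key, 0.0) + w
    if level == 0:
        nodes = {tuple([0.0] * dim): 1.0}
    pts = np.array(list(nodes.keys()))
    wts = np.array(list(nodes.values()))
    keep = np.abs(wts) > 1e-15
    return pts[keep], wts[keep]


def _compositions(total: int, dim: int):
    """All placements of `total` excess points over distinct coordinates."""
    if total == 0:
        yield ()
        return
    for npos in range(1, min(total, dim) + 1):
        for positions in itertools.combinations(range(dim), npos):
            for split in _positive_compositions(total, npos):
                yield tuple(zip(positions, split))


def _positive_compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for rest in _positive_compositions(total - first, parts - 1):
            yield (first,) + rest


@dataclass
class NodeFailure:
    node_index: int
    reason: str


def local_sensitivity(params: ParameterSet, steady,
                      parameters: Sequence[str] | None = None,
                      rel_width: float = 0.1,
                      level: int = 2,
                      varied: Sequence[str] | None = None) -> pd.DataFrame:
    """Neighborhood-averaged relative sensitivities.

    Averages the implicit-function sensitivities over the box
    ``θ_i (1 ± rel_width)`` using a sparse grid of the given ``level``
    (level 0 = center point only).  The box spans ``varied`` (default:
    the ranked rate parameters); at each off-center node the equilibrium
    is re-solved by Newton continuation from the center fixed point.
    Nodes where the equilibrium is lost are dropped and reported via the
    ``attrs['failures']`` of the result, with weights renormalized.
    """
    names = list(parameters) if parameters is not None else list(RATE_PARAMETERS)
    vary = list(varied) if varied is not None else names
    xinf = _steady_array(steady)
    pts, wts = sparse_grid(len(vary), level)
    base = params.to_dict()
    theta0 = np.array([base[n] for n in vary])
    acc = None
    wsum = 0.0
    failures: list[NodeFailure] = []
    for i, (xi, w) in enumerate(zip(pts, wts)):
        d = dict(base)
        for n, t0, x in zip(vary, theta0, xi):
            d[n] = t0 * (1.0 + rel_width * float(x))
        p = ParameterSet.from_dict(d)
        try:
            xb = solve_fixed_point(p, xinf) if np.any(xi != 0) \
                else np.ones(len(VARIABLES))
            S = steady_state_sensitivity(p, xinf, names, xbar=xb)
            out = output_sensitivities(S, p, xinf, xbar=xb)
        except RuntimeError as exc:
            failures.append(NodeFailure(i, str(exc)))
            continue
        acc = out * w if acc is None else acc + out * w
        wsum += w
    if acc is None or wsum == 0:
        raise RuntimeError("all sparse-grid nodes failed")
    result = acc / wsum
    result.attrs["failures"] = failures
    result.attrs["level"] = level
    result.attrs["rel_width"] = rel_width
    return result


def global_sensitivity(steady, base_ledger: AssumptionLedger,
                       fixed: FixedRates | None = None,
                       parameters: Sequence[str] | None = None,
                       scales: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
                       assumptions: Sequence[str] | None = None,
                       bandwidth: float = 1.0,
                       level: int = 0,
                       rel_width: float = 0.1,
                       seed: int = 0) -> pd.DataFrame:
    """Assumption-varied weighted global sensitivities.

    For every (assumption, scale) variation the parameters are re-derived
    from the steady state under the scaled ledger, the local sensitivity
    is computed there, and the results are averaged with Gaussian-in-
    log-scale weights ``w ∝ exp(−log10(scale)² / (2·bandwidth²))``
    (normalized), so derivations close to the original assumptions count
    most.  Variations whose re-fit fails are excluded and the weights
    renormalized; if all fail an error is raised.
    """
    names = list(parameters) if parameters is not None else list(RATE_PARAMETERS)
    if assumptions is None:
        assumptions = [c.name for c in base_ledger if c.scalable]
    acc = None
    wsum = 0.0
    failures: list[tuple[str, float, str]] = []
    for name in assumptions:
        for s in scales:
            ledger_k = base_ledger.with_scale(name, float(s))
            w = math.exp(-(math.log10(s)) ** 2 / (2.0 * bandwidth ** 2))
            try:
                fit = fit_cluster_parameters(steady, fixed, ledger_k, seed=seed)
                Sk = local_sensitivity(fit.params, steady, names,
                                       rel_width=rel_width, level=level)
            except (RuntimeError, ValueError) as exc:
                failures.append((name, float(s), str(exc)))
                continue
            acc = Sk * w if acc is None else acc + Sk * w
            wsum += w
    if acc is None or wsum == 0:
        raise RuntimeError("all assumption variations failed to fit")
    result = acc / wsum
    result.attrs["failures"] = failures
    result.attrs["bandwidth"] = bandwidth
    result.attrs["scales"] = list(scales)
    return result


@dataclass
class SensitivityReport:
    """Raw, local and global relative sensitivities for one cluster."""

    cluster: int
    raw: pd.DataFrame      # parameter x {cancer, total_cells}
    local: pd.DataFrame
    global_: pd.DataFrame

    def table(self) -> pd.DataFrame:
        rows = []
        for output in ("cancer", "total_cells"):
            df = pd.DataFrame({
                "parameter": self.raw.index,
                "output": output,
                "s": self.raw[output].to_numpy(),
                "S_local": self.local[output].to_numpy(),
                "S_global": self.global_[output].to_numpy(),
            })
            df["sign"] = np.sign(df["S_global"]).astype(int)
            df["rank"] = (-df["S_global"].abs()).rank(method="first").astype(int)
            df["cluster"] = self.cluster
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def rank_and_sign(sens: pd.Series | pd.DataFrame,
                  top_k: int = 6,
                  exclude: Iterable[str] = ()) -> pd.DataFrame:
    """Top-k parameters by |sensitivity| with their signs.

    ``sens`` is a per-parameter series (or a frame whose first column is
    used).  ``exclude`` drops parameter groups, e.g. the cancer- and
    necrotic-equation parameters when ranking immune parameters.
    """
    s = sens.iloc[:, 0] if isinstance(sens, pd.DataFrame) else sens
    s = s.drop(index=[p for p in exclude if p in s.index])
    order = s.abs().sort_values(ascending=False)
    top = order.index[:top_k]
    return pd.DataFrame({
        "parameter": top,
        "sensitivity": s.loc[top].to_numpy(),
        "sign": np.sign(s.loc[top].to_numpy()).astype(int),
        "rank": np.arange(1, len(top) + 1),
    })
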