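"""Cluster-wise parameter estimation from steady-state constraints.

The rate constants of the tumor-immune system are not observable directly.
Following the standard steady-state closure approach, each cluster's
largest tumors are treated as an equilibrium of the ODE system: the 14
conditions dX/dt = 0 at the observed steady state, together with a ledger
of ratio assumptions (e.g. "self-proliferation is 40x the mu1-driven
proliferation at the steady state") and a set of literature decay rates,
make the unknown rates a square, generically solvable nonlinear system.

Solving is done in log-parameter space, which enforces positivity and
makes the ratio constraints linear.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace as dc_replace
from types import SimpleNamespace
from typing import Any, Iterable, Sequence

import numpy as np
from scipy import optimize

from .config import load_default_config
from .model_core import (
    PARAMETER_NAMES,
    VARIABLES,
    ParameterSet,
    StateVector,
    index_of,
    rhs_dimensional,
)

__all__ = [
    "FixedRates",
    "RatioConstraint",
    "AssumptionLedger",
    "default_fixed_rates",
    "default_ledger",
    "steady_state_residual",
    "fit_cluster_parameters",
    "vary_assumptions",
    "FitResult",
]

#: Rates fixed from literature rather than estimated.
FIXED_RATE_NAMES: tuple[str, ...] = (
    "del_mu1", "del_mu2", "del_Ig", "del_H",
    "del_M", "del_MN", "del_Th", "del_Tr", "del_Tc",
    "del_TN", "del_D", "del_DN", "del_N", "del_C", "lam_C",
)


@dataclass(frozen=True)
class FixedRates:
    """Literature-derived decay/death rates and the cancer growth rate.

    ``provenance`` carries a human-readable note per rate.  These are
    order-of-magnitude literature values (cytokines: hours-scale
    half-lives; effector cells: days; naive cells: weeks), not a fit.
    """

    values: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FIXED_RATE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing fixed rates: {sorted(missing)}")
        for k, v in self.values.items():
            if k not in FIXED_RATE_NAMES:
                raise ValueError(f"{k} is not a fixable rate")
            if not v > 0:
                raise ValueError(f"fixed rate {k} must be > 0, got {v}")

    @classmethod
    def from_config(cls, cfg: dict[str, Any]) -> "FixedRates":
        fr = cfg["fixed_rates"]
        return cls(values={k: float(v["value"]) for k, v in fr.items()},
                   provenance={k: str(v.get("provenance", "")) for k, v in fr.items()})


def default_fixed_rates() -> FixedRates:
    return FixedRates.from_config(load_default_config())


@dataclass(frozen=True)
class RatioConstraint:
    """One closure assumption: ``prod(lhs) = scale * ratio * prod(rhs)``.

    ``lhs_params``/``rhs_params`` name model parameters and
    ``lhs_steady``/``rhs_steady`` name state variables whose steady-state
    values enter the products.  ``ratio`` is the structural constant of the
    assumption (e.g. 40, or a data-derived abundance ratio) and ``scale``
    is the knob that the robustness experiments turn.
    """

    name: str
    lhs_params: tuple[str, ...] = ()
    rhs_params: tuple[str, ...] = ()
    lhs_steady: tuple[str, ...] = ()
    rhs_steady: tuple[str, ...] = ()
    ratio: float = 1.0
    scale: float = 1.0
    scalable: bool = True

    def __post_init__(self) -> None:
        if self.ratio <= 0 or self.scale <= 0:
            raise ValueError(f"constraint {self.name}: ratio and scale must be > 0")

    def log_residual(self, params, steady_values: np.ndarray) -> float:
        """log(lhs) - log(scale * ratio * rhs); zero when satisfied."""

        def logprod(pnames: tuple[str, ...], snames: tuple[str, ...]) -> float:
            total = 0.0
            for n in pnames:
                v = getattr(params, n)
                total += math.log(v) if v > 0 else -745.0
            for n in snames:
                total += math.log(steady_values[index_of(n)])
            return total

        lhs = logprod(self.lhs_params, self.lhs_steady)
        rhs = logprod(self.rhs_params, self.rhs_steady)
        return lhs - (rhs + math.log(self.scale * self.ratio))


class AssumptionLedger:
    """Ordered collection of ratio constraints closing the steady-state fit."""

    def __init__(self, constraints: Iterable[RatioConstraint]):
        self.constraints: list[RatioConstraint] = list(constraints)
        names = [c.name for c in self.constraints]
        if len(set(names)) != len(names):
            raise ValueError("duplicate constraint names in ledger")

    def __len__(self) -> int:
        return len(self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.constraints]

    def get(self, name: str) -> RatioConstraint:
        for c in self.constraints:
            if c.name == name:
                return c
        raise KeyError(name)

    def with_scale(self, name: str, multiplier: float) -> "AssumptionLedger":
        """A new ledger with one assumption's scale multiplied."""
        if multiplier <= 0:
            raise ValueError("scale multiplier must be > 0")
        out = []
        found = False
        for c in self.constraints:
            if c.name == name:
                out.append(dc_replace(c, scale=c.scale * multiplier))
                found = True
            else:
                out.append(c)
        if not found:
            raise KeyError(name)
        return AssumptionLedger(out)

    def residuals(self, params, steady_values: np.ndarray) -> np.ndarray:
        return np.array([c.log_residual(params, steady_values)
                         for c in self.constraints])

    def to_records(self) -> list[dict[str, Any]]:
        return [
            {
                "name": c.name,
                "lhs_params": list(c.lhs_params), "lhs_steady": list(c.lhs_steady),
                "rhs_params": list(c.rhs_params), "rhs_steady": list(c.rhs_steady),
                "ratio": c.ratio, "scale": c.scale, "scalable": c.scalable,
            }
            for c in self.constraints
        ]

    @classmethod
    def from_records(cls, records: Sequence[dict[str, Any]]) -> "AssumptionLedger":
        return cls(
            RatioConstraint(
                name=r["name"],
                lhs_params=tuple(r.get("lhs_params", ())),
                rhs_params=tuple(r.get("rhs_params", ())),
                lhs_steady=tuple(r.get("lhs_steady", ())),
                rhs_steady=tuple(r.get("rhs_steady", ())),
                ratio=float(r.get("ratio", 1.0)),
                scale=float(r.get("scale", 1.0)),
                scalable=bool(r.get("scalable", True)),
            )
            for r in records
        )


def _share_ratio(shares: dict[str, float], a: str, b: str) -> float:
    if shares[a] <= 0 or shares[b] <= 0:
        raise ValueError("production/activation shares must be > 0")
    return shares[a] / shares[b]


def default_ledger(closure: dict[str, Any] | None = None,
                   m1_m2_ratio: float | None = None,
                   cluster: int | None = None) -> AssumptionLedger:
    """Build the default 21-constraint closure ledger.

    ``closure`` follows the ``closure:`` section of the config;
    ``m1_m2_ratio`` (M1/M2 macrophage abundance ratio, ideally estimated
    from the cohort's deconvolved fractions) overrides the config value.
    When only ``cluster`` is given, the per-cluster config default is used.
    """
    cfg = closure if closure is not None else load_default_config()["closure"]
    if m1_m2_ratio is None and cluster is not None:
        by_cluster = cfg.get("m1_m2_ratio_by_cluster", {})
        m1_m2_ratio = by_cluster.get(cluster, by_cluster.get(str(cluster)))
    ratio_m = float(m1_m2_ratio if m1_m2_ratio is not None else cfg["m1_m2_ratio"])
    prod = cfg["production_shares"]
    act = cfg["activation_shares"]
    inh = cfg["inhibition_vs_natural"]

    c = []
    # -- quoted assumptions --------------------------------------------------
    c.append(RatioConstraint(
        "cancer_self_vs_mu1",
        lhs_params=("lam_C",), rhs_params=("lam_C_mu1",), rhs_steady=("mu1",),
        ratio=float(cfg["cancer_self_vs_mu1"])))
    c.append(RatioConstraint(
        "ifng_kill_vs_apoptosis",
        lhs_params=("del_C_Ig",), lhs_steady=("I_g",), rhs_params=("del_C",),
        ratio=float(cfg["ifng_kill_vs_apoptosis"])))
    c.append(RatioConstraint(
        "macrophage_activation_ratio",
        lhs_params=("lam_M_Ig",), lhs_steady=("I_g",),
        rhs_params=("lam_M_mu1",), rhs_steady=("mu1",),
        ratio=ratio_m))
    # -- remaining closure (our defaults, same style) ------------------------
    c.append(RatioConstraint(
        "tc_kill_vs_apoptosis",
        lhs_params=("del_C_Tc",), lhs_steady=("T_c",), rhs_params=("del_C",),
        ratio=float(cfg["tc_kill_vs_apoptosis"])))
    c.append(RatioConstraint(
        "mu2_vs_mu1_growth",
        lhs_params=("lam_C_mu2",), lhs_steady=("mu2",),
        rhs_params=("lam_C_mu1",), rhs_steady=("mu1",),
        ratio=float(cfg["mu2_vs_mu1_growth"])))
    # cytokine production shares
    for cyt, producers in (("mu1", ("T_h", "M", "C")),
                           ("mu2", ("T_h", "M", "C"))):
        ref = "M"
        for other in producers:
            if other == ref:
                continue
            c.append(RatioConstraint(
                f"{cyt}_share_{other}_vs_{ref}",
                lhs_params=(f"lam_{cyt}_{_suffix(other)}",), lhs_steady=(other,),
                rhs_params=(f"lam_{cyt}_{_suffix(ref)}",), rhs_steady=(ref,),
                ratio=_share_ratio(prod[cyt], other, ref)))
    c.append(RatioConstraint(
        "Ig_share_Th_vs_Tc",
        lhs_params=("lam_Ig_Th",), lhs_steady=("T_h",),
        rhs_params=("lam_Ig_Tc",), rhs_steady=("T_c",),
        ratio=_share_ratio(prod["I_g"], "T_h", "T_c")))
    for other in ("M", "D"):
        c.append(RatioConstraint(
            f"H_share_{other}_vs_N",
            lhs_params=(f"lam_H_{other}",), lhs_steady=(other,),
            rhs_params=("lam_H_N",), rhs_steady=("N",),
            ratio=_share_ratio(prod["H"], other, "N")))
    # activation splits
    c.append(RatioConstraint(
        "Th_activation_M_vs_D",
        lhs_params=("lam_Th_M",), lhs_steady=("M",),
        rhs_params=("lam_Th_D",), rhs_steady=("D",),
        ratio=_share_ratio(act["T_h"], "M", "D")))
    for other in ("T_h", "D"):
        c.append(RatioConstraint(
            f"Tc_activation_{_suffix(other)}_vs_M",
            lhs_params=(f"lam_Tc_{_suffix(other)}",), lhs_steady=(other,),
            rhs_params=("lam_Tc_M",), rhs_steady=("M",),
            ratio=_share_ratio(act["T_c"], other, "M")))
    c.append(RatioConstraint(
        "D_activation_C_vs_H",
        lhs_params=("lam_D_C",), lhs_steady=("C",),
        rhs_params=("lam_D_H",), rhs_steady=("H",),
        ratio=_share_ratio(act["D"], "C", "H")))
    # induced inhibition/death vs natural death
    for cname, pname, svar, nat in (
            ("Th_inhibition_by_Tr", "del_Th_Tr", "T_r", "del_Th"),
            ("Th_inhibition_by_mu1", "del_Th_mu1", "mu1", "del_Th"),
            ("Tc_inhibition_by_Tr", "del_Tc_Tr", "T_r", "del_Tc"),
            ("Tc_inhibition_by_mu1", "del_Tc_mu1", "mu1", "del_Tc"),
            ("D_death_by_C", "del_D_C", "C", "del_D")):
        key = cname.split("_by_")[0].split("_")[0] + "_" + cname.split("_by_")[1]
        c.append(RatioConstraint(
            cname,
            lhs_params=(pname,), lhs_steady=(svar,), rhs_params=(nat,),
            ratio=float(inh[key])))
    return AssumptionLedger(c)


def _suffix(var: str) -> str:
    # parameter-name suffix for a producing/activating variable
    return {"T_h": "Th", "T_c": "Tc", "T_r": "Tr"}.get(var, var)


def _equation_scales(p, x: np.ndarray) -> np.ndarray:
    """Per-equation reference flux (the outflux side) used to make steady-
    state residuals relative."""
    (M_N, M, T_N, T_h, T_r, T_c, D_N, D, C, N, I_g, mu1, mu2, H) = x
    m_act = p.lam_M_Ig * I_g + p.lam_M_mu1 * mu1
    th_act = p.lam_Th_M * M + p.lam_Th_D * D
    tc_act = p.lam_Tc_Th * T_h + p.lam_Tc_M * M + p.lam_Tc_D * D
    d_act = p.lam_D_C * C + p.lam_D_H * H
    c_death = p.del_C_Tc * T_c + p.del_C_Ig * I_g + p.del_C
    scales = np.array([
        (m_act + p.del_MN) * M_N,
        p.del_M * M,
        (th_act + p.lam_Tr_mu1 * mu1 + tc_act + p.del_TN) * T_N,
        (p.del_Th_Tr * T_r + p.del_Th_mu1 * mu1 + p.del_Th) * T_h,
        p.del_Tr * T_r,
        (p.del_Tc_Tr * T_r + p.del_Tc_mu1 * mu1 + p.del_Tc) * T_c,
        (d_act + p.del_DN) * D_N,
        (p.del_D_C * C + p.del_D) * D,
        c_death * C,
        p.del_N * N,
        p.del_Ig * I_g,
        p.del_mu1 * mu1,
        p.del_mu2 * mu2,
        p.del_H * H,
    ])
    return np.maximum(scales, 1e-300)


def steady_state_residual(params, steady: StateVector | np.ndarray,
                          ledger: AssumptionLedger) -> np.ndarray:
    """Scaled fixed-point residuals (14) followed by ledger residuals.

    The first 14 entries are dX/dt at ``steady`` divided per equation by
    its outflux, so they are relative; ledger entries are log-ratio
    residuals.  The vector length equals the number of unknown parameters
    of the default estimation problem (14 + number of constraints).
    """
    x = steady.values if isinstance(steady, StateVector) else np.asarray(steady, float)
    if np.any(x <= 0):
        bad = [VARIABLES[i] for i in np.flatnonzero(x <= 0)]
        raise ValueError(f"steady state must be strictly positive; offending: {bad}")
    eq = rhs_dimensional(x, params, check=False) / _equation_scales(params, x)
    return np.concatenate([eq, ledger.residuals(params, x)])


@dataclass
class FitResult:
    """A fitted parameter set with solve diagnostics."""

    params: ParameterSet
    residual: np.ndarray
    max_abs_residual: float
    n_restarts_used: int
    ledger: AssumptionLedger
    fixed: FixedRates

    def to_json(self) -> str:
        return json.dumps({
            "params": self.params.to_dict(),
            "max_abs_residual": self.max_abs_residual,
            "n_restarts_used": self.n_restarts_used,
            "ledger": self.ledger.to_records(),
            "fixed_rates": self.fixed.values,
            "fixed_rate_provenance": self.fixed.provenance,
        }, indent=1)


def _initial_guess(unknowns: Sequence[str], fixed: FixedRates,
                   x: np.ndarray) -> np.ndarray:
    """Balance each unknown rate against the dominant opposing flux of its
    equation, as if it alone carried that flux."""
    s = {name: x[index_of(name)] for name in VARIABLES}
    f = fixed.values
    guess: dict[str, float] = {}
    for cyt, dec in (("mu1", "del_mu1"), ("mu2", "del_mu2")):
        flux = f[dec] * s[cyt]
        for prod in ("T_h", "M", "C"):
            guess[f"lam_{cyt}_{_suffix(prod)}"] = flux / s[prod]
    for prod in ("T_h", "T_c"):
        guess[f"lam_Ig_{_suffix(prod)}"] = f["del_Ig"] * s["I_g"] / s[prod]
    for prod in ("M", "D", "N"):
        guess[f"lam_H_{prod}"] = f["del_H"] * s["H"] / s[prod]
    guess["lam_M_Ig"] = f["del_M"] * s["M"] / (s["I_g"] * s["M_N"])
    guess["lam_M_mu1"] = f["del_M"] * s["M"] / (s["mu1"] * s["M_N"])
    guess["lam_Th_M"] = f["del_Th"] * s["T_h"] / (s["M"] * s["T_N"])
    guess["lam_Th_D"] = f["del_Th"] * s["T_h"] / (s["D"] * s["T_N"])
    guess["lam_Tr_mu1"] = f["del_Tr"] * s["T_r"] / (s["mu1"] * s["T_N"])
    guess["lam_Tc_Th"] = f["del_Tc"] * s["T_c"] / (s["T_h"] * s["T_N"])
    guess["lam_Tc_M"] = f["del_Tc"] * s["T_c"] / (s["M"] * s["T_N"])
    guess["lam_Tc_D"] = f["del_Tc"] * s["T_c"] / (s["D"] * s["T_N"])
    guess["lam_D_C"] = f["del_D"] * s["D"] / (s["C"] * s["D_N"])
    guess["lam_D_H"] = f["del_D"] * s["D"] / (s["H"] * s["D_N"])
    guess["del_Th_Tr"] = f["del_Th"] / s["T_r"]
    guess["del_Th_mu1"] = f["del_Th"] / s["mu1"]
    guess["del_Tc_Tr"] = f["del_Tc"] / s["T_r"]
    guess["del_Tc_mu1"] = f["del_Tc"] / s["mu1"]
    guess["del_D_C"] = f["del_D"] / s["C"]
    guess["lam_C_mu1"] = f["lam_C"] / (40.0 * s["mu1"])
    guess["lam_C_mu2"] = f["lam_C"] / (40.0 * s["mu2"])
    guess["del_C_Tc"] = 10.0 * f["del_C"] / s["T_c"]
    guess["del_C_Ig"] = 10.0 * f["del_C"] / s["I_g"]
    guess["A_MN"] = f["del_MN"] * s["M_N"] + f["del_M"] * s["M"]
    guess["A_TN"] = (f["del_TN"] * s["T_N"] + f["del_Th"] * s["T_h"]
                     + f["del_Tr"] * s["T_r"] + f["del_Tc"] * s["T_c"])
    guess["A_DN"] = f["del_DN"] * s["D_N"] + f["del_D"] * s["D"]
    guess["C0"] = 2.0 * s["C"]
    guess["alpha_NC"] = min(0.9, f["del_N"] * s["N"] / (21.0 * f["del_C"] * s["C"]))
    return np.array([guess[name] for name in unknowns])


def fit_cluster_parameters(steady: StateVector | np.ndarray,
                           fixed: FixedRates | None = None,
                           ledger: AssumptionLedger | None = None,
                           seed: int = 0,
                           *,
                           cluster: int | None = None,
                           tol: float = 1e-9,
                           n_restarts: int = 3) -> FitResult:
    """Solve for all unknown rates of one cluster.

    The unknowns are every :class:`ParameterSet` field not pinned by
    ``fixed``; the equations are the 14 steady-state conditions plus the
    ledger constraints.  Solved with a quasi-Newton root finder in
    log-parameter space (positivity by construction), deterministically:
    the initial guess balances each rate against its equation's dominant
    opposing term, with up to ``n_restarts`` seeded jittered retries.
    """
    x = steady.values if isinstance(steady, StateVector) else np.asarray(steady, float)
    if np.any(x <= 0):
        bad = [VARIABLES[i] for i in np.flatnonzero(x <= 0)]
        raise ValueError(f"steady state must be strictly positive; offending: {bad}")
    if fixed is None:
        fixed = default_fixed_rates()
    if ledger is None:
        ledger = default_ledger(cluster=cluster)

    unknowns = [n for n in PARAMETER_NAMES if n not in fixed.values]
    n_eq = len(VARIABLES) + len(ledger)
    if len(unknowns) != n_eq:
        raise ValueError(
            f"estimation problem is not square: {len(unknowns)} unknowns vs "
            f"{n_eq} equations (14 steady-state + {len(ledger)} constraints)"
        )

    def assemble(u: np.ndarray) -> SimpleNamespace:
        ns = SimpleNamespace(**fixed.values)
        for name, v in zip(unknowns, u):
            setattr(ns, name, v)
        return ns

    def fun(logu: np.ndarray) -> np.ndarray:
        return steady_state_residual(assemble(np.exp(logu)), x, ledger)

    guess0 = _initial_guess(unknowns, fixed, x)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            g = guess0
        else:
            g = guess0 * np.exp(0.2 * rng.standard_normal(len(guess0)))
        sol = optimize.root(fun, np.log(g), method="hybr",
                            options={"xtol": 1e-13, "maxfev": 20000})
        res = fun(sol.x)
        m = float(np.max(np.abs(res)))
        if best is None or m < best[0]:
            best = (m, sol.x)
        if m < tol:
            params = ParameterSet.from_dict(
                {**fixed.values,
                 **dict(zip(unknowns, np.exp(sol.x)))})
            return FitResult(params=params, residual=res, max_abs_residual=m,
                             n_restarts_used=attempt, ledger=ledger, fixed=fixed)
    raise RuntimeError(
        f"parameter solve did not converge after {n_restarts} restarts; "
        f"best max|residual| = {best[0]:.3e}"
    )


def vary_assumptions(ledger: AssumptionLedger,
                     scales: Sequence[float]) -> list[AssumptionLedger]:
    """One ledger per (scalable assumption, scale) combination.

    Each returned ledger has exactly one assumption's scale multiplied by
    one entry of ``scales``; used by the robustness and global-sensitivity
    experiments.
    """
    for s in scales:
        if s <= 0:
            raise ValueError("assumption scales must be > 0")
    out = []
    for c in ledger:
        if not c.scalable:
            continue
        for s in scales:
            out.append(ledger.with_scale(c.name, float(s)))
    return out
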