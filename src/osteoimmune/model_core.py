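"""Tumor-immune interaction ODE system for osteosarcoma.

The model tracks ten cell populations and four cytokine groups in the
osteosarcoma microenvironment.  Mass-action kinetics couple naive-cell
activation, effector-cell action on the tumor, logistic cancer growth with
carrying capacity ``C0``, and necrosis.  Two fast interleukins (IL-12,
IL-23) are eliminated by a quasi-steady-state assumption: their effect is
absorbed into the activation rates of T cells by macrophages and dendritic
cells, and they are available only as a diagnostic readout.

State variables, in the canonical order used everywhere in this package::

    M_N   naive macrophages / monocytes          [cells]
    M     macrophages (M1 + M2)                  [cells]
    T_N   naive T cells                          [cells]
    T_h   helper T cells                         [cells]
    T_r   regulatory T cells                     [cells]
    T_c   cytotoxic cells (CD8+ T and NK)        [cells]
    D_N   naive dendritic cells                  [cells]
    D     activated dendritic cells              [cells]
    C     cancer cells                           [cells]
    N     necrotic cells                         [cells]
    I_g   IFN-gamma                              [expression units]
    mu1   TGF-beta / IL-4 / IL-10 / IL-13 group  [expression units]
    mu2   IL-6 / IL-17 group                     [expression units]
    H     HMGB1                                  [expression units]
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "VARIABLES",
    "CELL_VARIABLES",
    "CYTOKINE_VARIABLES",
    "StateVector",
    "ParameterSet",
    "PARAMETER_NAMES",
    "rhs_dimensional",
    "rhs_dimensionless",
    "quasi_steady_cytokines",
]

#: Canonical variable ordering; all arrays, tables and JSON files use it.
VARIABLES: tuple[str, ...] = (
    "M_N", "M", "T_N", "T_h", "T_r", "T_c", "D_N", "D", "C", "N",
    "I_g", "mu1", "mu2", "H",
)

CELL_VARIABLES: tuple[str, ...] = VARIABLES[:10]
CYTOKINE_VARIABLES: tuple[str, ...] = VARIABLES[10:]

_IDX = {name: i for i, name in enumerate(VARIABLES)}


def index_of(name: str) -> int:
    """Position of a variable in the canonical ordering."""
    return _IDX[name]


@dataclass
class StateVector:
    """A point in the 14-dimensional state space.

    ``values`` follows the canonical ordering of :data:`VARIABLES`.  The
    ``dimensionless`` flag records whether the entries are ratios to a
    reference steady state (equilibria map to all-ones) or dimensional
    (cells; expression units for cytokines).
    """

    values: np.ndarray
    dimensionless: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(VARIABLES),):
            raise ValueError(
                f"state must have {len(VARIABLES)} components, "
                f"got shape {self.values.shape}"
            )

    def __getitem__(self, name: str) -> float:
        return float(self.values[_IDX[name]])

    def replace(self, **updates: float) -> "StateVector":
        vals = self.values.copy()
        for name, v in updates.items():
            vals[_IDX[name]] = v
        return StateVector(vals, dimensionless=self.dimensionless)

    def to_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(VARIABLES, self.values)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float], dimensionless: bool = False) -> "StateVector":
        return cls(np.array([d[name] for name in VARIABLES], dtype=float),
                   dimensionless=dimensionless)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str, dimensionless: bool = False) -> "StateVector":
        return cls.from_dict(json.loads(s), dimensionless=dimensionless)


@dataclass
class ParameterSet:
    """All rate constants of the model.

    ``lam_*`` are proliferation/activation/production rates, ``del_*`` are
    inhibition/decay/death rates, ``A_*`` are constant naive-cell source
    terms, ``C0`` the cancer carrying capacity and ``alpha_NC`` the fraction
    of killed cancer cells that become necrotic.  The quasi-steady IL-12 /
    IL-23 proportionality constants are not parameters here: they are
    absorbed into ``lam_Th_M``, ``lam_Th_D``, ``lam_Tc_M`` and ``lam_Tc_D``.
    """

    # cytokine production [per day per cell]
    lam_mu1_Th: float = 0.0
    lam_mu1_M: float = 0.0
    lam_mu1_C: float = 0.0
    lam_mu2_Th: float = 0.0
    lam_mu2_M: float = 0.0
    lam_mu2_C: float = 0.0
    lam_Ig_Th: float = 0.0
    lam_Ig_Tc: float = 0.0
    lam_H_M: float = 0.0
    lam_H_D: float = 0.0
    lam_H_N: float = 0.0
    # cytokine decay [per day]
    del_mu1: float = 0.0
    del_mu2: float = 0.0
    del_Ig: float = 0.0
    del_H: float = 0.0
    # macrophage activation [per day per expression unit]
    lam_M_Ig: float = 0.0
    lam_M_mu1: float = 0.0
    # T-cell activation [per day per cell or per expression unit]
    lam_Th_M: float = 0.0
    lam_Th_D: float = 0.0
    lam_Tr_mu1: float = 0.0
    lam_Tc_Th: float = 0.0
    lam_Tc_M: float = 0.0
    lam_Tc_D: float = 0.0
    # dendritic-cell activation
    lam_D_C: float = 0.0
    lam_D_H: float = 0.0
    # inhibition / death rates
    del_Th_Tr: float = 0.0
    del_Th_mu1: float = 0.0
    del_Th: float = 0.0
    del_Tr: float = 0.0
    del_Tc_Tr: float = 0.0
    del_Tc_mu1: float = 0.0
    del_Tc: float = 0.0
    del_D_C: float = 0.0
    del_D: float = 0.0
    del_M: float = 0.0
    del_MN: float = 0.0
    del_TN: float = 0.0
    del_DN: float = 0.0
    del_N: float = 0.0
    del_C: float = 0.0
    del_C_Tc: float = 0.0
    del_C_Ig: float = 0.0
    # cancer growth [per day; per day per expression unit for cytokine terms]
    lam_C: float = 0.0
    lam_C_mu1: float = 0.0
    lam_C_mu2: float = 0.0
    # naive-cell sources [cells per day]
    A_MN: float = 0.0
    A_TN: float = 0.0
    A_DN: float = 0.0
    # carrying capacity [cells] and necrotic conversion fraction
    C0: float = 1.0
    alpha_NC: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if self.C0 <= 0:
            raise ValueError("carrying capacity C0 must be > 0")
        if self.alpha_NC > 1:
            raise ValueError("necrotic fraction alpha_NC must be <= 1")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **updates: float) -> "ParameterSet":
        d = self.to_dict()
        d.update(updates)
        return ParameterSet.from_dict(d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ParameterSet":
        return cls.from_dict(json.loads(s))


PARAMETER_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ParameterSet))


def _as_array(state: "StateVector | np.ndarray | Iterable[float]") -> np.ndarray:
    if isinstance(state, StateVector):
        return state.values
    return np.asarray(state, dtype=float)


def _check_state(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite components")
    if np.any(x < 0):
        bad = [VARIABLES[i] for i in np.flatnonzero(x < 0)]
        raise ValueError(
            f"state has negative components {bad}; "
            "this usually signals integrator overshoot"
        )


def rhs_dimensional(state, params: ParameterSet, *, check: bool = True) -> np.ndarray:
    """Time derivative dX/dt of the dimensional system.

    Pure function of its inputs: nothing is clamped here; keeping the
    trajectory non-negative is the integrator's concern.
    """
    x = _as_array(state)
    if check:
        _check_state(x)
    p = params
    (M_N, M, T_N, T_h, T_r, T_c, D_N, D, C, N, I_g, mu1, mu2, H) = x

    m_act = p.lam_M_Ig * I_g + p.lam_M_mu1 * mu1
    th_act = p.lam_Th_M * M + p.lam_Th_D * D
    tc_act = p.lam_Tc_Th * T_h + p.lam_Tc_M * M + p.lam_Tc_D * D
    d_act = p.lam_D_C * C + p.lam_D_H * H
    c_growth = p.lam_C + p.lam_C_mu1 * mu1 + p.lam_C_mu2 * mu2
    c_death = p.del_C_Tc * T_c + p.del_C_Ig * I_g + p.del_C

    dx = np.empty_like(x)
    dx[0] = p.A_MN - m_act * M_N - p.del_MN * M_N
    dx[1] = m_act * M_N - p.del_M * M
    dx[2] = (p.A_TN - th_act * T_N - p.lam_Tr_mu1 * mu1 * T_N
             - tc_act * T_N - p.del_TN * T_N)
    dx[3] = th_act * T_N - (p.del_Th_Tr * T_r + p.del_Th_mu1 * mu1 + p.del_Th) * T_h
    dx[4] = p.lam_Tr_mu1 * mu1 * T_N - p.del_Tr * T_r
    dx[5] = tc_act * T_N - (p.del_Tc_Tr * T_r + p.del_Tc_mu1 * mu1 + p.del_Tc) * T_c
    dx[6] = p.A_DN - d_act * D_N - p.del_DN * D_N
    dx[7] = d_act * D_N - (p.del_D_C * C + p.del_D) * D
    dx[8] = c_growth * C * (1.0 - C / p.C0) - c_death * C
    dx[9] = p.alpha_NC * c_death * C - p.del_N * N
    dx[10] = p.lam_Ig_Th * T_h + p.lam_Ig_Tc * T_c - p.del_Ig * I_g
    dx[11] = p.lam_mu1_Th * T_h + p.lam_mu1_M * M + p.lam_mu1_C * C - p.del_mu1 * mu1
    dx[12] = p.lam_mu2_Th * T_h + p.lam_mu2_M * M + p.lam_mu2_C * C - p.del_mu2 * mu2
    dx[13] = p.lam_H_M * M + p.lam_H_D * D + p.lam_H_N * N - p.del_H * H
    return dx


def rhs_dimensionless(state, params: ParameterSet, steady,
                      *, check: bool = True) -> np.ndarray:
    """Derivative of the rescaled system X̄ = X / X∞.

    Identically ``rhs_dimensional(X̄ · X∞) / X∞`` componentwise; equilibria
    of the dimensional system map to the all-ones state.
    """
    xbar = _as_array(state)
    xinf = _as_array(steady)
    if np.any(xinf <= 0):
        bad = [VARIABLES[i] for i in np.flatnonzero(xinf <= 0)]
        raise ValueError(
            f"non-dimensionalization requires strictly positive steady-state "
            f"components; offending variables: {bad}"
        )
    return rhs_dimensional(xbar * xinf, params, check=check) / xinf


def quasi_steady_cytokines(state, coeffs=(1.0, 1.0, 1.0, 1.0)) -> tuple[float, float]:
    """Quasi-steady IL-12 and IL-23 levels, ``(c1·M + c2·D, c3·M + c4·D)``.

    Diagnostic readout only.  These interleukins equilibrate fast and are
    proportional to their producers (M1 macrophages and dendritic cells);
    their effect on T-cell activation is already folded into the activation
    rates, so the proportionality constants are unidentifiable and fixed to
    1 by convention here.
    """
    c1, c2, c3, c4 = (float(c) for c in coeffs)
    if min(c1, c2, c3, c4) < 0:
        raise ValueError("quasi-steady coefficients must be non-negative")
    x = _as_array(state)
    M, D = x[_IDX["M"]], x[_IDX["D"]]
    return c1 * M + c2 * D, c3 * M + c4 * D
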