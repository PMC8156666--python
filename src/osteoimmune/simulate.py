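"""Trajectory integration, convergence detection and dynamics features.

Simulations are run on the dimensionless system (every variable rescaled
by its steady-state value) so that equilibria map to the all-ones state
and shape thresholds are scale-free; dimensional trajectories are obtained
by multiplying back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    VARIABLES,
    ParameterSet,
    StateVector,
    index_of,
    rhs_dimensional,
    rhs_dimensionless,
)

__all__ = [
    "Trajectory",
    "ConvergenceRecord",
    "DynamicsFeatures",
    "integrate",
    "integrate_to_convergence",
    "detect_convergence",
    "extract_features",
    "cross_cluster_experiment",
]

#: negative values from solver overshoot below this fraction of the
#: variable's scale are clamped to zero; anything larger is an error.
_NEGATIVITY_TOL = 1e-12


@dataclass
class ConvergenceRecord:
    converged: bool
    time: float | None
    criterion_value: float
    eps: float
    window: float


@dataclass
class Trajectory:
    """A simulated path of the system on a strictly increasing time grid."""

    t: np.ndarray
    states: np.ndarray  # (n_times, 14)
    dimensionless: bool
    cluster: int | None = None
    convergence: ConvergenceRecord | None = None
    steady: np.ndarray | None = None  # reference scale when dimensionless

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.states = np.asarray(self.states, float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.states.shape != (self.t.size, len(VARIABLES)):
            raise ValueError("state matrix must be (n_times, 14)")

    def variable(self, name: str) -> np.ndarray:
        return self.states[:, index_of(name)]

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def to_dimensional(self) -> "Trajectory":
        if not self.dimensionless:
            return self
        if self.steady is None:
            raise ValueError("no steady-state scale attached")
        return Trajectory(self.t, self.states * self.steady, dimensionless=False,
                          cluster=self.cluster, convergence=self.convergence,
                          steady=self.steady)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, variable, value, cluster) table."""
        n = self.t.size
        return pd.DataFrame({
            "time": np.repeat(self.t, len(VARIABLES)),
            "variable": np.tile(VARIABLES, n),
            "value": self.states.ravel(),
            "cluster": self.cluster if self.cluster is not None else -1,
        })


def _postprocess(t: np.ndarray, y: np.ndarray, atol: float) -> np.ndarray:
    """Clamp tiny negative overshoot (within the solver's error scale);
    reject anything material."""
    scale = np.maximum(np.max(np.abs(y), axis=0), 1.0)
    floor = -np.maximum(_NEGATIVITY_TOL * scale, 10.0 * atol)
    if np.any(y < floor[None, :]):
        worst = float(np.min(y / scale[None, :]))
        raise RuntimeError(
            f"integrator produced materially negative states "
            f"(min relative value {worst:.3e})"
        )
    return np.maximum(y, 0.0)


def integrate(params: ParameterSet,
              x0: StateVector | np.ndarray,
              horizon: float,
              steady: StateVector | np.ndarray | None = None,
              *,
              rtol: float = 1e-8,
              n_points: int = 2001,
              cluster: int | None = None) -> Trajectory:
    """Integrate the initial-value problem over ``[0, horizon]`` days.

    If ``steady`` is given, ``x0`` is interpreted and the trajectory is
    returned in dimensionless form (ratios to ``steady``); otherwise the
    dimensional system is integrated directly.  Deterministic; stiffness
    is handled by LSODA with one automatic retry at tighter tolerance.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    x0v = x0.values if isinstance(x0, StateVector) else np.asarray(x0, float)
    if np.any(x0v < 0) or not np.all(np.isfinite(x0v)):
        raise ValueError("initial state must be finite and non-negative")

    if steady is not None:
        sv = steady.values if isinstance(steady, StateVector) else np.asarray(steady, float)
        rhs = lambda t, y: rhs_dimensionless(y, params, sv, check=False)
        atol = rtol * 1e-4
    else:
        sv = None
        rhs = lambda t, y: rhs_dimensional(y, params, check=False)
        # per-component floors: cell counts and cytokine levels differ by
        # ten orders of magnitude on the dimensional scale
        scale = np.maximum(np.abs(x0v), 1e-9 * max(float(np.max(x0v)), 1.0))
        atol = rtol * 1e-4 * scale

    t_eval = np.linspace(0.0, horizon, n_points)
    for attempt, rt in enumerate((rtol, rtol * 1e-2)):
        sol = solve_ivp(rhs, (0.0, horizon), x0v, method="LSODA",
                        rtol=rt, atol=atol, t_eval=t_eval)
        if sol.success:
            break
    else:
        raise RuntimeError(f"integration failed: {sol.message}")
    y = _postprocess(sol.t, sol.y.T, float(np.max(atol)))
    return Trajectory(sol.t, y, dimensionless=steady is not None,
                      cluster=cluster, steady=sv)


def detect_convergence(traj: Trajectory, eps: float = 1e-3,
                       window: float = 200.0) -> ConvergenceRecord:
    """Earliest time after which the trajectory stays within ``eps``
    (relative) of its endpoint over at least ``window`` days."""
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    end = traj.endpoint
    floor = max(float(np.max(np.abs(end))), 1e-30) * 1e-9
    denom = np.maximum(np.abs(end), floor)
    dev = np.max(np.abs(traj.states - end) / denom, axis=1)
    within = dev < eps
    crit = float(np.max(dev[within])) if np.any(within) else float(np.min(dev))
    bad = np.flatnonzero(~within)
    # start of the trailing run during which the state stays near the endpoint
    t_run = float(traj.t[bad[-1] + 1]) if bad.size else float(traj.t[0])
    if bad.size and bad[-1] + 1 >= traj.t.size:
        return ConvergenceRecord(False, None, crit, eps, window)
    if traj.t[-1] - t_run >= window:
        return ConvergenceRecord(True, t_run + window, crit, eps, window)
    return ConvergenceRecord(False, None, crit, eps, window)


def integrate_to_convergence(params: ParameterSet,
                             x0: StateVector | np.ndarray,
                             steady: StateVector | np.ndarray | None = None,
                             *,
                             horizon: float = 5000.0,
                             max_horizon: float = 20000.0,
                             eps: float = 1e-3,
                             window: float = 200.0,
                             rtol: float = 1e-8,
                             cluster: int | None = None) -> Trajectory:
    """Integrate, extending the horizon (x2 each time) until the
    steady-state criterion is met or ``max_horizon`` is reached."""
    h = horizon
    while True:
        n_points = max(2001, int(h))  # ~1-day resolution for feature timing
        n_points = min(n_points, 20001)
        traj = integrate(params, x0, h, steady, rtol=rtol,
                         n_points=n_points, cluster=cluster)
        rec = detect_convergence(traj, eps=eps, window=window)
        traj.convergence = rec
        if rec.converged or h >= max_horizon:
            return traj
        h = min(2 * h, max_horizon)


Shape = Literal["increasing", "decreasing", "rise_then_fall", "fall_then_rise"]


@dataclass
class DynamicsFeatures:
    """Per-variable shape classification and timing features.

    ``t_peak``/``t_trough`` are times of the global extrema after the
    initial boundary layer; ``t_max_growth`` is the time at which cancer
    grows fastest.  ``shape`` classifies each variable as monotone or
    switching, using a relative-amplitude significance threshold.
    """

    shape: dict[str, Shape]
    t_peak: dict[str, float]
    t_trough: dict[str, float]
    amplitude: dict[str, float]
    t_max_growth: float
    steady_values: dict[str, float]
    provisional: bool = False
    threshold: float = 0.1
    burn_in: float = 0.0


def _trim_boundary_layer(t: np.ndarray, y: np.ndarray,
                         burn_in: float) -> np.ndarray:
    """Index mask dropping the initial relaxation transient.

    Keeps everything from the first local extremum on, provided that
    extremum occurs within ``burn_in``; otherwise drops only ``t <
    min(burn_in, time of first extremum)``.  Rationale: fast variables
    (cytokines, rapidly equilibrating pools) relax from their sampled
    initial values within days; that boundary layer is not part of the
    slow progression shape.
    """
    dy = np.diff(y)
    sign = np.sign(dy)
    nz = np.flatnonzero(sign != 0)
    t_ext = t[-1]
    if nz.size:
        flips = np.flatnonzero(np.diff(sign[nz]) != 0)
        if flips.size:
            t_ext = t[nz[flips[0]] + 1]
    start = min(burn_in, t_ext)
    return t >= start


def extract_features(traj: Trajectory, threshold: float = 0.1,
                     burn_in: float | None = None) -> DynamicsFeatures:
    """Classify every variable's trajectory shape and timing.

    An interior peak (trough) is significant when it exceeds the larger
    (undercuts the smaller) of the endpoint values by more than
    ``threshold`` times the variable's dynamic range after the initial
    transient.  When both a peak and a trough are significant the shape is
    decided by whichever extremum lies closer to the time of maximal
    cancer growth: the switch in the immune response is tied to the tumor
    surge, while an early extremum reflects relaxation from the sampled
    initial state.  ``burn_in`` (days) bounds the initial transient that
    is excluded from classification; default is 1% of the convergence
    time (or of the horizon when not converged).
    """
    rec = traj.convergence
    provisional = not (rec is not None and rec.converged)
    if burn_in is None:
        t_ref = rec.time if (rec is not None and rec.converged and rec.time) \
            else traj.t[-1]
        burn_in = 0.01 * float(t_ref)

    t = traj.t
    C = traj.variable("C")
    dC = np.gradient(C, t)
    t_max_growth = float(t[int(np.argmax(dC))])

    shape: dict[str, Shape] = {}
    t_peak: dict[str, float] = {}
    t_trough: dict[str, float] = {}
    amplitude: dict[str, float] = {}
    for name in VARIABLES:
        y = traj.variable(name)
        m = _trim_boundary_layer(t, y, burn_in)
        tt, yy = t[m], y[m]
        x0, xe = float(yy[0]), float(yy[-1])
        imax, imin = int(np.argmax(yy)), int(np.argmin(yy))
        ref = max(float(yy[imax] - yy[imin]), threshold * abs(xe), 1e-12)
        peak_amp = float(yy[imax] - max(x0, xe))
        trough_amp = float(min(x0, xe) - yy[imin])
        has_peak = peak_amp > threshold * ref
        has_trough = trough_amp > threshold * ref
        t_peak[name] = float(tt[imax])
        t_trough[name] = float(tt[imin])
        amplitude[name] = float(yy[imax] - yy[imin])
        if has_peak and has_trough:
            near_peak = abs(tt[imax] - t_max_growth) <= abs(tt[imin] - t_max_growth)
            shape[name] = "rise_then_fall" if near_peak else "fall_then_rise"
        elif has_peak:
            shape[name] = "rise_then_fall"
        elif has_trough:
            shape[name] = "fall_then_rise"
        else:
            # ties (constant trajectories) default to "increasing"
            shape[name] = "increasing" if xe >= x0 else "decreasing"
    steady_values = dict(zip(VARIABLES, (float(v) for v in traj.endpoint)))
    return DynamicsFeatures(shape=shape, t_peak=t_peak, t_trough=t_trough,
                            amplitude=amplitude, t_max_growth=t_max_growth,
                            steady_values=steady_values,
                            provisional=provisional, threshold=threshold,
                            burn_in=burn_in)


def cross_cluster_experiment(params_by_cluster: Mapping[int, ParameterSet],
                             x0_by_cluster: Mapping[int, StateVector | np.ndarray],
                             steadies: Mapping[int, StateVector | np.ndarray] | None = None,
                             **kwargs) -> dict[tuple[int, int], Trajectory]:
    """Integrate every (parameter cluster i, initial-condition cluster j)
    pair; used to show the attractor is set by the parameters, not the
    starting composition."""
    out: dict[tuple[int, int], Trajectory] = {}
    for i, params in params_by_cluster.items():
        steady = steadies[i] if steadies is not None else None
        for j, x0 in x0_by_cluster.items():
            traj = integrate_to_convergence(params, x0, steady,
                                            cluster=i, **kwargs)
            out[(i, j)] = traj
    return out
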