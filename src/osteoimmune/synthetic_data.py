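"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Real inputs are deconvolved immune fractions plus clinical composition
percentages and cytokine levels, with three immune clusters.  The
generators here emulate exactly that: Dirichlet compositions around
cluster-specific mean profiles (cluster 2 with the highest naive-
macrophage content, cluster 3 with near-equal naive and M2 macrophage
content), logistic-normal composition percentages renormalized to 100,
and log-normal cytokine levels.  Everything is deterministic given a
seed, so every pipeline stage is testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_prep import (
    CIBERSORT_CELL_TYPES,
    CYTOKINE_COLUMNS,
    IMMUNE_COMPARTMENTS,
    PCT_COLUMNS,
    validate_cohort,
)
from .config import load_default_config
from .model_core import StateVector

__all__ = [
    "ClusterProfile",
    "default_profiles",
    "generate_cohort",
    "generate_from_steady_state",
]


@dataclass
class ClusterProfile:
    """Distributional description of one immune cluster.

    ``mean_fractions`` is a valid composition over the 22 cell types;
    ``precision`` the Dirichlet concentration (larger = tighter around
    the mean); percentages are perturbed on the log scale with spread
    ``pct_spread`` and renormalized to sum 100; cytokines are log-normal
    around ``mean_cytokines`` with log-sd ``cytokine_spread``.
    """

    cluster: int
    mean_fractions: dict[str, float]
    precision: float = 200.0
    mean_pcts: dict[str, float] = field(default_factory=lambda: {
        "pct_normal": 1.5, "pct_stroma": 6.0,
        "pct_tumor": 90.0, "pct_necrotic": 2.5})
    pct_spread: float = 0.3
    mean_cytokines: dict[str, float] = field(default_factory=lambda: {
        "I_g": 0.4, "mu1": 22.0, "mu2": 1.7, "H": 4.8})
    cytokine_spread: float = 0.2
    n_samples: int = 30

    def __post_init__(self) -> None:
        vals = np.array([self.mean_fractions[t] for t in CIBERSORT_CELL_TYPES])
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(
                "mean_fractions must be a composition over the 22 cell types")
        if self.precision <= 0:
            raise ValueError("Dirichlet precision must be > 0")


def _base_fraction_template() -> dict[str, float]:
    # unmapped mass (B cells, plasma, gamma-delta, mast, granulocytes)
    return {
        "B cells naive": 0.02, "B cells memory": 0.01, "Plasma cells": 0.02,
        "T cells gamma delta": 0.01, "Mast cells resting": 0.02,
        "Mast cells activated": 0.005, "Eosinophils": 0.005,
        "Neutrophils": 0.02,
    }


def default_profiles() -> dict[int, ClusterProfile]:
    """Three cluster profiles encoding the cohort's composition pattern.

    Cluster 2 has the strictly highest naive-macrophage (M0 + monocyte)
    mean; cluster 3 has near-equal naive-macrophage and M2 content
    (within 10%); M2 macrophages dominate M1 everywhere, least so in
    cluster 3.  Cytokine means follow the cluster steady-state pattern
    (cluster 1 highest IFN-gamma).
    """
    pattern = {
        # mapped-compartment means per cluster:
        #          M0+Mono  M1     M2    TN     Th     Tr     Tc     DN     D
        1: dict(MN=0.115, M1=0.075, M2=0.30, TN=0.095, Th=0.135, Tr=0.07,
                Tc=0.13, DN=0.009, D=0.016),
        2: dict(MN=0.42, M1=0.024, M2=0.24, TN=0.13, Th=0.025, Tr=0.011,
                Tc=0.004, DN=0.011, D=0.009),
        3: dict(MN=0.33, M1=0.155, M2=0.31, TN=0.09, Th=0.008, Tr=0.009,
                Tc=0.012, DN=0.0035, D=0.0025),
    }
    cytokines = {
        1: {"I_g": 0.87, "mu1": 21.5, "mu2": 2.07, "H": 5.08},
        2: {"I_g": 0.05, "mu1": 20.7, "mu2": 1.61, "H": 4.95},
        3: {"I_g": 0.26, "mu1": 23.7, "mu2": 1.37, "H": 4.45},
    }
    profiles = {}
    for k, s in pattern.items():
        f = {t: 0.0 for t in CIBERSORT_CELL_TYPES}
        f.update(_base_fraction_template())
        f["Macrophages M0"] = 0.7 * s["MN"]
        f["Monocytes"] = 0.3 * s["MN"]
        f["Macrophages M1"] = s["M1"]
        f["Macrophages M2"] = s["M2"]
        f["T cells CD4 naive"] = s["TN"]
        f["T cells CD4 memory resting"] = 0.6 * s["Th"]
        f["T cells CD4 memory activated"] = 0.25 * s["Th"]
        f["T cells follicular helper"] = 0.15 * s["Th"]
        f["T cells regulatory (Tregs)"] = s["Tr"]
        f["T cells CD8"] = 0.7 * s["Tc"]
        f["NK cells resting"] = 0.2 * s["Tc"]
        f["NK cells activated"] = 0.1 * s["Tc"]
        f["Dendritic cells resting"] = s["DN"]
        f["Dendritic cells activated"] = s["D"]
        total = sum(f.values())
        f = {t: v / total for t, v in f.items()}
        profiles[k] = ClusterProfile(cluster=k, mean_fractions=f,
                                     mean_cytokines=cytokines[k])
    return profiles


def _sample_percentages(rng: np.random.Generator, means: Mapping[str, float],
                        spread: float, n: int) -> np.ndarray:
    mu = np.array([means[c] for c in PCT_COLUMNS], float)
    z = rng.normal(0.0, spread, size=(n, len(PCT_COLUMNS)))
    raw = mu[None, :] * np.exp(z)
    return 100.0 * raw / raw.sum(axis=1, keepdims=True)


def generate_cohort(profiles: Mapping[int, ClusterProfile] | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Draw a full synthetic cohort table, one block per cluster."""
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    blocks = []
    for k in sorted(profiles):
        p = profiles[k]
        mean = np.array([p.mean_fractions[t] for t in CIBERSORT_CELL_TYPES])
        alpha = np.maximum(p.precision * mean, 1e-8)
        fracs = rng.dirichlet(alpha, size=p.n_samples)
        pcts = _sample_percentages(rng, p.mean_pcts, p.pct_spread, p.n_samples)
        cyt_mu = np.array([p.mean_cytokines[c] for c in CYTOKINE_COLUMNS])
        spread = p.cytokine_spread
        cyts = cyt_mu[None, :] * np.exp(
            rng.normal(-0.5 * spread ** 2, spread,
                       size=(p.n_samples, len(CYTOKINE_COLUMNS))))
        df = pd.DataFrame(fracs, columns=list(CIBERSORT_CELL_TYPES))
        df.insert(0, "sample_id", [f"SYN-{k}-{i:03d}" for i in range(p.n_samples)])
        for j, c in enumerate(PCT_COLUMNS):
            df[c] = pcts[:, j]
        for j, c in enumerate(CYTOKINE_COLUMNS):
            df[c] = cyts[:, j]
        df["cluster"] = k
        blocks.append(df)
    return validate_cohort(pd.concat(blocks, ignore_index=True))


def generate_from_steady_state(steady: StateVector, n: int = 60,
                               dispersion: float = 0.05, seed: int = 0,
                               alpha_dim: float | None = None,
                               cluster: int = 1,
                               percentile: float = 85.0,
                               m1_m2: float = 0.25,
                               pct_stroma: float = 5.0) -> pd.DataFrame:
    """A cohort whose large-tumor tail averages to a known steady state.

    The samples above the ``percentile`` cancer cutoff are drawn with
    componentwise mean equal to ``steady`` (log-normal noise with
    mean-correction; ``dispersion`` is the log-sd, 0 = exact); the
    remaining samples are shrunken copies whose cancer counts stay
    strictly below the cutoff.  Closing the loop: running the steady-
    state extraction on the result recovers ``steady`` within Monte-Carlo
    error.  ``dispersion`` must stay below ~0.15 so the tail is separated.
    """
    if np.any(steady.values <= 0):
        raise ValueError("steady state must be strictly positive")
    if not 0 <= dispersion < 0.15:
        raise ValueError("dispersion must be in [0, 0.15)")
    if alpha_dim is None:
        alpha_dim = float(load_default_config()["alpha_dim"])
    rng = np.random.default_rng(seed)
    # sized so the percentile cutoff interpolates strictly below the tail
    n_tail = max(1, int(np.floor(n * (1.0 - percentile / 100.0))))
    rows = []
    for i in range(n):
        in_tail = i < n_tail
        noise = np.exp(rng.normal(-0.5 * dispersion ** 2, dispersion,
                                  size=len(steady.values))) \
            if dispersion > 0 else np.ones(len(steady.values))
        x = steady.values * noise
        if not in_tail:
            # bulk: smaller tumors, safely below the tail's cancer range
            x = x * rng.uniform(0.25, 0.6)
        rows.append(_state_to_sample(x, alpha_dim, f"SYN-SS-{i:03d}",
                                     cluster, m1_m2, pct_stroma))
    return validate_cohort(pd.DataFrame(rows))


def _state_to_sample(x: np.ndarray, alpha_dim: float, sample_id: str,
                     cluster: int, m1_m2: float, pct_stroma: float) -> dict:
    """Invert the population derivation: state vector -> cohort row."""
    s = StateVector(x)
    frac = {t: 0.0 for t in CIBERSORT_CELL_TYPES}
    comp = {c: s[c] / alpha_dim for c in IMMUNE_COMPARTMENTS}
    mapped_total = sum(comp.values())
    if mapped_total >= 1.0:
        raise ValueError(
            "immune populations exceed alpha_dim; increase the scale factor")
    frac["Macrophages M0"] = 0.7 * comp["M_N"]
    frac["Monocytes"] = 0.3 * comp["M_N"]
    w1 = m1_m2 / (1.0 + m1_m2)
    frac["Macrophages M1"] = w1 * comp["M"]
    frac["Macrophages M2"] = (1.0 - w1) * comp["M"]
    frac["T cells CD4 naive"] = comp["T_N"]
    frac["T cells CD4 memory resting"] = 0.6 * comp["T_h"]
    frac["T cells CD4 memory activated"] = 0.25 * comp["T_h"]
    frac["T cells follicular helper"] = 0.15 * comp["T_h"]
    frac["T cells regulatory (Tregs)"] = comp["T_r"]
    frac["T cells CD8"] = 0.7 * comp["T_c"]
    frac["NK cells resting"] = 0.2 * comp["T_c"]
    frac["NK cells activated"] = 0.1 * comp["T_c"]
    frac["Dendritic cells resting"] = comp["D_N"]
    frac["Dendritic cells activated"] = comp["D"]
    frac["Neutrophils"] = 1.0 - mapped_total  # leftover, unmapped type
    # composition percentages consistent with C = I * pct_tumor/pct_normal
    w = np.array([1.0, s["C"] / alpha_dim, s["N"] / alpha_dim])
    pct = (100.0 - pct_stroma) * w / w.sum()
    row = {"sample_id": sample_id, **frac,
           "pct_normal": pct[0], "pct_stroma": pct_stroma,
           "pct_tumor": pct[1], "pct_necrotic": pct[2],
           "I_g": s["I_g"], "mu1": s["mu1"], "mu2": s["mu2"], "H": s["H"],
           "cluster": cluster}
    return row
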