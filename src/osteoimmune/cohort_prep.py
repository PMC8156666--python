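"""From deconvolved compositions to absolute populations and steady states.

Bulk-tumor deconvolution yields *relative* immune-cell fractions per
sample (22 canonical cell types).  The model needs absolute cell counts,
so the pipeline (i) aggregates the 22 types onto the 8 immune model
compartments, (ii) scales fractions to counts with a single factor
``alpha_dim`` anchored to a geometric estimate of the cell content of an
average tumor, (iii) derives cancer and necrotic counts from the clinical
composition percentages, and (iv) extracts a per-cluster steady state as
the average over the largest tumors (above a cancer-abundance percentile).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import load_default_config
from .model_core import StateVector, VARIABLES

__all__ = [
    "CIBERSORT_CELL_TYPES",
    "IMMUNE_COMPARTMENTS",
    "GeometryConfig",
    "aggregate_model_cells",
    "fractions_to_populations",
    "geometric_cell_count",
    "calibrate_alpha_dim",
    "cluster_steady_state",
    "m1_m2_ratio",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_cohort",
]

#: The 22 deconvolution cell types (LM22 signature naming).
CIBERSORT_CELL_TYPES: tuple[str, ...] = (
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive",
    "T cells CD4 memory resting", "T cells CD4 memory activated",
    "T cells follicular helper", "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting", "NK cells activated",
    "Monocytes", "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
)

IMMUNE_COMPARTMENTS: tuple[str, ...] = (
    "M_N", "M", "T_N", "T_h", "T_r", "T_c", "D_N", "D")

PCT_COLUMNS = ("pct_normal", "pct_stroma", "pct_tumor", "pct_necrotic")
CYTOKINE_COLUMNS = ("I_g", "mu1", "mu2", "H")


@dataclass(frozen=True)
class GeometryConfig:
    """Average tumor volume [mL] and cell diameter [micrometers]."""

    tumor_volume_ml: float = 275.0
    cell_diameter_um: float = 35.0

    def __post_init__(self) -> None:
        if self.tumor_volume_ml <= 0 or self.cell_diameter_um <= 0:
            raise ValueError("geometry values must be strictly positive")

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any]) -> "GeometryConfig":
        g = cfg["geometry"]
        return cls(float(g["tumor_volume_ml"]), float(g["cell_diameter_um"]))


def default_mapping() -> dict[str, list[str]]:
    return {k: list(v) for k, v in
            load_default_config()["cell_type_mapping"].items()}


def aggregate_model_cells(fractions: Mapping[str, float],
                          mapping: Mapping[str, Sequence[str]] | None = None,
                          strict: bool = False) -> tuple[dict[str, float], float]:
    """Sum the 22 deconvolution fractions onto the 8 model compartments.

    Returns ``(compartment fractions, dropped mass)`` where the dropped
    mass is the total fraction carried by unmapped cell types (B cells,
    plasma cells, mast cells, granulocytes, ...).  With ``strict=True`` a
    fraction name absent from both the mapping and the canonical type
    list is an error.
    """
    mapping = dict(mapping) if mapping is not None else default_mapping()
    by_type: dict[str, str] = {}
    for comp, types in mapping.items():
        if comp not in IMMUNE_COMPARTMENTS:
            raise ValueError(f"unknown model compartment {comp!r} in mapping")
        for t in types:
            by_type[t] = comp
    out = {c: 0.0 for c in IMMUNE_COMPARTMENTS}
    dropped = 0.0
    for name, frac in fractions.items():
        f = float(frac)
        if f < 0:
            raise ValueError(f"negative fraction for {name!r}")
        comp = by_type.get(name)
        if comp is not None:
            out[comp] += f
        else:
            if strict and name not in CIBERSORT_CELL_TYPES:
                raise ValueError(f"unknown cell type {name!r} (strict mapping)")
            dropped += f
    return out, dropped


def fractions_to_populations(sample: Mapping[str, float], alpha_dim: float,
                             mapping: Mapping[str, Sequence[str]] | None = None
                             ) -> StateVector:
    """Convert one cohort row to a dimensional state (cell counts).

    The total immune population is ``I = alpha_dim`` (fractions sum to 1),
    and the cancer / necrotic counts follow from the clinical composition:
    ``C = I * pct_tumor / pct_normal`` and ``N = I * pct_necrotic /
    pct_normal``, equating the normal-cell percentage with the total
    immune percentage.  Cytokine levels are carried over unscaled.
    """
    if alpha_dim <= 0:
        raise ValueError("alpha_dim must be > 0")
    pn = float(sample["pct_normal"])
    if pn <= 0:
        raise ValueError("sample unusable: pct_normal must be > 0")
    fracs = {name: sample[name] for name in CIBERSORT_CELL_TYPES if name in sample}
    agg, _ = aggregate_model_cells(fracs, mapping)
    values = {c: agg[c] * alpha_dim for c in IMMUNE_COMPARTMENTS}
    values["C"] = alpha_dim * float(sample["pct_tumor"]) / pn
    values["N"] = alpha_dim * float(sample["pct_necrotic"]) / pn
    for c in CYTOKINE_COLUMNS:
        values[c] = float(sample[c])
    return StateVector.from_dict(values)


def geometric_cell_count(geom: GeometryConfig) -> float:
    """Cell count of an average tumor from its volume and cell diameter.

    Cubic-packing reconstruction: volume (in cubic micrometers) divided by
    the cube of the cell diameter.  For 275 mL and 35 um this gives
    ~6.4e9 cells.
    """
    volume_um3 = geom.tumor_volume_ml * 1e12  # 1 mL = 1e12 um^3
    return volume_um3 / geom.cell_diameter_um ** 3


def calibrate_alpha_dim(cohort: pd.DataFrame, target_count: float) -> float:
    """Scale factor making the cohort-average cancer count hit the target.

    ``C`` is linear in ``alpha_dim``, so the closed form
    ``alpha = target / mean(pct_tumor / pct_normal)`` is exact.  Samples
    with ``pct_normal <= 0`` are unusable and skipped.
    """
    usable = cohort[cohort["pct_normal"] > 0]
    if usable.empty:
        raise ValueError("no usable samples (all have pct_normal <= 0)")
    ratio = (usable["pct_tumor"] / usable["pct_normal"]).mean()
    if ratio <= 0:
        raise ValueError("cohort has zero mean tumor/normal ratio")
    return float(target_count / ratio)


def cluster_steady_state(cluster_samples: pd.DataFrame, alpha_dim: float,
                         percentile: float = 85.0,
                         mapping: Mapping[str, Sequence[str]] | None = None
                         ) -> StateVector:
    """Steady state of a cluster: mean state over its largest tumors.

    The cutoff is the given percentile (linear interpolation) of the
    cluster's cancer-count distribution; the average runs over samples
    with *strictly more* cancer cells than the cutoff.  Cytokine levels
    are averaged over the same tail on their own expression scale.
    """
    if len(cluster_samples) < 2:
        raise ValueError("need at least 2 samples to extract a steady state")
    pops = [fractions_to_populations(row, alpha_dim, mapping)
            for _, row in cluster_samples.iterrows()]
    counts = np.array([p["C"] for p in pops])
    cutoff = float(np.percentile(counts, percentile))
    tail = [p for p, c in zip(pops, counts) if c > cutoff]
    if not tail and percentile < 100 and np.isclose(cutoff, counts.max()):
        # ties at the top (e.g. identical samples): deterministic fallback
        tail = [p for p, c in zip(pops, counts)
                if np.isclose(c, counts.max(), rtol=1e-12)]
    if not tail:
        raise ValueError(
            f"no sample above the {percentile}th-percentile cancer cutoff "
            f"({cutoff:.3g}); cannot extract a steady state")
    mean = np.mean([p.values for p in tail], axis=0)
    return StateVector(mean)


def m1_m2_ratio(samples: pd.DataFrame) -> float:
    """Mean M1 fraction over mean M2 fraction, used by the macrophage
    activation-split assumption."""
    m1 = samples["Macrophages M1"].mean()
    m2 = samples["Macrophages M2"].mean()
    if m2 <= 0:
        raise ValueError("cohort has zero mean M2 fraction")
    return float(m1 / m2)


# ---------------------------------------------------------------------------
# CSV schema

def validate_cohort(df: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Check the cohort table invariants; returns the frame unchanged."""
    required = (["sample_id"] + list(CIBERSORT_CELL_TYPES)
                + list(PCT_COLUMNS) + list(CYTOKINE_COLUMNS) + ["cluster"])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    frac = df[list(CIBERSORT_CELL_TYPES)].to_numpy()
    if np.any(frac < 0):
        raise ValueError("negative immune fractions")
    bad = np.abs(frac.sum(axis=1) - 1.0) > atol
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} sample(s) have immune fractions not summing to 1")
    pct = df[list(PCT_COLUMNS)].to_numpy()
    if np.any((pct < 0) | (pct > 100)):
        raise ValueError("composition percentages must lie in [0, 100]")
    if not df["cluster"].isin([1, 2, 3]).all():
        raise ValueError("cluster labels must be in {1, 2, 3}")
    return df


def read_cohort_csv(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    validate_cohort(df).to_csv(path, index=False)
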