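"""Fraction aggregation, population scaling, geometry, steady-state extraction."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from osteoimmune.cohort_prep import (
    CIBERSORT_CELL_TYPES,
    IMMUNE_COMPARTMENTS,
    GeometryConfig,
    aggregate_model_cells,
    calibrate_alpha_dim,
    cluster_steady_state,
    fractions_to_populations,
    geometric_cell_count,
    m1_m2_ratio,
    read_cohort_csv,
    write_cohort_csv,
)
from osteoimmune.model_core import VARIABLES
from osteoimmune.synthetic_data import generate_cohort, generate_from_steady_state


def _zero_fractions():
    return {t: 0.0 for t in CIBERSORT_CELL_TYPES}


def test_macrophage_aggregation_is_additive():
    f = _zero_fractions()
    f["Macrophages M1"] = 0.1
    f["Macrophages M2"] = 0.2
    f["B cells naive"] = 0.7
    agg, dropped = aggregate_model_cells(f)
    assert agg["M"] == pytest.approx(0.3)
    assert dropped == pytest.approx(0.7)


def test_fully_unmapped_mass_is_reported():
    f = _zero_fractions()
    f["Neutrophils"] = 1.0
    agg, dropped = aggregate_model_cells(f)
    assert all(v == 0.0 for v in agg.values())
    assert dropped == pytest.approx(1.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_aggregation_conserves_mapped_mass(seed):
    rng = np.random.default_rng(seed)
    vals = rng.dirichlet(np.ones(len(CIBERSORT_CELL_TYPES)))
    f = dict(zip(CIBERSORT_CELL_TYPES, vals))
    agg, dropped = aggregate_model_cells(f)
    assert sum(agg.values()) + dropped == pytest.approx(1.0, abs=1e-12)


def test_unknown_type_rejected_when_strict():
    f = _zero_fractions()
    f["Made-up cells"] = 1.0
    with pytest.raises(ValueError, match="unknown cell type"):
        aggregate_model_cells(f, strict=True)


def _sample(pct_tumor, pct_normal, pct_necrotic, fractions=None):
    row = fractions if fractions is not None else _zero_fractions()
    row = dict(row)
    row.update(pct_normal=pct_normal, pct_stroma=0.0, pct_tumor=pct_tumor,
               pct_necrotic=pct_necrotic, I_g=1.0, mu1=1.0, mu2=1.0, H=1.0)
    return row


def test_cancer_count_from_composition_ratio():
    # total immune population 10 with 50% tumor and 10% immune -> 50 cancer cells
    sv = fractions_to_populations(_sample(50.0, 10.0, 0.0), alpha_dim=10.0)
    assert sv["C"] == pytest.approx(50.0)
    assert sv["N"] == 0.0


def test_cancer_to_necrotic_ratio_matches_percentages():
    rng = np.random.default_rng(5)
    for _ in range(20):
        pt, pn, pnec = rng.uniform(1, 90, size=3)
        sv = fractions_to_populations(_sample(pt, pn, pnec), alpha_dim=1e8)
        assert sv["C"] / sv["N"] == pytest.approx(pt / pnec)


def test_zero_normal_percentage_is_unusable():
    with pytest.raises(ValueError, match="pct_normal"):
        fractions_to_populations(_sample(50.0, 0.0, 1.0), alpha_dim=1.0)


def test_alpha_dim_is_a_pure_scale():
    f = _zero_fractions()
    f["Macrophages M2"] = 0.4
    f["T cells CD8"] = 0.6
    a = fractions_to_populations(_sample(30.0, 10.0, 5.0, f), alpha_dim=1e8)
    b = fractions_to_populations(_sample(30.0, 10.0, 5.0, f), alpha_dim=3e8)
    cells = slice(0, 10)
    np.testing.assert_allclose(b.values[cells], 3.0 * a.values[cells], rtol=1e-12)
    np.testing.assert_allclose(b.values[10:], a.values[10:])  # cytokines unscaled


@pytest.mark.parametrize("vol,diam,expected,sig", [
    (275.0, 35.0, 6.4e9, 2),
    (1.0, 100.0, 1.0e6, 6),  # 1e12 um^3 / 1e6 um^3 per cell
])
def test_geometric_cell_count(vol, diam, expected, sig):
    got = geometric_cell_count(GeometryConfig(vol, diam))
    assert got == pytest.approx(expected, rel=0.5 * 10 ** (1 - sig))


def test_doubling_diameter_divides_count_by_eight():
    a = geometric_cell_count(GeometryConfig(275.0, 35.0))
    b = geometric_cell_count(GeometryConfig(275.0, 70.0))
    assert a / b == pytest.approx(8.0, rel=1e-12)


def test_alpha_calibration_closed_form_and_round_trip():
    df = pd.DataFrame([_sample(64.0, 1.0, 0.0)])
    assert calibrate_alpha_dim(df, 6.4e9) == pytest.approx(1e8)

    cohort = generate_cohort(seed=11)
    alpha = calibrate_alpha_dim(cohort, 6.4e9)
    counts = [fractions_to_populations(row, alpha)["C"]
              for _, row in cohort.iterrows()]
    assert np.mean(counts) == pytest.approx(6.4e9, rel=1e-9)
    assert calibrate_alpha_dim(cohort, 2 * 6.4e9) == pytest.approx(2 * alpha)


def test_identical_samples_give_their_common_state():
    steady = np.array([6.2e6, 2.0e7, 4.9e6, 7.1e6, 3.7e6, 2.3e7, 4.8e5, 9.9e5,
                       1.3e10, 3.8e8, 0.87, 21.5, 2.07, 5.08])
    from osteoimmune.model_core import StateVector
    one = generate_from_steady_state(StateVector(steady), n=2, dispersion=0.0,
                                     seed=0).iloc[[0]]
    df = pd.concat([one] * 7, ignore_index=True)
    for pct in (50.0, 85.0, 99.0):
        got = cluster_steady_state(df, alpha_dim=1.765e8, percentile=pct)
        np.testing.assert_allclose(got.values, steady, rtol=1e-9)


def test_percentile_cutoff_matches_enumeration():
    """Toy cluster with cancer counts 1..20: compare against brute force."""
    from osteoimmune.model_core import StateVector
    alpha = 100.0
    rows = []
    for i, c in enumerate(range(1, 21)):
        f = _zero_fractions()
        f["Macrophages M2"] = 1.0
        row = _sample(float(c), 100.0, 1.0, f)  # C = alpha * c / 100
        row["sample_id"] = i
        rows.append(row)
    df = pd.DataFrame(rows)
    got = cluster_steady_state(df, alpha_dim=alpha, percentile=85.0)
    counts = alpha * np.arange(1, 21) / 100.0
    cutoff = np.percentile(counts, 85.0)  # brute-force oracle
    tail = counts[counts > cutoff]
    assert got["C"] == pytest.approx(tail.mean())
    assert got["M"] == pytest.approx(alpha)


def test_no_sample_above_cutoff_is_rejected():
    from osteoimmune.model_core import StateVector
    steady = np.ones(14) * 1e6
    df = generate_from_steady_state(StateVector(steady), n=5, dispersion=0.0,
                                    seed=0)
    with pytest.raises(ValueError, match="cutoff"):
        cluster_steady_state(df, alpha_dim=1.765e8, percentile=100.0)


def test_cohort_csv_round_trip(tmp_path):
    df = generate_cohort(seed=2)
    path = tmp_path / "cohort.csv"
    write_cohort_csv(df, path)
    back = read_cohort_csv(path)
    assert back.shape == df.shape
    np.testing.assert_allclose(
        back[list(CIBERSORT_CELL_TYPES)].to_numpy(),
        df[list(CIBERSORT_CELL_TYPES)].to_numpy(), rtol=1e-12)


def test_m1_m2_ratio_from_cohort():
    df = generate_cohort(seed=4)
    for k, lo, hi in ((1, 0.15, 0.4), (2, 0.05, 0.2), (3, 0.3, 0.7)):
        r = m1_m2_ratio(df[df.cluster == k])
        assert lo < r < hi, f"cluster {k} M1/M2 ratio {r:.3f}"
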