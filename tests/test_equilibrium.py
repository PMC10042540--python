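"""Equilibrium-competition arithmetic and the exact mass-action oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covnuc.equilibrium import (
    CompetitionAssay,
    InfeasibleAssayError,
    SpeciesConcentrations,
    equilibrium_species,
    estimate_affinity,
    exact_competition_oracle,
    kd_from_relative,
    relative_association,
    solve_competitive_equilibrium,
    total_gdp_from_t0,
)


@pytest.mark.parametrize(
    "pct_gdp, pct_analogue, total, expected",
    [
        (37.0, 63.0, 50.0, 29.4),  # pda assay
        (43.0, 57.0, 50.0, 37.7),  # bda assay
        (50.0, 50.0, 50.0, 50.0),  # equal split identity
    ],
)
def test_total_gdp_from_t0(pct_gdp, pct_analogue, total, expected):
    assert total_gdp_from_t0(pct_gdp, pct_analogue, total) == pytest.approx(
        expected, abs=0.05
    )


def test_total_gdp_zero_analogue_percentage_is_an_error():
    with pytest.raises(ZeroDivisionError, match="assay"):
        total_gdp_from_t0(100.0, 0.0, 50.0)


@pytest.mark.parametrize(
    "gdp_total, eq_analogue, eq_gdp, analogue_total, expected",
    [
        (29.4, 47.0, 53.0, 50.0, (13.8, 15.6, 36.2, 13.8)),
        (37.7, 39.5, 60.5, 50.0, (14.9, 22.8, 35.1, 14.9)),
        (30.0, 0.0, 100.0, 50.0, (0.0, 30.0, 50.0, 0.0)),
    ],
)
def test_equilibrium_species_worked_examples(
    gdp_total, eq_analogue, eq_gdp, analogue_total, expected
):
    sp = equilibrium_species(gdp_total, eq_analogue, eq_gdp, analogue_total)
    ba, bg, fa, fg = expected
    assert sp.bound_analogue == pytest.approx(ba, abs=0.05)
    assert sp.bound_gdp == pytest.approx(bg, abs=0.05)
    assert sp.free_analogue == pytest.approx(fa, abs=0.05)
    assert sp.free_gdp == pytest.approx(fg, abs=0.05)


def test_equilibrium_species_negative_free_is_infeasible():
    # bound analogue would exceed the analogue total
    with pytest.raises(InfeasibleAssayError):
        equilibrium_species(200.0, 40.0, 60.0, 50.0)


@pytest.mark.parametrize(
    "species, expected",
    [
        (SpeciesConcentrations(29.4, 15.582, 13.818, 13.818, 36.182), 0.34),
        (SpeciesConcentrations(37.7, 22.8085, 14.8915, 14.8915, 35.1085), 0.28),
        (SpeciesConcentrations(20.0, 5.0, 5.0, 5.0, 5.0), 1.0),
    ],
)
def test_relative_association_worked_examples(species, expected):
    assert relative_association(species) == pytest.approx(expected, abs=0.005)


def test_relative_association_zero_term_is_undefined():
    sp = SpeciesConcentrations(10.0, 5.0, 0.0, 5.0, 5.0)
    with pytest.raises(ZeroDivisionError):
        relative_association(sp)


@given(
    st.floats(min_value=0.01, max_value=100.0),
    st.floats(min_value=0.5, max_value=2.0),
)
@settings(deadline=None)
def test_relative_association_scale_invariant(base, scale):
    sp = SpeciesConcentrations(2 * base, base, 0.7 * base, 0.3 * base, 1.3 * base)
    scaled = SpeciesConcentrations(
        2 * base * scale, base * scale, 0.7 * base * scale,
        0.3 * base * scale, 1.3 * base * scale,
    )
    assert relative_association(sp) == pytest.approx(
        relative_association(scaled), rel=1e-12
    )


@pytest.mark.parametrize(
    "k_rel, ref, ka, kd",
    [
        (0.34, 2.5, 0.136, 7.35),
        (0.28, 2.5, 0.112, 8.93),
        (1.0, 2.5, 0.4, 2.5),
    ],
)
def test_kd_from_relative_worked_examples(k_rel, ref, ka, kd):
    est = kd_from_relative(k_rel, ref)
    assert est.k_a == pytest.approx(ka, abs=0.0005)
    assert est.k_d == pytest.approx(kd, abs=0.05)
    assert est.k_a * est.k_d == pytest.approx(1.0, rel=1e-12)


@given(st.floats(min_value=0.01, max_value=10.0), st.floats(min_value=1.01, max_value=3.0))
@settings(deadline=None)
def test_kd_from_relative_strictly_decreasing(k_rel, factor):
    assert kd_from_relative(k_rel * factor, 2.5).k_d < kd_from_relative(k_rel, 2.5).k_d


# ---------------------------------------------------------------------------
# Exact oracle
# ---------------------------------------------------------------------------


def test_oracle_symmetry_equal_affinities():
    sp = exact_competition_oracle(5.0, 5.0, 30.0, 40.0, 40.0)
    assert sp.bound_gdp == pytest.approx(sp.bound_analogue, rel=1e-10)


def test_oracle_matches_tight_binding_arithmetic():
    # In the tight-binding regime the oracle's species ratio equals the
    # affinity ratio kd_gdp / kd_analogue.
    sp = exact_competition_oracle(2.5, 7.4, 29.4, 29.4, 50.0)
    assert relative_association(sp) == pytest.approx(2.5 / 7.4, rel=1e-6)


def test_oracle_no_protein_limit():
    sp = exact_competition_oracle(2.5, 7.4, 0.0, 29.4, 50.0)
    assert sp.bound_gdp == 0.0
    assert sp.bound_analogue == 0.0
    assert sp.free_gdp == pytest.approx(29.4)
    assert sp.free_analogue == pytest.approx(50.0)


@given(
    kd_gdp=st.floats(min_value=0.1, max_value=1000.0),  # pM
    kd_analogue=st.floats(min_value=0.1, max_value=1000.0),
    protein=st.floats(min_value=10.0, max_value=100.0),  # µM
    analogue=st.floats(min_value=10.0, max_value=100.0),
)
@settings(deadline=None, max_examples=50)
def test_oracle_mass_conservation_and_kd_definitions(
    kd_gdp, kd_analogue, protein, analogue
):
    gdp = protein
    sp = exact_competition_oracle(kd_gdp, kd_analogue, protein, gdp, analogue)
    assert sp.bound_gdp + sp.free_gdp == pytest.approx(gdp, abs=1e-9)
    assert sp.bound_analogue + sp.free_analogue == pytest.approx(analogue, abs=1e-9)
    p_free = protein - sp.bound_gdp - sp.bound_analogue
    # Both isotherms satisfied: Kd = [P][L]/[PL]
    assert p_free * sp.free_gdp / sp.bound_gdp == pytest.approx(
        kd_gdp * 1e-6, rel=1e-8
    )
    assert p_free * sp.free_analogue / sp.bound_analogue == pytest.approx(
        kd_analogue * 1e-6, rel=1e-8
    )


@given(
    kd_gdp=st.floats(min_value=0.1, max_value=1000.0),  # both Kd <= 1 nM
    kd_analogue=st.floats(min_value=0.1, max_value=1000.0),
    protein=st.floats(min_value=10.0, max_value=100.0),
    analogue=st.floats(min_value=10.0, max_value=100.0),
)
@settings(deadline=None, max_examples=50)
def test_tight_binding_round_trip(kd_gdp, kd_analogue, protein, analogue):
    """Oracle species fed through the simplified estimator recover the input
    analogue K_D within 2% in the tight-binding regime."""
    sp = exact_competition_oracle(kd_gdp, kd_analogue, protein, protein, analogue)
    k_rel = relative_association(sp)
    est = kd_from_relative(k_rel, kd_gdp)
    assert est.k_d == pytest.approx(kd_analogue, rel=0.02)


def test_n_ligand_solver_reduces_to_two_ligand():
    _, bound, free = solve_competitive_equilibrium(
        30.0, [29.4, 50.0], [2.5e-6, 7.4e-6]
    )
    sp = exact_competition_oracle(2.5, 7.4, 30.0, 29.4, 50.0)
    assert bound[0] == pytest.approx(sp.bound_gdp, rel=1e-10)
    assert bound[1] == pytest.approx(sp.bound_analogue, rel=1e-10)


# ---------------------------------------------------------------------------
# Full estimation pipeline
# ---------------------------------------------------------------------------


def test_estimate_affinity_paper_mode_full_chain():
    assay = CompetitionAssay(
        analogue_id="pdaGDP", analogue_total=50.0,
        t0_percent_gdp=37.0, t0_percent_analogue=63.0,
        eq_percent_gdp=53.0, eq_percent_analogue=47.0,
    )
    est = estimate_affinity(assay)
    assert round(est.k_rel_a, 2) == 0.34
    assert est.k_d == pytest.approx(7.4, abs=0.1)


def test_estimate_affinity_exact_mode_close_to_paper_mode():
    assay = CompetitionAssay(
        analogue_id="bdaGDP", analogue_total=50.0,
        t0_percent_gdp=43.0, t0_percent_analogue=57.0,
        eq_percent_gdp=60.5, eq_percent_analogue=39.5,
    )
    paper = estimate_affinity(assay, mode="paper")
    exact = estimate_affinity(assay, mode="exact")
    # Tight binding: both estimators agree closely.
    assert exact.k_d == pytest.approx(paper.k_d, rel=0.02)
    assert exact.mode == "exact"


def test_unquantifiable_assay_is_flagged_not_computed():
    assay = CompetitionAssay(
        analogue_id="edaGDP", analogue_total=50.0,
        t0_percent_gdp=50.0, t0_percent_analogue=50.0,
        eq_percent_gdp=50.0, eq_percent_analogue=50.0,
        quantifiable=False,
    )
    est = estimate_affinity(assay)
    assert est.flagged
    assert math.isnan(est.k_d)
    assert "overlap" in est.flag_reason


def test_assay_percentages_must_sum_to_100():
    with pytest.raises(ValueError, match="sum to 100"):
        CompetitionAssay("x", 50.0, 40.0, 50.0, 50.0, 50.0)


def test_assay_fraction_constructor_canonicalizes_to_percent():
    a = CompetitionAssay.from_fractions("x", 50.0, 0.37, 0.63, 0.53, 0.47)
    assert a.t0_percent_gdp == pytest.approx(37.0)
    assert a.eq_percent_analogue == pytest.approx(47.0)
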