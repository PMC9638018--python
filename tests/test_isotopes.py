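"""Natural-abundance correction: closed forms, exhaustive oracles, recovery."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings, strategies as st

from immetab import isotopes as iso
from immetab.isotopes import (
    FRAGMENT_FORMULAS,
    IsotopologueSpectrum,
    build_correction_matrix,
    correct_mid,
    fractional_enrichment,
    labeled_abundance,
    metabolite_ratio,
    natural_isotope_distribution,
    normalize_to_internal_standard,
    parse_formula,
)

from conftest import brute_force_correction_matrix, brute_force_isotope_distribution


class TestNaturalIsotopeDistribution:
    def test_empty_formula_is_point_mass_at_zero(self):
        npt.assert_array_equal(natural_isotope_distribution({}), [1.0])

    def test_pure_light_isotope_single_atom(self):
        table = {"C": {0: 1.0, 1: 0.0}}
        npt.assert_allclose(natural_isotope_distribution({"C": 1}, table), [1.0, 0.0])

    def test_two_carbons_match_binomial_closed_form(self):
        p = iso.NATURAL_ABUNDANCE["C"][1]
        expected = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        npt.assert_allclose(
            natural_isotope_distribution({"C": 2}), expected, atol=1e-15
        )

    def test_agrees_with_exhaustive_enumeration_c3h3(self):
        got = natural_isotope_distribution({"C": 3, "H": 3})
        want = brute_force_isotope_distribution({"C": 3, "H": 3})
        assert np.max(np.abs(got - want)) < 1e-12

    def test_untruncated_distribution_sums_to_one(self):
        for formula in [{"C": 4, "H": 6, "O": 4}, {"Si": 2, "O": 3}, {"S": 2}]:
            assert natural_isotope_distribution(formula).sum() == pytest.approx(1.0, abs=1e-9)

    def test_truncation_pads_and_cuts(self):
        full = natural_isotope_distribution({"C": 2})
        cut = natural_isotope_distribution({"C": 2}, max_shift=1)
        npt.assert_allclose(cut, full[:2])
        padded = natural_isotope_distribution({"C": 1}, max_shift=4)
        assert len(padded) == 5 and padded[2:].sum() == 0

    def test_unknown_element_names_the_symbol(self):
        with pytest.raises(KeyError, match="Xx"):
            natural_isotope_distribution({"Xx": 1})

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "Si"]),
            st.integers(min_value=0, max_value=4),
            min_size=1,
            max_size=3,
        ).filter(lambda f: 0 < sum(f.values()) <= 8)
    )
    def test_random_small_formulas_match_enumeration(self, formula):
        got = natural_isotope_distribution(formula)
        want = brute_force_isotope_distribution(formula)
        assert np.max(np.abs(got - want)) < 1e-12


class TestCorrectionMatrix:
    def test_zero_tracer_positions_is_single_natural_column(self):
        M = build_correction_matrix({"C": 3, "H": 2}, 0, K=3)
        npt.assert_allclose(
            M[:, 0], natural_isotope_distribution({"C": 3, "H": 2}, max_shift=3)
        )
        assert M.shape == (4, 1)

    def test_all_light_abundances_give_identity(self):
        table = {"C": {0: 1.0}, "H": {0: 1.0}}
        M = build_correction_matrix({"C": 4, "H": 4}, 4, table=table)
        npt.assert_allclose(M, np.eye(5))

    def test_toy_formula_matches_exhaustive_oracle(self):
        formula = {"C": 3, "H": 3}
        M = build_correction_matrix(formula, 3, K=3)
        want = brute_force_correction_matrix(formula, 3, K=3)
        assert np.max(np.abs(M - want)) < 1e-12

    def test_untruncated_columns_sum_to_one(self):
        formula = {"C": 4, "H": 6, "O": 4}
        M = build_correction_matrix(formula, 4, K=4 + 12)  # generous window
        # column j occupies rows j..; with a window this wide nothing is lost
        npt.assert_allclose(M.sum(axis=0), np.ones(5), atol=1e-9)

    def test_carbon_only_mode_ignores_other_elements(self):
        M = build_correction_matrix({"C": 4, "Si": 2, "O": 4}, 4, carbon_only=True)
        want = build_correction_matrix({"C": 4}, 4)
        npt.assert_allclose(M, want)

    def test_tracer_positions_beyond_carbons_rejected(self):
        with pytest.raises(ValueError, match="exceeds carbon count"):
            build_correction_matrix({"C": 3}, 4)

    def test_fragment_presets_are_consistent(self):
        for name, (formula, n_pos) in FRAGMENT_FORMULAS.items():
            assert formula["C"] >= n_pos, name
            M = build_correction_matrix(formula, n_pos)
            assert M.shape == (n_pos + 1, n_pos + 1)
            assert np.all(M >= 0) and np.all(M <= 1)


class TestCorrectMid:
    @pytest.mark.parametrize("metabolite", sorted(FRAGMENT_FORMULAS))
    def test_noise_free_inverse_recovers_known_mid(self, metabolite):
        formula, n_pos = FRAGMENT_FORMULAS[metabolite]
        M = build_correction_matrix(formula, n_pos)
        true = np.linspace(1, 2, n_pos + 1)
        true /= true.sum()
        counts = 1e6 * (M @ true)
        mid = correct_mid(IsotopologueSpectrum("s", metabolite, counts), M)
        assert np.max(np.abs(mid.fractions - true)) < 1e-9

    def test_identity_matrix_returns_normalized_counts(self):
        counts = np.array([2.0, 1.0, 1.0])
        mid = correct_mid(IsotopologueSpectrum("s", "x", counts), np.eye(3))
        npt.assert_allclose(mid.fractions, counts / counts.sum())

    def test_mid_is_normalized_and_non_negative(self):
        formula, n_pos = FRAGMENT_FORMULAS["succinate"]
        M = build_correction_matrix(formula, n_pos)
        rng = np.random.default_rng(1)
        for _ in range(20):
            true = rng.dirichlet(np.ones(n_pos + 1))
            counts = (M @ true) * rng.lognormal(0, 0.05, n_pos + 1)
            mid = correct_mid(IsotopologueSpectrum("s", "succinate", counts), M)
            assert np.all(mid.fractions >= 0)
            assert mid.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reconvolution_reproduces_spectrum_shape(self):
        formula, n_pos = FRAGMENT_FORMULAS["malate"]
        M = build_correction_matrix(formula, n_pos)
        true = np.array([0.2, 0.1, 0.1, 0.25, 0.35])
        counts = M @ true
        mid = correct_mid(IsotopologueSpectrum("s", "malate", counts), M)
        # optimal rescaling of the recovered MID back through the forward model
        pred = M @ mid.fractions
        scale = float(counts @ pred) / float(pred @ pred)
        assert np.linalg.norm(scale * pred - counts) < 1e-9

    def test_monotone_in_true_top_isotopologue(self):
        formula, n_pos = FRAGMENT_FORMULAS["succinate"]
        M = build_correction_matrix(formula, n_pos)
        recovered = []
        for m4 in [0.2, 0.5, 0.8]:
            true = np.full(n_pos + 1, (1 - m4) / n_pos)
            true[-1] = m4
            counts = M @ true
            mid = correct_mid(IsotopologueSpectrum("s", "succinate", counts), M)
            recovered.append(mid.fractions[-1])
        assert recovered[0] < recovered[1] < recovered[2]

    def test_fully_labeled_tracer_gives_modal_m4(self):
        # cells grown on fully 13C-labeled succinate: most of the pool is m+4
        formula, n_pos = FRAGMENT_FORMULAS["succinate"]
        M = build_correction_matrix(formula, n_pos)
        true = np.array([0.15, 0.03, 0.04, 0.08, 0.70])
        counts = 1e6 * (M @ true)
        mid = correct_mid(IsotopologueSpectrum("s", "succinate", counts), M)
        assert np.argmax(mid.fractions) == 4

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            correct_mid(IsotopologueSpectrum("s", "x", np.zeros(3)), np.eye(3))

    def test_rank_deficient_matrix_rejected(self):
        M = np.ones((3, 3))
        with pytest.raises(ValueError, match="rank-deficient"):
            correct_mid(IsotopologueSpectrum("s", "x", np.array([1.0, 1, 1])), M)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            correct_mid(IsotopologueSpectrum("s", "x", np.ones(4)), np.eye(3))


class TestSummaries:
    @pytest.mark.parametrize(
        "mid, expected",
        [([1, 0, 0, 0, 0], 0.0), ([0, 0, 0, 0, 1], 1.0), ([0.5, 0, 0, 0, 0.5], 0.5)],
    )
    def test_fractional_enrichment(self, mid, expected):
        assert fractional_enrichment(np.array(mid)) == pytest.approx(expected)

    def test_internal_standard_normalization(self):
        assert normalize_to_internal_standard(500, 500) == 1.0
        assert normalize_to_internal_standard(1500, 500) == 3.0
        with pytest.raises(ValueError):
            normalize_to_internal_standard(100, 0)

    def test_labeled_abundance_excludes_m0(self):
        npt.assert_allclose(labeled_abundance(np.array([1.0, 0, 0]), 5.0), [0, 0])
        npt.assert_allclose(
            labeled_abundance(np.array([0, 0, 0, 0, 1.0]), 2.0), [0, 0, 0, 2.0]
        )

    def test_metabolite_ratio(self):
        assert metabolite_ratio(4, 2) == 2
        assert metabolite_ratio(3.3, 3.3) == 1
        with pytest.raises(ValueError):
            metabolite_ratio(1, 0)

    def test_parse_formula(self):
        assert parse_formula("C12H25O4Si2") == {"C": 12, "H": 25, "O": 4, "Si": 2}
        assert parse_formula("CH4") == {"C": 1, "H": 4}
        with pytest.raises(ValueError):
            parse_formula("12C")
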