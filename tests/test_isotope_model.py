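"""Isotope-pattern computations: natural, labeled, RIA estimators."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turnoverms.constants import ELEMENT_ISOTOPES, EXCHANGEABLE_HYDROGENS
from turnoverms.isotope_model import (
    EnrichmentModel,
    PeptideSpec,
    asymptotic_ria,
    count_exchangeable_hydrogens,
    isotope_deviation,
    labeled_pattern,
    mixture_pattern,
    natural_isotope_pattern,
    peptide_composition,
    ria_from_complete_profile,
    ria_from_isotopomer_ratio,
)


def brute_force_pattern(composition: dict[str, int], L: int) -> np.ndarray:
    """Oracle: enumerate every isotopologue of a tiny molecule directly."""
    atoms = []
    for elem, n in composition.items():
        atoms.extend([ELEMENT_ISOTOPES[elem]] * n)
    pattern = np.zeros(L)
    for combo in itertools.product(*(range(len(a)) for a in atoms)):
        offset = sum(
            int(round(atoms[i][c][0] - atoms[i][0][0]))
            for i, c in enumerate(combo)
        )
        if offset < L:
            prob = np.prod([atoms[i][c][1] for i, c in enumerate(combo)])
            pattern[offset] += prob
    return pattern / pattern.sum()


class TestNaturalPattern:
    def test_water_matches_brute_force_enumeration(self):
        got = natural_isotope_pattern({"H": 2, "O": 1}, L=2)
        expected = brute_force_pattern({"H": 2, "O": 1}, L=2)
        assert np.allclose(got, expected, atol=1e-12)
        # the light isotopologue dominates overwhelmingly
        assert got[0] > 0.999

    def test_methane_matches_brute_force_enumeration(self):
        comp = {"C": 1, "H": 4}
        got = natural_isotope_pattern(comp, L=4)
        expected = brute_force_pattern(comp, L=4)
        assert np.allclose(got, expected, atol=1e-12)

    def test_monoisotopic_element_is_identity(self):
        # fluorine-like: hydrogen alone is nearly monoisotopic; use a
        # fabricated one-atom species of carbon's 12C only via H-free comp
        pattern = natural_isotope_pattern({"H": 1}, L=4)
        assert pattern[0] == pytest.approx(1.0, abs=1e-3)
        assert pattern.sum() == pytest.approx(1.0, abs=1e-9)

    def test_peptide_monoisotope_dominates_first_neighbor(self, natural):
        # FANTMGLVIER: A0 > A1 for this composition
        assert natural[0] > natural[1]

    def test_truncation_renormalizes(self, peptide):
        short = natural_isotope_pattern(peptide, L=4)
        assert short.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ValueError, match="Xx"):
            natural_isotope_pattern({"Xx": 1}, L=4)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            natural_isotope_pattern({}, L=4)


class TestCompleteProfileRia:
    @pytest.mark.parametrize(
        "profile, expected",
        [
            ([100, 50, 30, 10, 5, 2], 100 / 197),
            ([1, 0, 0, 0, 0, 0], 1.0),
            ([0, 1, 1, 1, 1, 1], 0.0),
            # a 7th isotopomer is outside the six-peak normalization
            ([100, 50, 30, 10, 5, 2, 99], 100 / 197),
        ],
    )
    def test_hand_computed_values(self, profile, expected):
        assert ria_from_complete_profile(profile) == pytest.approx(
            expected, abs=1e-9
        )

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            ria_from_complete_profile([0.0] * 6)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            ria_from_complete_profile([1.0, 2.0])


class TestAsymptoticRia:
    def test_direct_evaluation(self):
        model = EnrichmentModel(pW=0.046, pH=0.000115)
        # 0.5 * (1 - 0.046/(1 - 0.000115))**20, evaluated by hand
        assert asymptotic_ria(0.5, model, 20) == pytest.approx(
            0.1949347784667288, rel=1e-12
        )

    def test_no_labeling_leaves_natural_ria(self):
        assert asymptotic_ria(0.5, EnrichmentModel(pW=0.0), 25) == 0.5

    def test_no_exchangeable_hydrogens_leaves_natural_ria(self):
        assert asymptotic_ria(0.5, EnrichmentModel(pW=0.046), 0) == 0.5

    def test_decreasing_in_neh_and_pw(self):
        model = EnrichmentModel(pW=0.046)
        values = [asymptotic_ria(0.5, model, n) for n in (5, 10, 20, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))
        by_pw = [
            asymptotic_ria(0.5, EnrichmentModel(pW=pw), 20)
            for pw in (0.01, 0.03, 0.046, 0.08)
        ]
        assert all(a > b for a, b in zip(by_pw, by_pw[1:]))

    def test_invalid_enrichment_rejected(self):
        with pytest.raises(ValueError):
            asymptotic_ria(0.5, EnrichmentModel(pW=0.9999, pH=0.5), 10)


class TestLabeledPattern:
    def test_zero_incorporation_is_identity(self, natural, peptide):
        assert np.allclose(labeled_pattern(natural, peptide.neh, 0.0), natural)

    def test_single_trial_binomial(self):
        nat = np.zeros(8)
        nat[0] = 1.0
        got = labeled_pattern(nat, 1, 0.3)
        assert got[0] == pytest.approx(0.7)
        assert got[1] == pytest.approx(0.3)
        assert got[2:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_monoisotope_matches_untruncated_convolution(self, natural):
        # oracle: full-length convolution with no truncation loss
        neh, pX = 12, 0.0459
        from scipy.stats import binom

        weights = binom.pmf(np.arange(neh + 1), neh, pX)
        full = np.convolve(natural, weights)
        got = labeled_pattern(natural, neh, pX)
        norm = got[0] / (full[0] / full.sum())
        # truncation renormalization inflates all kept peaks equally
        assert np.allclose(
            got[: natural.size] * (full[: natural.size] / full[: natural.size].sum() / got)[0],
            full[: natural.size] / full[: natural.size].sum(),
            rtol=1e-9,
        )
        assert norm >= 1.0

    def test_fractional_neh_monoisotope_matches_plateau_formula(self, natural):
        # the zero-label probability must equal (1-pX)**NEH exactly,
        # fractional NEH included — the plateau-RIA consistency anchor
        pX = 0.0459
        for neh in (7.0, 19.13, 3.4):
            lab = labeled_pattern(natural, neh, pX)
            # undo the truncation renormalization via the total kept mass
            from turnoverms.isotope_model import _binomial_weights

            weights = _binomial_weights(neh, pX, natural.size)
            kept = np.convolve(natural, weights)[: natural.size].sum()
            assert lab[0] * kept == pytest.approx(
                natural[0] * (1 - pX) ** neh, rel=1e-10
            )


class TestMixtureAndRatioMethod:
    def test_mixture_endpoints_and_linearity(self, natural, labeled):
        assert np.allclose(mixture_pattern(natural, labeled, 0.0), natural)
        assert np.allclose(mixture_pattern(natural, labeled, 1.0), labeled)
        mid = mixture_pattern(natural, labeled, 0.5)
        assert np.allclose(mid, 0.5 * natural + 0.5 * labeled)

    @pytest.mark.parametrize("pair", [(1, 0), (2, 0), (2, 1)])
    @pytest.mark.parametrize("f", [0.0, 0.2, 0.4, 0.75, 1.0])
    def test_ratio_method_equals_complete_profile(self, natural, labeled, pair, f):
        """On undistorted mixtures the two-isotopomer estimator must
        reproduce the complete-profile monoisotopic RIA."""
        mix = mixture_pattern(natural, labeled, f)
        ria_complete = ria_from_complete_profile(mix)
        i, j = pair
        ria_pair = ria_from_isotopomer_ratio(mix[i] / mix[j], i, j, natural, labeled)
        assert ria_pair == pytest.approx(ria_complete, abs=1e-6)

    def test_ratio_method_matches_grid_search_oracle(self, natural, labeled):
        f_true = 0.4
        mix = mixture_pattern(natural, labeled, f_true)
        # oracle: dense grid search over the labeled fraction
        nat6 = natural[:6] / natural[:6].sum()
        lab6 = labeled[:6] / labeled[:6].sum()
        grid = np.linspace(0, 1, 200001)
        model = ((1 - grid)[:, None] * nat6 + grid[:, None] * lab6)
        ratios = model[:, 2] / model[:, 0]
        f_hat = grid[np.argmin(np.abs(ratios - mix[2] / mix[0]))]
        oracle = (1 - f_hat) * nat6[0] + f_hat * lab6[0]
        got = ria_from_isotopomer_ratio(mix[2] / mix[0], 2, 0, natural, labeled)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_out_of_range_ratio_signals_interference(self, natural, labeled):
        with pytest.raises(ValueError, match="interference"):
            ria_from_isotopomer_ratio(1e3, 1, 0, natural, labeled)

    def test_high_channel_interference_spares_low_pairs(self, natural, labeled):
        """Perturbing only M3-M5 leaves the (1,0) and (2,0) estimates
        untouched while the complete-profile RIA shifts."""
        mix = mixture_pattern(natural, labeled, 0.4)
        clean = ria_from_complete_profile(mix)
        distorted = mix.copy()
        distorted[3:6] += 0.3 * mix.max()
        assert ria_from_complete_profile(distorted) != pytest.approx(clean, abs=1e-4)
        for pair in [(1, 0), (2, 0)]:
            i, j = pair
            got = ria_from_isotopomer_ratio(
                distorted[i] / distorted[j], i, j, natural, labeled
            )
            assert got == pytest.approx(clean, abs=1e-9)

    def test_mixture_monoisotopic_ria_decreasing_in_f(self, natural, labeled):
        rias = [
            ria_from_complete_profile(mixture_pattern(natural, labeled, f))
            for f in np.linspace(0, 1, 21)
        ]
        assert all(a > b for a, b in zip(rias, rias[1:]))


class TestIsotopeDeviation:
    def test_identical_patterns_zero(self, natural):
        assert isotope_deviation(natural, natural) == 0.0

    def test_disjoint_support_reaches_bound(self):
        a = [1, 0, 0, 0, 0, 0]
        b = [0, 1, 0, 0, 0, 0]
        assert isotope_deviation(a, b) == pytest.approx(2.0)

    def test_hand_computed_value(self):
        got = isotope_deviation([0.5, 0.3, 0.2, 0, 0, 0], [0.4, 0.4, 0.2, 0, 0, 0])
        assert got == pytest.approx(0.2, abs=1e-12)


class TestExchangeableHydrogens:
    def test_empty_sequence(self):
        assert count_exchangeable_hydrogens("") == 0.0

    def test_additivity_and_permutation_symmetry(self):
        assert count_exchangeable_hydrogens("GG") == pytest.approx(
            2 * EXCHANGEABLE_HYDROGENS["G"]
        )
        assert count_exchangeable_hydrogens("AG") == pytest.approx(
            count_exchangeable_hydrogens("GA")
        )

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="B"):
            count_exchangeable_hydrogens("ABC")

    def test_table_override(self):
        assert count_exchangeable_hydrogens("AA", table={"A": 1.5}) == 3.0

    def test_neh_cannot_exceed_hydrogen_count(self):
        comp = peptide_composition("AG")
        with pytest.raises(ValueError):
            PeptideSpec(sequence="AG", charge=1, neh=comp["H"] + 1)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.sampled_from(list("ACDEFGHIKLMNPQRSTVWY")), min_size=4, max_size=20
    ),
    st.floats(min_value=0.0, max_value=0.2),
    st.floats(min_value=0.0, max_value=1.0),
)
def test_pattern_operations_stay_normalized(residues, pX, f):
    """Every pattern-producing operation returns a distribution."""
    spec = PeptideSpec(sequence="".join(residues), charge=2)
    nat = natural_isotope_pattern(spec)
    assert nat.sum() == pytest.approx(1.0, abs=1e-9)
    lab = labeled_pattern(nat, spec.neh, pX)
    assert lab.sum() == pytest.approx(1.0, abs=1e-9)
    mix = mixture_pattern(nat, lab, f)
    assert mix.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(mix >= 0)
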