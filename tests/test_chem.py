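"""Formula algebra, exact masses, valence rules, isotopologue patterns."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halomet import chem
from halomet.chem import (
    ElementalFormula,
    IonSpec,
    cation_mz,
    isotopologue_pattern,
    monoisotopic_mass,
    nitrogen_rule_ok,
    parse_formula,
    ppm_error,
    rdbe,
    round_half_away,
)

from conftest import oracle_isotope_pattern

formula_counts = st.fixed_dictionaries(
    {},
    optional={
        el: st.integers(min_value=1, max_value=20)
        for el in ("C", "H", "N", "O", "S", "Cl", "Br")
    },
).filter(lambda d: len(d) > 0)


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C19H14BrClN6O2", {"C": 19, "H": 14, "Br": 1, "Cl": 1, "N": 6, "O": 2}),
            ("H", {"H": 1}),
            ("C6H10O5", {"C": 6, "H": 10, "O": 5}),
            ("CH4", {"C": 1, "H": 4}),
            ("HCl", {"H": 1, "Cl": 1}),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_formula(text).as_dict() == expected

    @pytest.mark.parametrize("bad", ["", "  ", "X2", "C19H-4", "C0", "C6h6", "12C"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)

    @given(formula_counts)
    @settings(deadline=None, max_examples=100)
    def test_hill_roundtrip(self, counts):
        f = ElementalFormula.from_counts(counts)
        assert parse_formula(f.hill()) == f


class TestMasses:
    def test_anhydroglucose(self):
        m = monoisotopic_mass(parse_formula("C6H10O5"))
        assert round_half_away(m, 4) == 162.0528
        assert round_half_away(m, 2) == 162.05

    @given(formula_counts, formula_counts)
    @settings(deadline=None, max_examples=50)
    def test_additivity(self, a, b):
        fa, fb = ElementalFormula.from_counts(a), ElementalFormula.from_counts(b)
        assert monoisotopic_mass(fa) + monoisotopic_mass(fb) == pytest.approx(
            monoisotopic_mass(fa + fb), abs=1e-9
        )

    def test_parent_neutral_mass(self):
        # independent hand calculation over NIST monoisotopic masses
        assert monoisotopic_mass(parse_formula("C19H14BrClN6O2")) == pytest.approx(
            472.0050, abs=5e-5
        )

    @pytest.mark.parametrize(
        "formula,printed",
        [
            ("C19H14BrClN6O2", 473.0123),
            ("C19H12BrClN6O", 455.0017),
            ("C24H20BrClN6O7", 619.0338),
            ("C9H5BrClN3O2", 301.9326),
        ],
    )
    def test_cation_mz_reference_ions(self, formula, printed):
        assert round_half_away(cation_mz(parse_formula(formula)), 4) == printed

    def test_cation_mz_subtracts_electron(self):
        f = parse_formula("C19H14BrClN6O2")
        no_electron = monoisotopic_mass(f) + chem.MONO_MASS["H"]
        assert round_half_away(no_electron, 4) == 473.0128  # wrong without it
        assert round_half_away(cation_mz(f), 4) == 473.0123

    def test_catalog_masses_within_print_precision(self, catalog):
        # all transcribed calcd values agree with recomputation to within
        # one unit in the fourth decimal (printed rounding)
        for rec in catalog:
            assert abs(cation_mz(rec.formula) - rec.calcd_mz) < 1.5e-4, rec.name

    def test_unsupported_adduct(self):
        with pytest.raises(ValueError):
            IonSpec(parse_formula("CH4"), adduct="M+Na")


class TestPpmError:
    @pytest.mark.parametrize(
        "obs,ref,expected",
        [
            (455.0022, 455.0017, 1.1),
            (651.0616, 651.0600, 2.5),
            (473.0126, 473.0123, 0.6),
        ],
    )
    def test_printed_values_table_mode(self, obs, ref, expected):
        assert round_half_away(ppm_error(obs, ref), 1) == expected

    @given(st.floats(min_value=50.0, max_value=2000.0))
    def test_identity(self, x):
        assert ppm_error(x, x) == 0.0

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


class TestValenceRules:
    @pytest.mark.parametrize(
        "formula,expected",
        [("C19H14BrClN6O2", 15.0), ("CH4", 0.0), ("C6H10O5", 2.0)],
    )
    def test_rdbe(self, formula, expected):
        assert rdbe(parse_formula(formula)) == expected

    @pytest.mark.parametrize(
        "formula,ok",
        [
            ("C19H14BrClN6O2", True),  # nominal 472 even, 6 N
            ("NH3", True),  # nominal 17 odd, 1 N
            ("CH4N", False),  # nominal 30 even, 1 N: radical parity
        ],
    )
    def test_nitrogen_rule(self, formula, ok):
        assert nitrogen_rule_ok(parse_formula(formula)) is ok

    def test_nitrogen_rule_catalog(self, catalog):
        assert all(nitrogen_rule_ok(rec.formula) for rec in catalog)


class TestIsotopologues:
    @pytest.mark.parametrize(
        "formula",
        ["CH4", "H2O", "C2H5Cl", "C2H3BrO", "C3H5BrClN", "CH2S2O", "C4Cl2N2"],
    )
    def test_matches_brute_force_oracle(self, formula):
        # exhaustive per-atom enumeration as the independent oracle
        expected = oracle_isotope_pattern(formula)
        got = isotopologue_pattern(parse_formula(formula), prune=0.0).clusters
        assert len(got) == len(expected)
        for (gmz, gab), (emz, eab) in zip(got, expected):
            assert gmz == pytest.approx(emz, abs=1e-9)
            assert gab == pytest.approx(eab, abs=1e-6)

    def test_methane_a1(self):
        pat = isotopologue_pattern(parse_formula("CH4"))
        assert pat.clusters[0][1] == 100.0
        # one carbon: ~1.1% A+1 from the 13C satellite (1.07/98.93 per C)
        # plus five 2H contributions
        expected = 0.0107 / 0.9893 + 5 * 0.000115 / 0.999885
        assert pat.clusters[1][1] == pytest.approx(100 * expected, rel=0.01)

    def test_parent_reference_isotope_ions(self):
        # A+2 and A+4 cluster centroids of the parent [M+H]+ land on the
        # instrument-reported reference ions within 1 mDa
        pat = isotopologue_pattern(parse_formula("C19H14BrClN6O2"))
        a2 = min(pat.clusters, key=lambda c: abs(c[0] - 475.0101))
        a4 = min(pat.clusters, key=lambda c: abs(c[0] - 477.0074))
        assert abs(a2[0] - 475.0101) < 1e-3
        assert abs(a4[0] - 477.0074) < 1e-3
        # and A+2 is the base peak for a one-Br-one-Cl ion
        assert a2[1] == 100.0

    @given(
        st.integers(min_value=5, max_value=20),
        st.integers(min_value=5, max_value=20),
        st.integers(min_value=0, max_value=6),
        st.integers(min_value=0, max_value=6),
    )
    @settings(deadline=None, max_examples=25)
    def test_brcl_signature(self, nc, nh, nn, no):
        """Any one-Br-one-Cl formula shows A+2/A in [1.25, 1.35] and a
        real A+4 cluster."""
        f = ElementalFormula.from_counts(
            {"C": nc, "H": nh, "N": nn, "O": no, "Br": 1, "Cl": 1}
        )
        pat = isotopologue_pattern(f)
        a_mz, a_ab = pat.clusters[0]
        a2 = [ab for mz, ab in pat.clusters if abs(mz - (a_mz + 1.997)) < 0.01]
        a4 = [ab for mz, ab in pat.clusters if abs(mz - (a_mz + 3.995)) < 0.02]
        assert a2 and 1.25 <= a2[0] / a_ab <= 1.35
        assert a4 and a4[0] > 0

    @pytest.mark.parametrize("formula", ["CH4", "C6H10O5", "C3H5BrClN"])
    def test_probability_conservation(self, formula):
        total = chem.total_species_probability(parse_formula(formula))
        assert abs(total - 1.0) < 1e-9


def test_round_half_away():
    assert round_half_away(2.4576, 1) == 2.5
    assert round_half_away(2.44, 1) == 2.4
    assert round_half_away(-2.45, 1) == -2.5
    assert round_half_away(473.01229045, 4) == 473.0123
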