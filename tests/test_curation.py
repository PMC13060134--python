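"""Chemistry core: formulas, masses, delta masses, nomenclature, library."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carnlib.curation import (
    CARNITINE,
    CARNITINE_MH,
    assign_car_nomenclature,
    build_library,
    canonical_delta_key,
    chain_length_category,
    composition_class,
    compute_delta_mass,
    decompose_delta,
    delta_formula_from_precursor,
    formula_string,
    ion_mz,
    mass_defect,
    monoisotopic_mass,
    parse_formula,
)
from .conftest import make_spectrum


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C9H17NO4", {"C": 9, "H": 17, "N": 1, "O": 4}),
            ("C7H15NO3", {"C": 7, "H": 15, "N": 1, "O": 3}),
            ("H2O", {"H": 2, "O": 1}),
            ("CHCl3", {"C": 1, "H": 1, "Cl": 3}),
        ],
    )
    def test_hill_formulas(self, text, expected):
        assert parse_formula(text) == expected

    @pytest.mark.parametrize("bad", ["C9Hx", "Xy2", "", "C-3"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "P", "Cl"]),
            st.integers(1, 40),
            min_size=1,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_through_formula_string(self, counts):
        assert parse_formula(formula_string(counts)) == counts


class TestMasses:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C7H15NO3", 161.1052),  # free carnitine, neutral
            ("H2O", 18.0106),
            ("C2H2O", 42.0106),  # acetylation delta
            ("SO3", 79.9568),  # sulfation delta
            ("C6H8O6", 176.0321),  # glucuronidation delta
            ("CH2", 14.0157),
            ("O", 15.9949),
        ],
    )
    def test_neutral_monoisotopic_masses(self, formula, expected):
        assert monoisotopic_mass(parse_formula(formula)) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "formula,expected_mz",
        [
            ("C7H15NO3", 162.1125),  # carnitine [M+H]+
            ("C9H17NO4", 204.1230),  # acetylcarnitine [M+H]+
            ("C3H9N", 60.0808),  # diagnostic ions as protonated neutrals
            ("C4H4O2", 85.0284),
            ("C7H13NO2", 144.1019),
        ],
    )
    def test_protonated_ion_mz(self, formula, expected_mz):
        assert ion_mz(parse_formula(formula)) == pytest.approx(expected_mz, abs=5e-5)

    def test_empty_formula_is_massless(self):
        assert monoisotopic_mass({}) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mass({"C": -1})


class TestDeltaMass:
    def test_acetylcarnitine_gives_acetylation_delta(self):
        assert canonical_delta_key(compute_delta_mass(204.1230)) == 42.01

    def test_free_carnitine_gives_zero(self):
        assert canonical_delta_key(compute_delta_mass(162.1125)) == 0.00

    def test_sulfo_pair_differs_by_sulfation(self):
        base = CARNITINE_MH + monoisotopic_mass(parse_formula("C10H18O2"))
        sulfo = base + monoisotopic_mass(parse_formula("SO3"))
        diff = compute_delta_mass(sulfo) - compute_delta_mass(base)
        assert round(diff, 2) == 79.96

    def test_multiply_charged_rejected(self):
        with pytest.raises(ValueError):
            compute_delta_mass(204.1230, charge=2)

    def test_precursor_below_core_flagged(self):
        with pytest.raises(ValueError):
            compute_delta_mass(100.0)


class TestMassDefect:
    @pytest.mark.parametrize(
        "value,expected",
        [(42.0106, 0.0106), (15.995, -0.005), (0.0, 0.0), (176.0321, 0.0321)],
    )
    def test_examples(self, value, expected):
        assert mass_defect(value) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(-400, 400), st.integers(-5, 5))
    @settings(max_examples=100, deadline=None)
    def test_range_and_integer_shift_invariance(self, delta, k):
        d = mass_defect(delta)
        assert -0.5 < d <= 0.5
        # shift invariance up to the wrap-around at the half-integer tie
        diff = abs(mass_defect(delta + k) - d)
        assert min(diff, 1.0 - diff) < 1e-6


class TestDeltaFormula:
    def test_subtracts_carnitine_core(self):
        assert delta_formula_from_precursor(parse_formula("C9H17NO4")) == {
            "C": 2, "H": 2, "O": 1,
        }

    def test_carnitine_itself_gives_empty_delta(self):
        assert delta_formula_from_precursor(dict(CARNITINE)) == {}

    def test_core_deficit_gives_none(self):
        assert delta_formula_from_precursor(parse_formula("C6H12O6")) is None


class TestCarNomenclature:
    @pytest.mark.parametrize(
        "formula,name",
        [
            ("C2H2O", "CAR C2:0"),
            ("C18H32O2", "CAR C18:1;O"),
            ("C18H34O", "CAR C18:0"),
            ("C10H14O3", "CAR C10:2;O2"),
        ],
    )
    def test_cho_deltas_named(self, formula, name):
        assert assign_car_nomenclature(parse_formula(formula)) == name

    @pytest.mark.parametrize("formula", ["C3H5NO", "CH2", "C2H6O", "O2", "C5H12O"])
    def test_unnameable_deltas_return_none(self, formula):
        # nitrogen, no oxygen, odd hydrogen arithmetic, no carbon, negative y
        assert assign_car_nomenclature(parse_formula(formula)) is None

    def test_round_trip_over_constructible_grid(self):
        for x, y, z in itertools.product(range(2, 31), range(0, 7), range(0, 4)):
            h = 2 * x - 2 * y - 2
            if h < 0:
                continue
            counts = {"C": x, "O": z + 1}
            if h:
                counts["H"] = h
            expected = f"CAR C{x}:{y}" + ("" if z == 0 else ";O" if z == 1 else f";O{z}")
            assert assign_car_nomenclature(counts) == expected


class TestDecomposeDelta:
    def test_acetylation_found_rank_one(self):
        out = decompose_delta(42.0106, 5.0, {"C": (0, 5), "H": (0, 10), "O": (0, 3)})
        assert out and out[0] == {"C": 2, "H": 2, "O": 1}

    def test_water_found(self):
        out = decompose_delta(18.0106, 5.0, {"C": (0, 3), "H": (0, 6), "O": (0, 2)})
        assert {"H": 2, "O": 1} in out

    def test_no_composition_at_zero_tolerance(self):
        assert decompose_delta(42.5, 1e-9, {"C": (0, 3), "H": (0, 6), "O": (0, 2)}) == []

    def test_matches_independent_enumeration(self):
        bounds = {"C": (0, 6), "H": (0, 12), "N": (0, 2), "O": (0, 4)}
        target = 59.0371  # C2H5NO (glycine-like delta)
        got = decompose_delta(target, 10.0, bounds)
        # independent triple-loop enumeration
        from carnlib.curation import MONOISOTOPIC

        expected = []
        tol = 10.0 * 1e-6 * (CARNITINE_MH + target)
        for c in range(7):
            for h in range(13):
                for n in range(3):
                    for o in range(5):
                        mass = (
                            c * MONOISOTOPIC["C"] + h * MONOISOTOPIC["H"]
                            + n * MONOISOTOPIC["N"] + o * MONOISOTOPIC["O"]
                        )
                        if abs(mass - target) <= tol:
                            expected.append(
                                {k: v for k, v in
                                 zip("CHNO", (c, h, n, o)) if v}
                            )
        assert {formula_string(f) for f in got} == {formula_string(f) for f in expected}


class TestChainLengthCategory:
    @pytest.mark.parametrize(
        "x,cat",
        [(2, "short"), (6, "short"), (7, "medium"), (12, "medium"),
         (13, "long"), (21, "long"), (22, "very_long"), (30, "very_long"),
         (0, "out_of_range"), (1, "out_of_range"), (31, "out_of_range")],
    )
    def test_brackets(self, x, cat):
        assert chain_length_category(x) == cat


class TestBuildLibrary:
    @staticmethod
    def _spec(sid, delta_formula, dataset):
        precursor = CARNITINE_MH + monoisotopic_mass(parse_formula(delta_formula))
        return make_spectrum(
            sid, precursor, [(60.0808, 10.0), (85.0284, 100.0), (144.1019, 50.0)],
            dataset_id=dataset,
        )

    def test_two_dataset_rule(self):
        spectra = {
            "a": self._spec("a", "C2H2O", "D1"),
            "b": self._spec("b", "C2H2O", "D2"),
            "c": self._spec("c", "C4H6O", "D1"),
        }
        assignments = {"a": ["a", "b"], "c": ["c"]}
        entries = build_library(assignments, spectra, min_datasets=2)
        keys = {e.delta_key for e in entries}
        assert keys == {42.01}
        (entry,) = entries
        assert entry.supporting_datasets == {"D1", "D2"}

    def test_support_tallied_across_entries_with_same_key(self):
        # two clusters, same delta, each seen in a single (different) dataset
        spectra = {
            "a": self._spec("a", "C2H2O", "D1"),
            "b": self._spec("b", "C2H2O", "D2"),
        }
        entries = build_library({"a": ["a"], "b": ["b"]}, spectra, min_datasets=2)
        assert {e.delta_key for e in entries} == {42.01}
        assert len(entries) == 2

    def test_formula_attaches_car_name_and_class(self):
        spectra = {"a": self._spec("a", "C2H2O", "D1"), "b": self._spec("b", "C2H2O", "D2")}
        entries = build_library(
            {"a": ["a", "b"]}, spectra, min_datasets=2,
            delta_formulas={"a": {"C": 2, "H": 2, "O": 1}},
        )
        assert entries[0].car_name == "CAR C2:0"
        assert entries[0].composition_class == "CHO"

    def test_composition_class_labels(self):
        assert composition_class({"C": 2, "H": 2, "O": 1}) == "CHO"
        assert composition_class({"C": 2, "H": 5, "N": 1, "O": 1, "S": 1}) == "CHNOS"
        assert composition_class(None) == "unassigned"
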