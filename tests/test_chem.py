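"""Formula arithmetic, monoisotopic masses, and the monomer registry."""

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligomig.chem import (
    ATOMIC_MASS,
    ElementalFormula,
    FormulaError,
    LibraryError,
    MonomerLibrary,
    WATER,
    WATER_MASS,
    combine_formulas,
    format_formula,
    load_monomer_library,
    monoisotopic_mass,
    parse_formula,
)


@pytest.mark.parametrize(
    "text,expected",
    [
        ("C8H6O4", {"C": 8, "H": 6, "O": 4}),
        ("C26H28O8", {"C": 26, "H": 28, "O": 8}),
        ("H2O", {"H": 2, "O": 1}),
        ("NaCl", {"Na": 1, "Cl": 1}),
        ("CH4", {"C": 1, "H": 4}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).as_dict() == expected


@pytest.mark.parametrize("bad", ["", "  ", "Xx5", "C-2", "2CO", "C8H6O4!"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


@pytest.mark.parametrize(
    "formula,mass",
    [
        ("C8H6O4", 166.0266),  # phthalic-type diacid
        ("H2O", 18.0106),
        ("C6H10O4", 146.0579),  # adipic acid
        ("C5H12O2", 104.0837),  # neopentyl glycol
    ],
)
def test_monoisotopic_mass(formula, mass):
    assert monoisotopic_mass(parse_formula(formula)) == pytest.approx(mass, abs=5e-4)


def test_empty_formula_mass_zero():
    assert ElementalFormula.from_counts({}).mass == 0.0


def test_mass_agrees_with_pyteomics():
    """Independent oracle: pyteomics computes the same monoisotopic masses."""
    from pyteomics.mass import calculate_mass

    for f in ("C8H6O4", "C26H28O8", "C6H14O2", "H2O", "C9H6O6"):
        assert parse_formula(f).mass == pytest.approx(
            calculate_mass(formula=f), abs=1e-5
        )


elements = st.sampled_from(sorted(ATOMIC_MASS))
formulas = st.dictionaries(elements, st.integers(min_value=1, max_value=40), min_size=1).map(
    ElementalFormula.from_counts
)


@settings(max_examples=200, derandomize=True)
@given(formulas)
def test_parse_format_round_trip(f):
    assert parse_formula(format_formula(f)) == f


@settings(max_examples=100, derandomize=True)
@given(formulas, formulas)
def test_mass_additivity(a, b):
    assert combine_formulas([a, b]).mass == pytest.approx(a.mass + b.mass, abs=1e-9)


@settings(max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=6))
def test_water_bookkeeping(k):
    base = parse_formula("C26H28O8")
    parts = [base, WATER * k] if k else [base]
    assert combine_formulas(parts, n_water_removed=k).mass == pytest.approx(
        base.mass, abs=1e-9
    )
    assert k * WATER_MASS == pytest.approx(k * 18.010565, abs=1e-5)


def test_combine_reproduces_cyclic_dimer_formula():
    # two aromatic diacids + two neopentyl glycols, ring-closed (4 waters out)
    tpa, npg = parse_formula("C8H6O4"), parse_formula("C5H12O2")
    assert format_formula(combine_formulas([tpa, tpa, npg, npg], 4)) == "C26H28O8"


def test_combine_identity_and_negative_error():
    f = parse_formula("C8H6O4")
    assert combine_formulas([f], 0) == f
    with pytest.raises(FormulaError):
        combine_formulas([parse_formula("CH4")], 1)  # no oxygen to remove


class TestMonomerLibrary:
    def test_default_contains_terephthalic_type_diacid(self, library):
        tpa = library["TPA"]
        assert tpa.monomer_class == "diacid"
        assert format_formula(tpa.formula) == "C8H6O4"
        assert tpa.aromatic

    def test_functionality_from_class(self, library):
        assert (library["PA"].n_acid_groups, library["PA"].n_hydroxyl_groups) == (2, 0)
        assert (library["TMA"].n_acid_groups, library["TMA"].n_hydroxyl_groups) == (3, 0)
        assert (library["NPG"].n_acid_groups, library["NPG"].n_hydroxyl_groups) == (0, 2)
        assert (library["CL"].n_acid_groups, library["CL"].n_hydroxyl_groups) == (1, 1)

    def test_isobaric_groups_detected(self, library):
        groups = library.isobaric_groups()
        assert {m.id for m in groups["C8H6O4"]} == {"PA", "IPA", "TPA"}
        assert {m.id for m in groups["C4H10O2"]} == {"BD", "BD13", "MPO"}
        assert library.isobaric_group_of("MPO") == ("BD", "BD13", "MPO")

    def test_duplicate_abbreviation_rejected(self, library):
        with pytest.raises(LibraryError, match="duplicate"):
            MonomerLibrary(list(library.monomers) + [library.monomers[0]])

    def test_empty_library_rejected(self):
        with pytest.raises(LibraryError):
            MonomerLibrary([])

    def test_load_from_file_and_errors(self, tmp_path, library):
        path = tmp_path / "lib.csv"
        path.write_text(
            textwrap.dedent(
                """\
                id,abbreviation,name,formula,class,aromatic
                PA,PA,phthalic acid,C8H6O4,diacid,true
                NPG,NPG,neopentyl glycol,C5H12O2,diol,false
                """
            )
        )
        lib = load_monomer_library(path)
        assert len(lib) == 2 and lib["PA"].mass == pytest.approx(166.0266, abs=5e-4)

        empty = tmp_path / "empty.csv"
        empty.write_text("")
        with pytest.raises(LibraryError):
            load_monomer_library(empty)

        bad = tmp_path / "bad.csv"
        bad.write_text("id,abbreviation,name,formula,class,aromatic\nX,X,x,,diol,false\n")
        with pytest.raises(LibraryError, match="missing"):
            load_monomer_library(bad)
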