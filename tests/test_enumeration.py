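"""Oligomer composition feasibility, mass accounting, and enumeration."""

from itertools import product as iter_product

import pytest

from oligomig.chem import WATER_MASS, format_formula
from oligomig.enumeration import (
    OligomerComposition,
    enumerate_oligomers,
    ester_bond_count,
    is_feasible,
    neutral_mass,
    oligomer_formula,
    oligomer_table,
)


def comp(counts, topo):
    return OligomerComposition.from_counts(counts, topo)


@pytest.mark.parametrize(
    "counts,topo,bonds",
    [
        ({"PA": 2, "NPG": 2}, "cyclic", 4),
        ({"PA": 2, "CHDM": 1}, "linear", 2),
        ({"PA": 1}, "linear", 0),
        ({"CL": 5}, "cyclic", 5),
    ],
)
def test_ester_bond_count(counts, topo, bonds):
    assert ester_bond_count(comp(counts, topo)) == bonds


@pytest.mark.parametrize(
    "counts,topo,feasible",
    [
        ({"PA": 2, "NPG": 2}, "cyclic", True),
        ({"PA": 2, "NPG": 1}, "cyclic", False),  # acid/diol imbalance in a ring
        ({"CL": 5}, "cyclic", True),  # lactone homopolymer ring
        ({"PA": 2, "NPG": 1}, "linear", True),  # diacid-terminated chain
        ({"PA": 1, "CHDM": 2}, "linear", True),  # diol-terminated chain
        ({"PA": 3, "NPG": 1}, "linear", False),  # cannot alternate
        ({"NPG": 2}, "cyclic", False),  # diol-only ring
        ({"TMA": 1, "NPG": 2}, "linear", True),  # triacid allowed in chains
        ({"TMA": 1, "NPG": 2}, "cyclic", False),  # branched rings excluded
        ({"PA": 1, "NPG": 1, "CL": 3}, "cyclic", True),  # hydroxyacids insert freely
    ],
)
def test_feasibility_rules(library, counts, topo, feasible):
    ok, reason = is_feasible(comp(counts, topo), library)
    assert ok is feasible, reason


def test_unknown_monomer_rejected(library):
    with pytest.raises(KeyError):
        is_feasible(comp({"XYZ": 1}, "linear"), library)


def test_neutral_mass_cyclic_tetramer(library):
    c = comp({"PA": 2, "NPG": 2}, "cyclic")
    assert neutral_mass(c, library) == pytest.approx(468.1784, abs=5e-4)


def test_linear_is_one_water_heavier(library):
    cy = neutral_mass(comp({"PA": 2, "NPG": 2}, "cyclic"), library)
    ln = neutral_mass(comp({"PA": 2, "NPG": 2}, "linear"), library)
    assert ln - cy == pytest.approx(WATER_MASS, abs=1e-9)


def test_cyclic_dimer_formula(library):
    c = comp({"TPA": 2, "NPG": 2}, "cyclic")
    assert format_formula(oligomer_formula(c, library)) == "C26H28O8"


def test_enumeration_contains_known_cyclic_tetramer(pa_npg_library):
    oligs = enumerate_oligomers(pa_npg_library, max_units=4, max_mass=1000.0)
    hits = [
        o
        for o in oligs
        if o.composition.composition_string() == "2NPG+2PA" and o.composition.is_cyclic
    ]
    assert len(hits) == 1
    assert hits[0].mass == pytest.approx(468.1784, abs=5e-4)


def test_enumeration_sorted_and_bounded(pa_npg_library):
    oligs = enumerate_oligomers(pa_npg_library, max_units=6, max_mass=800.0)
    masses = [o.mass for o in oligs]
    assert masses == sorted(masses)
    assert all(m <= 800.0 for m in masses)
    assert all(o.composition.n_units <= 6 for o in oligs)


def test_cutoff_monotonicity(pa_npg_library):
    small = {
        (o.composition.monomer_counts, o.composition.topology)
        for o in enumerate_oligomers(pa_npg_library, max_units=6, max_mass=600.0)
    }
    large = {
        (o.composition.monomer_counts, o.composition.topology)
        for o in enumerate_oligomers(pa_npg_library, max_units=6, max_mass=1000.0)
    }
    assert small <= large


def brute_force(library, ids, max_units, max_mass):
    """Independent oracle: all count vectors, feasibility applied post hoc,
    mass computed directly from monomer masses."""
    out = set()
    ranges = [range(max_units + 1)] * len(ids)
    for vec in iter_product(*ranges):
        n = sum(vec)
        if not 1 <= n <= max_units:
            continue
        counts = {mid: k for mid, k in zip(ids, vec) if k}
        for topo in ("linear", "cyclic"):
            c = OligomerComposition.from_counts(counts, topo)
            ok, _ = is_feasible(c, library)
            if not ok:
                continue
            bonds = n if topo == "cyclic" else n - 1
            mass = sum(library[m].mass * k for m, k in counts.items()) - bonds * WATER_MASS
            if mass <= max_mass:
                out.add((c.monomer_counts, topo, round(mass, 6)))
    return out


@pytest.mark.parametrize(
    "ids,max_units",
    [
        (["PA", "NPG"], 5),
        (["PA", "NPG", "CL"], 4),
        (["AA", "EG", "HD"], 5),
    ],
)
def test_enumeration_matches_brute_force(library, ids, max_units):
    sub = library.subset(ids)
    got = {
        (o.composition.monomer_counts, o.composition.topology, round(o.mass, 6))
        for o in enumerate_oligomers(sub, max_units=max_units, max_mass=1000.0)
    }
    assert got == brute_force(library, ids, max_units, 1000.0)


def test_cyclic_linear_pairing(library):
    sub = library.subset(["PA", "NPG", "EG"])
    oligs = enumerate_oligomers(sub, max_units=5, max_mass=900.0)
    by_key = {(o.composition.monomer_counts, o.composition.topology): o.mass for o in oligs}
    for (counts, topo), mass in by_key.items():
        if topo == "cyclic" and (counts, "linear") in by_key:
            assert by_key[(counts, "linear")] - mass == pytest.approx(WATER_MASS, abs=1e-9)


def test_isobaric_monomers_give_distinct_compositions_same_mass(library):
    sub = library.subset(["PA", "IPA", "NPG"])
    oligs = enumerate_oligomers(sub, max_units=4, max_mass=1000.0)
    pa = [o for o in oligs if o.composition.composition_string() == "2NPG+2PA"]
    ipa = [o for o in oligs if o.composition.composition_string() == "2IPA+2NPG"]
    assert pa and ipa
    assert pa[0].mass == pytest.approx(ipa[0].mass, abs=1e-12)


def test_table_export_columns(pa_npg_library):
    df = oligomer_table(enumerate_oligomers(pa_npg_library, max_units=4))
    assert list(df.columns) == ["composition", "topology", "n_units", "formula", "neutral_mass"]
    assert len(df) > 0
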