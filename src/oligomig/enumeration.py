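"""Combinatorial enumeration of linear and cyclic polyester oligomers.

An oligomer is a composition — a multiset of monomer counts plus a topology —
not a sequence: positional isomers and isobaric acid isomers share one entry.
A linear n-mer carries n-1 ester bonds, a cycle carries n; each bond costs one
water, so the cyclic form of any composition is exactly one water lighter than
the linear form.

Feasibility encodes ester-chain chemistry at the composition level:

* cyclic rings need every unit difunctional and an exact diacid/diol balance
  (hydroxyacids insert freely and may also cyclize alone — lactones);
* linear chains allow an acid/ol imbalance of at most one (either end can be
  acid- or ol-terminated); hydroxyacids insert freely; monools only cap ends
  (at most two); tri-functional units (triols/triacids) force linear topology
  because a branched ring is under-determined at composition level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .chem import (
    ElementalFormula,
    Monomer,
    MonomerLibrary,
    WATER_MASS,
    combine_formulas,
)

__all__ = [
    "OligomerComposition",
    "NeutralOligomer",
    "ester_bond_count",
    "is_feasible",
    "neutral_mass",
    "oligomer_formula",
    "enumerate_oligomers",
    "oligomer_table",
    "DEFAULT_MAX_UNITS",
    "DEFAULT_MAX_MASS",
]

DEFAULT_MAX_UNITS = 8
#: Species above 1000 Da are toxicologically irrelevant (not absorbed through
#: the gastrointestinal tract) and are cut from the candidate database.
DEFAULT_MAX_MASS = 1000.0

TOPOLOGIES = ("linear", "cyclic")


@dataclass(frozen=True)
class OligomerComposition:
    """A multiset of monomer counts with a topology.

    ``monomer_counts`` is stored as a sorted tuple of (monomer_id, count)
    pairs so compositions are hashable and canonically ordered.
    """

    monomer_counts: tuple[tuple[str, int], ...]
    topology: str

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], topology: str) -> "OligomerComposition":
        if topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}, got {topology!r}")
        items = tuple(sorted((mid, c) for mid, c in counts.items() if c > 0))
        if not items:
            raise ValueError("composition must contain at least one monomer")
        if any(c < 1 for _, c in items):
            raise ValueError("monomer counts must be >= 1")
        return cls(items, topology)

    def as_dict(self) -> dict[str, int]:
        return dict(self.monomer_counts)

    @property
    def n_units(self) -> int:
        return sum(c for _, c in self.monomer_counts)

    @property
    def n_ester_bonds(self) -> int:
        return self.n_units if self.topology == "cyclic" else self.n_units - 1

    @property
    def n_distinct(self) -> int:
        return len(self.monomer_counts)

    @property
    def is_cyclic(self) -> bool:
        return self.topology == "cyclic"

    def composition_string(self) -> str:
        """Human-readable label like ``"2PA+2NPG"`` (counts of 1 unprefixed)."""
        parts = []
        for mid, c in self.monomer_counts:
            parts.append(mid if c == 1 else f"{c}{mid}")
        return "+".join(parts)

    def label(self) -> str:
        """Composition string with topology mark, e.g. ``"2PA+2NPG (C)"``."""
        return f"{self.composition_string()} ({'C' if self.is_cyclic else 'L'})"

    def __str__(self) -> str:
        return self.label()


@dataclass(frozen=True)
class NeutralOligomer:
    """A feasible composition with its neutral monoisotopic mass and formula."""

    composition: OligomerComposition
    mass: float
    formula: ElementalFormula

    @property
    def label(self) -> str:
        return self.composition.label()


def ester_bond_count(composition: OligomerComposition) -> int:
    """Number of ester bonds (= waters of condensation): n-1 linear, n cyclic."""
    return composition.n_ester_bonds


def _class_tallies(composition: OligomerComposition, library: MonomerLibrary):
    tallies = {cls: 0 for cls in ("diacid", "triacid", "diol", "triol", "monool", "hydroxyacid")}
    for mid, c in composition.monomer_counts:
        if mid not in library:
            raise KeyError(f"unknown monomer id {mid!r}")
        tallies[library[mid].monomer_class] += c
    return tallies


def is_feasible(composition: OligomerComposition, library: MonomerLibrary) -> tuple[bool, str]:
    """Whether a composition can exist as an ester chain/ring; returns
    ``(feasible, reason)`` with a human-readable reason on rejection."""
    t = _class_tallies(composition, library)
    n_acid_units = t["diacid"] + t["triacid"]
    n_ol_units = t["diol"] + t["triol"]
    if composition.is_cyclic:
        if t["triacid"] or t["triol"] or t["monool"]:
            return False, "cyclic topology requires all units difunctional"
        if t["diacid"] != t["diol"]:
            return False, (
                f"cyclic acid/diol imbalance ({t['diacid']} diacid vs {t['diol']} diol units)"
            )
        return True, "ok"
    # linear
    if t["monool"] > 2:
        return False, "more than two monool chain ends"
    if abs(n_acid_units - n_ol_units) > 1:
        return False, (
            f"linear chain cannot alternate ({n_acid_units} acid vs {n_ol_units} polyol units)"
        )
    return True, "ok"


def neutral_mass(composition: OligomerComposition, library: MonomerLibrary) -> float:
    """Monoisotopic neutral mass: sum of monomer masses minus one water per bond."""
    total = sum(library[mid].mass * c for mid, c in composition.monomer_counts)
    return total - composition.n_ester_bonds * WATER_MASS


def oligomer_formula(composition: OligomerComposition, library: MonomerLibrary) -> ElementalFormula:
    parts = []
    for mid, c in composition.monomer_counts:
        parts.append(library[mid].formula * c)
    return combine_formulas(parts, n_water_removed=composition.n_ester_bonds)


def make_oligomer(
    composition: OligomerComposition, library: MonomerLibrary
) -> NeutralOligomer:
    return NeutralOligomer(
        composition=composition,
        mass=neutral_mass(composition, library),
        formula=oligomer_formula(composition, library),
    )


def _count_vectors(
    monomers: Sequence[Monomer], max_units: int, max_mass: float
) -> Iterator[dict[str, int]]:
    """All count vectors with 1 <= total units <= max_units whose condensed
    mass can still be <= max_mass.  Mass pruning uses the cyclic bound (every
    unit loses one water), which is the lightest any topology can get."""
    n = len(monomers)

    def rec(i: int, counts: dict[str, int], units: int, residue_mass: float):
        if i == n:
            if units:
                yield dict(counts)
            return
        # zero copies of monomer i
        yield from rec(i + 1, counts, units, residue_mass)
        # k >= 1 copies; residue_mass is the cyclic-topology (lightest) mass
        # bound, so pruning on it never drops a feasible vector
        m = monomers[i]
        step = m.mass - WATER_MASS
        k = 1
        new_mass = residue_mass + step
        while units + k <= max_units and new_mass <= max_mass:
            counts[m.id] = k
            yield from rec(i + 1, counts, units + k, new_mass)
            k += 1
            new_mass += step
        counts.pop(m.id, None)

    yield from rec(0, {}, 0, 0.0)


def enumerate_oligomers(
    library: MonomerLibrary,
    max_units: int = DEFAULT_MAX_UNITS,
    max_mass: float = DEFAULT_MAX_MASS,
    topologies: Iterable[str] = TOPOLOGIES,
    include_monools: bool = False,
    include_trifunctional: bool = False,
) -> list[NeutralOligomer]:
    """Generate every feasible oligomer from *library* within the bounds.

    Monool chain caps and branched (tri-functional) species are excluded by
    default; tri-functional monomers, when enabled, only appear in linear
    compositions.  Output is deterministic: sorted by mass, then by canonical
    composition string, then topology.
    """
    if max_units < 1:
        raise ValueError("max_units must be >= 1")
    if max_mass <= 0:
        raise ValueError("max_mass must be > 0")
    topologies = tuple(topologies)
    for t in topologies:
        if t not in TOPOLOGIES:
            raise ValueError(f"unknown topology {t!r}")
    pool = [
        m
        for m in library
        if (include_monools or m.monomer_class != "monool")
        and (include_trifunctional or m.monomer_class not in ("triol", "triacid"))
    ]
    if not pool:
        return []
    out: list[NeutralOligomer] = []
    for counts in _count_vectors(pool, max_units, max_mass):
        for topo in topologies:
            comp = OligomerComposition.from_counts(counts, topo)
            ok, _ = is_feasible(comp, library)
            if not ok:
                continue
            mass = neutral_mass(comp, library)
            if mass > max_mass:
                continue
            out.append(make_oligomer(comp, library))
    out.sort(key=lambda o: (o.mass, o.composition.composition_string(), o.composition.topology))
    return out


def oligomer_table(oligomers: Sequence[NeutralOligomer]) -> pd.DataFrame:
    """Candidate-database export: one row per composition+topology."""
    return pd.DataFrame(
        {
            "composition": [o.composition.composition_string() for o in oligomers],
            "topology": [o.composition.topology for o in oligomers],
            "n_units": [o.composition.n_units for o in oligomers],
            "formula": [str(o.formula) for o in oligomers],
            "neutral_mass": [o.mass for o in oligomers],
        }
    )
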