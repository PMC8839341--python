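"""Elemental-formula arithmetic and the monomer registry.

All mass bookkeeping in the package reduces to integer element counts and
monoisotopic atomic masses.  Formulas are immutable mappings element -> count;
monomers are named building blocks (diacids, diols, ...) carrying a formula
and a functionality that the enumeration rules consume.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ATOMIC_MASS",
    "WATER_MASS",
    "ElementalFormula",
    "WATER",
    "parse_formula",
    "combine_formulas",
    "Monomer",
    "MonomerLibrary",
    "load_monomer_library",
    "default_library",
    "MONOMER_CLASSES",
]

# Monoisotopic atomic masses in Da, IUPAC/CIAAW values for the most abundant
# isotope.  Stored to >=9 decimal places; average masses are deliberately not
# used anywhere in the package.
ATOMIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.007825032,
    "N": 14.003074005,
    "O": 15.994914620,
    "S": 31.972071174,
    "P": 30.973761998,
    "Na": 22.989769282,
    "K": 38.963706486,
    "Cl": 34.968852682,
}

#: Monoisotopic mass of H2O; one ester condensation releases exactly one.
WATER_MASS: float = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]

_HILL_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or arithmetic that would go negative."""


@dataclass(frozen=True)
class ElementalFormula:
    """An immutable element -> count mapping with monoisotopic mass.

    Counts are non-negative integers; subtraction that would drive any count
    below zero raises :class:`FormulaError`.
    """

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        for el, n in counts.items():
            if el not in ATOMIC_MASS:
                raise FormulaError(f"unsupported element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer, got {n!r}")
        items = tuple(sorted((el, n) for el, n in counts.items() if n > 0))
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (0.0 for the empty formula)."""
        return sum(ATOMIC_MASS[el] * n for el, n in self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        c = Counter(dict(self.counts))
        c.update(dict(other.counts))
        return ElementalFormula.from_counts(c)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        c = Counter(dict(self.counts))
        c.subtract(dict(other.counts))
        if any(v < 0 for v in c.values()):
            raise FormulaError(f"subtraction {self} - {other} yields a negative element count")
        return ElementalFormula.from_counts(+c)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError("formula multiplier must be a non-negative integer")
        return ElementalFormula.from_counts({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalFormula({format_formula(self)!r})"


WATER = ElementalFormula.from_counts({"H": 2, "O": 1})


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``"C26H28O8"``.

    Supported elements are those in :data:`ATOMIC_MASS`; no isotope labels
    and no charges (ionization is handled downstream).
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Counter[str] = Counter()
    pos = 0
    for m in _HILL_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] += int(digits) if digits else 1
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula.from_counts(counts)


def format_formula(formula: ElementalFormula) -> str:
    """Hill order: C first, then H, then other elements alphabetically."""
    d = formula.as_dict()
    parts: list[str] = []
    for el in ("C", "H"):
        if el in d:
            n = d.pop(el)
            parts.append(el if n == 1 else f"{el}{n}")
    for el in sorted(d):
        n = d[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da of an :class:`ElementalFormula`."""
    return formula.mass


def combine_formulas(parts: Iterable[ElementalFormula], n_water_removed: int = 0) -> ElementalFormula:
    """Element-wise sum of *parts* minus ``n_water_removed`` waters.

    This is the condensation bookkeeping used everywhere: an oligomer formula
    is the sum of its monomer formulas minus one water per ester bond.
    """
    if n_water_removed < 0:
        raise FormulaError("n_water_removed must be >= 0")
    total = ElementalFormula.from_counts({})
    for p in parts:
        total = total + p
    if n_water_removed:
        total = total - (WATER * n_water_removed)
    return total


# ---------------------------------------------------------------------------
# Monomers
# ---------------------------------------------------------------------------

#: monomer_class -> (n_acid_groups, n_hydroxyl_groups)
MONOMER_CLASSES: Mapping[str, tuple[int, int]] = {
    "diacid": (2, 0),
    "triacid": (3, 0),
    "diol": (0, 2),
    "triol": (0, 3),
    "monool": (0, 1),
    "hydroxyacid": (1, 1),
}


@dataclass(frozen=True)
class Monomer:
    """A polyester building block.

    Hydroxyacids (e.g. ring-opened caprolactone) are stored in their open,
    hydrated acid form so that residue arithmetic (one water removed per
    ester bond) is uniform across classes.
    """

    id: str
    abbreviation: str
    name: str
    formula: ElementalFormula
    monomer_class: str
    aromatic: bool = False

    def __post_init__(self) -> None:
        if self.monomer_class not in MONOMER_CLASSES:
            raise ValueError(f"unknown monomer class {self.monomer_class!r} for {self.id}")
        if self.formula.mass <= 0:
            raise ValueError(f"monomer {self.id} has non-positive mass")

    @property
    def n_acid_groups(self) -> int:
        return MONOMER_CLASSES[self.monomer_class][0]

    @property
    def n_hydroxyl_groups(self) -> int:
        return MONOMER_CLASSES[self.monomer_class][1]

    @property
    def mass(self) -> float:
        return self.formula.mass

    @property
    def is_acid(self) -> bool:
        return self.monomer_class in ("diacid", "triacid")

    @property
    def is_polyol(self) -> bool:
        return self.monomer_class in ("diol", "triol", "monool")

    @property
    def difunctional(self) -> bool:
        return self.monomer_class in ("diacid", "diol", "hydroxyacid")


class LibraryError(ValueError):
    """Invalid monomer-library configuration."""


@dataclass
class MonomerLibrary:
    """An ordered collection of monomers with unique abbreviations."""

    monomers: Sequence[Monomer]
    provenance: str = ""
    _by_id: dict[str, Monomer] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.monomers:
            raise LibraryError("monomer library is empty")
        seen: set[str] = set()
        for m in self.monomers:
            for key in (m.id, m.abbreviation):
                pass
            if m.abbreviation in seen:
                raise LibraryError(f"duplicate abbreviation {m.abbreviation!r}")
            seen.add(m.abbreviation)
        ids = [m.id for m in self.monomers]
        if len(set(ids)) != len(ids):
            raise LibraryError("duplicate monomer ids")
        self._by_id = {m.id: m for m in self.monomers}
        self._by_id.update({m.abbreviation: m for m in self.monomers})

    def __iter__(self) -> Iterator[Monomer]:
        return iter(self.monomers)

    def __len__(self) -> int:
        return len(self.monomers)

    def __getitem__(self, key: str) -> Monomer:
        try:
            return self._by_id[key]
        except KeyError:
            raise KeyError(f"no monomer with id or abbreviation {key!r}") from None

    def __contains__(self, key: str) -> bool:
        return key in self._by_id

    def subset(self, ids: Iterable[str], provenance: str = "subset") -> "MonomerLibrary":
        return MonomerLibrary([self[i] for i in ids], provenance=provenance)

    def acids(self) -> list[Monomer]:
        return [m for m in self.monomers if m.is_acid]

    def polyols(self) -> list[Monomer]:
        return [m for m in self.monomers if m.is_polyol]

    def hydroxyacids(self) -> list[Monomer]:
        return [m for m in self.monomers if m.monomer_class == "hydroxyacid"]

    def isobaric_groups(self) -> dict[str, list[Monomer]]:
        """Group monomers by formula; groups of size > 1 are indistinguishable
        by mass alone (e.g. the phthalic-acid isomers, or 1,4-/1,3-butanediol
        and 2-methyl-1,3-propanediol)."""
        groups: dict[str, list[Monomer]] = {}
        for m in self.monomers:
            groups.setdefault(format_formula(m.formula), []).append(m)
        return groups

    def isobaric_group_of(self, monomer_id: str) -> tuple[str, ...]:
        """Ids of all library monomers sharing this monomer's formula."""
        target = format_formula(self[monomer_id].formula)
        return tuple(sorted(m.id for m in self.monomers if format_formula(m.formula) == target))


_LIBRARY_COLUMNS = ("id", "abbreviation", "name", "formula", "class", "aromatic")


def load_monomer_library(path: str | Path) -> MonomerLibrary:
    """Load a monomer library from a CSV config file.

    One record per monomer with columns ``id, abbreviation, name, formula,
    class, aromatic``; lines starting with ``#`` are comments.
    """
    path = Path(path)
    monomers: list[Monomer] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(filter(lambda ln: not ln.lstrip().startswith("#"), fh))]
    if not rows:
        raise LibraryError(f"no monomer records in {path}")
    for i, row in enumerate(rows):
        missing = [c for c in _LIBRARY_COLUMNS if not (row.get(c) or "").strip()]
        if missing:
            raise LibraryError(f"{path} record {i + 1}: missing field(s) {missing}")
        monomers.append(
            Monomer(
                id=row["id"].strip(),
                abbreviation=row["abbreviation"].strip(),
                name=row["name"].strip(),
                formula=parse_formula(row["formula"]),
                monomer_class=row["class"].strip(),
                aromatic=row["aromatic"].strip().lower() in ("1", "true", "yes", "y"),
            )
        )
    return MonomerLibrary(monomers, provenance=str(path))


def default_library() -> MonomerLibrary:
    """The built-in monomer library.

    Covers the starting substances commonly used to formulate polyester
    food-contact coatings: the five diacids and one triacid used as analytical
    standards in migration screening, the major coating diols, two triols, and
    ring-opened caprolactone.  Real formulations draw from a larger pool of
    polyols; this default is an approximation and is user-extensible via
    :func:`load_monomer_library`.
    """
    path = Path(__file__).parent / "data" / "default_monomers.csv"
    lib = load_monomer_library(path)
    lib.provenance = "oligomig built-in default"
    return lib
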