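"""Adduct ion computation: neutral species -> observable singly charged ions.

Positive-mode MALDI and ESI observe polyester oligomers as [M+H]+, [M+NH4]+,
[M+Na]+ and [M+K]+ (sodium dominates under NaTFA cationization); the targeted
acid-monomer screen runs in negative mode on [M-H]-.  Charge states beyond
|z| = 1 do not occur for these species at these masses and are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import Monomer, MonomerLibrary
from .enumeration import NeutralOligomer

__all__ = [
    "Adduct",
    "ADDUCTS",
    "POSITIVE_ADDUCTS",
    "adduct_mz",
    "CandidateIon",
    "build_ion_table",
    "targeted_acid_precursors",
]


@dataclass(frozen=True)
class Adduct:
    """A named ionization channel with its exact mass shift.

    ``mass_delta`` already accounts for the electron, e.g. +22.989218 Da for
    sodium cationization (Na minus one electron).
    """

    name: str
    charge: int
    mass_delta: float


ADDUCTS: Mapping[str, Adduct] = {
    "M+H": Adduct("M+H", +1, +1.007276),
    "M+NH4": Adduct("M+NH4", +1, +18.033823),
    "M+Na": Adduct("M+Na", +1, +22.989218),
    "M+K": Adduct("M+K", +1, +38.963158),
    "M-H": Adduct("M-H", -1, -1.007276),
}

POSITIVE_ADDUCTS: tuple[str, ...] = ("M+H", "M+NH4", "M+Na", "M+K")


def get_adduct(adduct: str | Adduct) -> Adduct:
    if isinstance(adduct, Adduct):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise KeyError(f"unsupported adduct {adduct!r}; known: {sorted(ADDUCTS)}") from None


def adduct_mz(neutral_mass: float, adduct: str | Adduct) -> float:
    """m/z of a singly charged adduct ion of a neutral of given mass."""
    return neutral_mass + get_adduct(adduct).mass_delta


@dataclass(frozen=True)
class CandidateIon:
    """An observable ion: a neutral species paired with an adduct."""

    neutral: NeutralOligomer | Monomer
    adduct: Adduct
    mz: float

    @property
    def label(self) -> str:
        if isinstance(self.neutral, Monomer):
            return f"{self.neutral.id} [{self.adduct.name}]"
        return f"{self.neutral.label} [{self.adduct.name}]"


def build_ion_table(
    oligomers: Sequence[NeutralOligomer],
    adducts: Iterable[str | Adduct] = POSITIVE_ADDUCTS,
) -> pd.DataFrame:
    """Cross product of neutrals and adducts, sorted by m/z.

    Columns: composition, topology, n_units, n_distinct, formula,
    neutral_mass, adduct, mz.  The ``n_distinct``/``n_units`` columns feed the
    annotation tie-break (prefer simpler compositions).
    """
    adduct_objs = [get_adduct(a) for a in adducts]
    rows = []
    for o in oligomers:
        for a in adduct_objs:
            rows.append(
                {
                    "composition": o.composition.composition_string(),
                    "topology": o.composition.topology,
                    "n_units": o.composition.n_units,
                    "n_distinct": o.composition.n_distinct,
                    "formula": str(o.formula),
                    "neutral_mass": o.mass,
                    "adduct": a.name,
                    "mz": o.mass + a.mass_delta,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "composition",
            "topology",
            "n_units",
            "n_distinct",
            "formula",
            "neutral_mass",
            "adduct",
            "mz",
        ],
    )
    return df.sort_values(["mz", "composition", "adduct"], kind="mergesort").reset_index(drop=True)


def targeted_acid_precursors(library: MonomerLibrary) -> pd.DataFrame:
    """Deprotonated [M-H]- precursors for every polyacid monomer.

    These are the exact-mass centers of the unit-resolution windows used in a
    targeted negative-mode screen for free acid monomers.  Returns an empty
    frame when the library holds no acids.
    """
    deprot = ADDUCTS["M-H"]
    rows = []
    for m in library.acids():
        rows.append(
            {
                "monomer": m.id,
                "name": m.name,
                "formula": str(m.formula),
                "neutral_mass": m.mass,
                "adduct": deprot.name,
                "mz": m.mass + deprot.mass_delta,
            }
        )
    df = pd.DataFrame(rows, columns=["monomer", "name", "formula", "neutral_mass", "adduct", "mz"])
    return df.sort_values("mz", kind="mergesort").reset_index(drop=True)
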