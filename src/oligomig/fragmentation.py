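"""Ester-cleavage fragment enumeration for MSn product-ion annotation.

Collision-induced dissociation of a protonated polyester oligomer cleaves
ester bonds, losing whole monomer residues (monomer - H2O) or free monomers.
At composition level every product ion is therefore a sub-multiset of the
parent's monomer counts with some number of water equivalents removed, plus a
proton.  That combinatorial view reproduces the diagnostic ions seen for
these coatings (e.g. protonated dehydrated phthalic acid at m/z 149, the
protonated acid+diol repeat at m/z 235) without modelling bond-resolved
structures — a documented heuristic, not a fragmentation physics model.

Sodiated and ammoniated precursors do not fragment usefully in an ion trap
(the charge stays on the cation); for them enumeration returns nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iter_product
from typing import Sequence

import pandas as pd

from .chem import MonomerLibrary, WATER_MASS
from .enumeration import NeutralOligomer
from .ionization import Adduct, get_adduct

__all__ = [
    "FragmentCandidate",
    "enumerate_fragments",
    "annotate_product_ions",
    "DEFAULT_PRODUCT_ION_TOL",
]

PROTON = 1.007276

#: unit-resolution ion-trap product ions are printed at integer precision
DEFAULT_PRODUCT_ION_TOL = 0.5


@dataclass(frozen=True)
class FragmentCandidate:
    """A candidate product ion: sub-composition + water-equivalents lost."""

    monomer_counts: tuple[tuple[str, int], ...]
    n_water_lost: int
    mz: float
    description: str

    @property
    def n_units(self) -> int:
        return sum(c for _, c in self.monomer_counts)


def _sub_label(counts: dict[str, int], n_water: int) -> str:
    body = "+".join(mid if c == 1 else f"{c}{mid}" for mid, c in sorted(counts.items()))
    return f"{body} - {n_water} H2O, protonated"


def enumerate_fragments(
    parent: NeutralOligomer,
    precursor_adduct: str | Adduct,
    library: MonomerLibrary,
    max_depth: int | None = None,
) -> list[FragmentCandidate]:
    """All composition-level product ions of a protonated parent.

    Every non-empty sub-multiset of the parent's monomer counts is a
    candidate, with water-equivalent losses ranging from (units - 1) to
    (units + 1) — i.e. fully condensed chain, ring-like, or one extra water
    loss — floored at zero; the full parent composition additionally extends
    to (parent ester bonds + 2) to cover the sequential water-loss ladder
    from the precursor.  Candidates are deduplicated by m/z (keeping the
    simplest composition) and all lie strictly below the precursor m/z.

    For non-protonated precursors (sodium, ammonium, potassium adducts) no
    fragmentation is modelled: returns an empty list.
    """
    adduct = get_adduct(precursor_adduct)
    if adduct.name != "M+H":
        return []
    counts = parent.composition.as_dict()
    if max_depth is None:
        max_depth = sum(counts.values())
    precursor_mz = parent.mass + adduct.mass_delta
    ids = sorted(counts)
    masses = {mid: library[mid].mass for mid in ids}
    parent_key = tuple(sorted(counts.items()))
    best: dict[float, FragmentCandidate] = {}
    for combo in iter_product(*(range(counts[mid] + 1) for mid in ids)):
        sub = {mid: k for mid, k in zip(ids, combo) if k > 0}
        if not sub:
            continue
        units = sum(sub.values())
        if sum(counts.values()) - units > max_depth and sub != counts:
            continue
        total = sum(masses[mid] * k for mid, k in sub.items())
        w_lo = max(0, units - 1)
        w_hi = units + 1
        if tuple(sorted(sub.items())) == parent_key:
            w_hi = max(w_hi, parent.composition.n_ester_bonds + 2)
        for w in range(w_lo, w_hi + 1):
            mz = total - w * WATER_MASS + PROTON
            if mz >= precursor_mz - 1e-9 or mz <= PROTON:
                continue
            cand = FragmentCandidate(
                monomer_counts=tuple(sorted(sub.items())),
                n_water_lost=w,
                mz=mz,
                description=_sub_label(sub, w),
            )
            key = round(mz, 6)
            prev = best.get(key)
            if prev is None or (cand.n_units, cand.description) < (prev.n_units, prev.description):
                best[key] = cand
    return sorted(best.values(), key=lambda c: c.mz)


def annotate_product_ions(
    observed: Sequence[float],
    candidates: Sequence[FragmentCandidate],
    tol: float = DEFAULT_PRODUCT_ION_TOL,
) -> pd.DataFrame:
    """Match observed product-ion m/z values to the nearest candidate.

    One row per observed ion; ions with no candidate within *tol* appear with
    ``matched=False`` and empty assignment fields.
    """
    rows = []
    for mz_obs in observed:
        nearest = None
        nearest_err = None
        for c in candidates:
            err = mz_obs - c.mz
            if nearest_err is None or abs(err) < abs(nearest_err):
                nearest, nearest_err = c, err
        if nearest is not None and abs(nearest_err) <= tol:
            rows.append(
                {
                    "mz_observed": float(mz_obs),
                    "matched": True,
                    "assignment": nearest.description,
                    "mz_theoretical": nearest.mz,
                    "error_da": float(nearest_err),
                }
            )
        else:
            rows.append(
                {
                    "mz_observed": float(mz_obs),
                    "matched": False,
                    "assignment": "",
                    "mz_theoretical": float("nan"),
                    "error_da": float("nan"),
                }
            )
    return pd.DataFrame(
        rows, columns=["mz_observed", "matched", "assignment", "mz_theoretical", "error_da"]
    )
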