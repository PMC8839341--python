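"""Cramer-class triage and TTC exposure thresholds for annotated oligomers.

When no substance-specific toxicology exists, the threshold of toxicological
concern (TTC) framework assigns a tolerable daily exposure by structural
class: Cramer I (simple, efficiently metabolised) 30 ug/kg bw/day, Cramer II
9, Cramer III (no strong presumption of safety) 1.5.

This module implements only the summary rule observed for polyester
oligomers: cyclic species containing an aromatic dicarboxylic acid are
Cramer III; linear species are Cramer I; anything else (e.g. cyclic lactone
homopolymers) is left unresolved and flagged for a full decision-tree
evaluation rather than guessed.  The rule is a heuristic consistent with the
reference assignments shipped with the package, not a replacement for the
33-question Cramer scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .chem import MonomerLibrary
from .enumeration import NeutralOligomer, OligomerComposition

__all__ = ["TTC_THRESHOLDS", "CramerAssignment", "assign_cramer", "classify_report"]

#: Tolerable daily exposure (ug per kg body weight per day) by Cramer class.
TTC_THRESHOLDS: dict[str, float] = {"I": 30.0, "II": 9.0, "III": 1.5}


@dataclass(frozen=True)
class CramerAssignment:
    cramer_class: str  # "I" | "II" | "III" | "unresolved"
    ttc_threshold: float | None  # ug/kg bw/day; None when unresolved
    rule_fired: str


def assign_cramer(
    oligomer: NeutralOligomer | OligomerComposition, library: MonomerLibrary
) -> CramerAssignment:
    """Apply the topology/aromaticity heuristic to one oligomer."""
    comp = oligomer.composition if isinstance(oligomer, NeutralOligomer) else oligomer
    has_aromatic_diacid = any(
        library[mid].aromatic and library[mid].monomer_class == "diacid"
        for mid, _ in comp.monomer_counts
    )
    if comp.is_cyclic and has_aromatic_diacid:
        return CramerAssignment(
            "III",
            TTC_THRESHOLDS["III"],
            "cyclic oligomer containing an aromatic dicarboxylic acid -> Cramer III",
        )
    if not comp.is_cyclic:
        return CramerAssignment("I", TTC_THRESHOLDS["I"], "linear oligomer -> Cramer I")
    return CramerAssignment(
        "unresolved",
        None,
        "cyclic without aromatic diacid: outside the heuristic, needs full Cramer tree",
    )


def classify_report(
    oligomers: Iterable[NeutralOligomer | OligomerComposition],
    library: MonomerLibrary,
) -> pd.DataFrame:
    """Per-compound safety table with class counts available via value_counts."""
    rows = []
    for o in oligomers:
        comp = o.composition if isinstance(o, NeutralOligomer) else o
        a = assign_cramer(o, library)
        rows.append(
            {
                "composition": comp.composition_string(),
                "topology": comp.topology,
                "cramer_class": a.cramer_class,
                "ttc_threshold_ug_per_kg_bw_day": a.ttc_threshold,
                "rule_fired": a.rule_fired,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "composition",
            "topology",
            "cramer_class",
            "ttc_threshold_ug_per_kg_bw_day",
            "rule_fired",
        ],
    )
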