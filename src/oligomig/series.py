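"""Homologous-series detection and monomer-set inference for MALDI spectra.

A polyester built from one diacid and one diol shows peaks in arithmetic
progression spaced by the repeat-unit mass (diacid + diol - 2 H2O); lactone
homopolymers (caprolactone) repeat at monomer - H2O.  Substituting one diol
for another shifts whole series by the diol mass difference — the
"monomer-exchange" deltas (e.g. +14 Da for neopentyl glycol -> 1,6-hexanediol).
This module turns that manual reading of a spectrum into an algorithm:
detect progressions by greedy nearest-peak chaining, tabulate exchange-delta
evidence, and rank the monomer subsets the evidence supports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import MonomerLibrary, WATER_MASS
from .annotation import PeakList

__all__ = [
    "RepeatUnit",
    "candidate_repeat_units",
    "SeriesHit",
    "detect_series",
    "detect_exchange_deltas",
    "InferredMonomerSet",
    "infer_monomer_set",
    "series_table",
    "DEFAULT_SERIES_TOL",
    "DEFAULT_MIN_LENGTH",
]

#: Da window for chaining consecutive series members (reflector MALDI data).
DEFAULT_SERIES_TOL = 0.2
#: Minimum members before a progression counts as a series.
DEFAULT_MIN_LENGTH = 3


@dataclass(frozen=True)
class RepeatUnit:
    """The residue whose mass separates consecutive homologue peaks.

    Either one diacid + one diol minus two waters, or one hydroxyacid minus
    one water.  ``member_ids`` lists every isobaric (acid, diol) pairing that
    shares this mass.
    """

    label: str
    mass: float
    acid_ids: tuple[str, ...]
    diol_ids: tuple[str, ...]
    member_ids: tuple[tuple[str, ...], ...] = ()

    @property
    def is_lactone(self) -> bool:
        return not self.diol_ids


def candidate_repeat_units(
    library: MonomerLibrary, dedup_decimals: int = 6
) -> list[RepeatUnit]:
    """All acid+diol pair units and hydroxyacid units, collapsed by mass.

    Isobaric monomers (e.g. the phthalic-acid isomers) produce one unit whose
    label joins the alternatives with ``/``.
    """
    raw: dict[float, list[tuple[str, tuple[str, ...], tuple[str, ...]]]] = {}

    def add(label: str, mass: float, acids: tuple[str, ...], diols: tuple[str, ...]):
        key = round(mass, dedup_decimals)
        raw.setdefault(key, []).append((label, acids, diols))

    for acid in [m for m in library if m.monomer_class == "diacid"]:
        for diol in [m for m in library if m.monomer_class == "diol"]:
            mass = acid.mass + diol.mass - 2 * WATER_MASS
            add(f"{acid.id}+{diol.id}", mass, (acid.id,), (diol.id,))
    for ha in library.hydroxyacids():
        add(ha.id, ha.mass - WATER_MASS, (ha.id,), ())

    units: list[RepeatUnit] = []
    for key in sorted(raw):
        entries = raw[key]
        acids = tuple(sorted({a for _, accs, _ in entries for a in accs}))
        diols = tuple(sorted({d for _, _, dls in entries for d in dls}))
        label = "/".join(sorted({lbl for lbl, _, _ in entries}))
        members = tuple(sorted({(*accs, *dls) for _, accs, dls in entries}))
        units.append(RepeatUnit(label=label, mass=key, acid_ids=acids, diol_ids=diols, member_ids=members))
    return units


@dataclass(frozen=True)
class SeriesHit:
    """One detected arithmetic progression of peaks."""

    unit: RepeatUnit
    member_indices: tuple[int, ...]
    base_mz: float
    mean_abs_deviation: float

    @property
    def n_members(self) -> int:
        return len(self.member_indices)


def detect_series(
    peaks: PeakList,
    unit: RepeatUnit,
    tol: float = DEFAULT_SERIES_TOL,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[SeriesHit]:
    """Maximal non-extendable chains p0, p0+u, p0+2u, ... within *tol* per step.

    Greedy nearest-peak chaining anchored at the base peak: the i-th expected
    position is base + i*u (extrapolated from the base, so random centroid
    errors do not compound along the chain), and the nearest peak within
    *tol* of it is taken.  Chains end at the first gap; overlapping series
    (sharing peaks) are allowed.  Deterministic for a given peak list.
    """
    mz = peaks.mz
    n = mz.size
    if n == 0:
        return []

    def nearest_within(target: float) -> int | None:
        j = int(np.searchsorted(mz, target))
        best, best_err = None, tol
        for k in (j - 1, j):
            if 0 <= k < n:
                err = abs(mz[k] - target)
                if err <= best_err:
                    best, best_err = k, err
        return best

    hits: list[SeriesHit] = []
    seen: set[tuple[int, ...]] = set()
    for start in range(n):
        # only start chains at peaks with no predecessor (maximality)
        if nearest_within(mz[start] - unit.mass) is not None:
            continue
        chain = [start]
        deviations: list[float] = []
        while True:
            target = mz[start] + len(chain) * unit.mass
            nxt = nearest_within(target)
            if nxt is None:
                break
            deviations.append(abs(mz[nxt] - target))
            chain.append(nxt)
        if len(chain) >= min_length:
            key = tuple(chain)
            if key not in seen:
                seen.add(key)
                hits.append(
                    SeriesHit(
                        unit=unit,
                        member_indices=key,
                        base_mz=float(mz[start]),
                        mean_abs_deviation=float(np.mean(deviations)) if deviations else 0.0,
                    )
                )
    return hits


def detect_exchange_deltas(
    peaks: PeakList,
    library: MonomerLibrary,
    tol: float = DEFAULT_SERIES_TOL,
) -> pd.DataFrame:
    """Evidence table for monomer-exchange mass shifts between diols.

    For every ordered diol pair (out, in) with distinct masses, counts peak
    pairs whose spacing matches mass(in) - mass(out) within *tol*.  Shifts of
    zero (isobaric diols) are excluded — they are undetectable by mass.
    """
    if len(peaks) < 2:
        return pd.DataFrame(columns=["monomer_out", "monomer_in", "delta", "n_peak_pairs"])
    mz = peaks.mz
    diols = [m for m in library if m.monomer_class == "diol"]
    rows = []
    for a, b in permutations(diols, 2):
        delta = b.mass - a.mass
        if delta <= 0:
            continue  # keep one orientation; the reverse is the same evidence
        lo = np.searchsorted(mz, mz + delta - tol, side="left")
        hi = np.searchsorted(mz, mz + delta + tol, side="right")
        count = int(np.sum(hi - lo))
        rows.append(
            {"monomer_out": a.id, "monomer_in": b.id, "delta": delta, "n_peak_pairs": count}
        )
    df = pd.DataFrame(rows, columns=["monomer_out", "monomer_in", "delta", "n_peak_pairs"])
    return df.sort_values(
        ["n_peak_pairs", "monomer_out", "monomer_in"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class InferredMonomerSet:
    """A candidate monomer subset with the evidence that supports it.

    ``monomer_groups`` are isobaric groups (tuples of ids sharing one
    formula) — mass spectra cannot separate within a group.  ``diol_ranking``
    orders the diol groups by the summed intensity of the series peaks each
    explains (ordinal only, no quantification claim).
    """

    monomer_groups: tuple[tuple[str, ...], ...]
    n_series_members: int
    n_exchange_confirmations: int
    diol_ranking: tuple[tuple[tuple[str, ...], float], ...]
    series: list[SeriesHit]

    @property
    def score(self) -> tuple[int, int]:
        return (self.n_series_members, self.n_exchange_confirmations)


def infer_monomer_set(
    peaks: PeakList,
    library: MonomerLibrary,
    tol: float = DEFAULT_SERIES_TOL,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_rel_intensity: float = 0.01,
) -> list[InferredMonomerSet]:
    """Rank the monomer subsets supported by series and exchange evidence.

    Series reading emulates how an analyst works a MALDI spectrum: peaks
    below ``min_rel_intensity`` of the base peak are treated as grass and
    ignored.  For every candidate repeat unit, series are detected; units
    with at least one series contribute their monomers (as isobaric groups).
    Acid-based units sharing an acid group are merged into one subset holding
    all of that acid's supported diols; lactone units form their own subsets.
    Subsets are ranked by (series members explained, exchange confirmations).
    Within a subset, diols are ranked by their intensity-weighted share of
    the rank-1 composition assignments of the series peaks (ordinal only).
    """
    if min_rel_intensity > 0 and len(peaks) and peaks.intensity.max() > 0:
        floor = min_rel_intensity * float(peaks.intensity.max())
        mask = peaks.intensity >= floor
        picked = PeakList(
            mz=peaks.mz[mask],
            intensity=peaks.intensity[mask],
            instrument=peaks.instrument,
            tolerance=peaks.tolerance,
        )
    else:
        picked = peaks

    units = candidate_repeat_units(library)
    supported: list[tuple[RepeatUnit, list[SeriesHit]]] = []
    for u in units:
        hits = detect_series(picked, u, tol=tol, min_length=min_length)
        if hits:
            supported.append((u, hits))

    exchange = detect_exchange_deltas(picked, library, tol=tol)

    def group_of(mid: str) -> tuple[str, ...]:
        return library.isobaric_group_of(mid)

    # merge units by the isobaric group of their acid component
    by_acid: dict[tuple[str, ...], list[tuple[RepeatUnit, list[SeriesHit]]]] = {}
    for u, hits in supported:
        acid_group = tuple(sorted({g for a in u.acid_ids for g in group_of(a)}))
        by_acid.setdefault(acid_group, []).append((u, hits))

    results: list[InferredMonomerSet] = []
    for acid_group, entries in by_acid.items():
        groups: set[tuple[str, ...]] = {acid_group}
        diol_groups: set[tuple[str, ...]] = set()
        all_hits: list[SeriesHit] = []
        explained: set[int] = set()
        n_members = 0
        for u, hits in entries:
            all_hits.extend(hits)
            explained.update(i for h in hits for i in h.member_indices)
            n_members += sum(h.n_members for h in hits)
            for d in u.diol_ids:
                g = group_of(d)
                groups.add(g)
                diol_groups.add(g)
        n_exch = 0
        if not exchange.empty:
            for _, row in exchange.iterrows():
                if row["n_peak_pairs"] < 1:
                    continue
                g_out, g_in = group_of(row["monomer_out"]), group_of(row["monomer_in"])
                if g_out in diol_groups and g_in in diol_groups:
                    n_exch += int(row["n_peak_pairs"])
        ranking = _rank_diols_by_annotation(
            picked, library, acid_group, sorted(diol_groups), sorted(explained), tol
        )
        results.append(
            InferredMonomerSet(
                monomer_groups=tuple(sorted(groups)),
                n_series_members=n_members,
                n_exchange_confirmations=n_exch,
                diol_ranking=ranking,
                series=all_hits,
            )
        )
    results.sort(key=lambda r: (-r.n_series_members, -r.n_exchange_confirmations, r.monomer_groups))
    return results


def _rank_diols_by_annotation(
    peaks: PeakList,
    library: MonomerLibrary,
    acid_group: tuple[str, ...],
    diol_groups: Sequence[tuple[str, ...]],
    peak_indices: Sequence[int],
    tol: float,
) -> tuple[tuple[tuple[str, ...], float], ...]:
    """Diol proportion ranking: annotate the series peaks against the
    inferred subset and sum intensity-weighted diol shares of the rank-1
    compositions.  Tall peaks are dominated by the high-proportion diol, so
    this reproduces the analyst's intensity reading."""
    from .annotation import MassTolerance, match_peaks
    from .enumeration import enumerate_oligomers
    from .ionization import POSITIVE_ADDUCTS, build_ion_table

    if not diol_groups or not peak_indices:
        return ()
    reps = [g[0] for g in ([acid_group] + list(diol_groups))]
    group_of_rep = {g[0]: g for g in diol_groups}
    sub = library.subset(reps, provenance="series inference")
    max_mass = float(peaks.mz[list(peak_indices)].max()) + 50.0
    ions = build_ion_table(enumerate_oligomers(sub, max_mass=max_mass), POSITIVE_ADDUCTS)
    series_peaks = PeakList(
        mz=peaks.mz[list(peak_indices)],
        intensity=peaks.intensity[list(peak_indices)],
        instrument=peaks.instrument,
        tolerance=peaks.tolerance,
    )
    matches = match_peaks(series_peaks, ions, MassTolerance(tol, "da"))
    score: dict[tuple[str, ...], float] = {g: 0.0 for g in diol_groups}
    if not matches.empty:
        top = matches[matches["rank"] == 1]
        for _, row in top.iterrows():
            comp = row["composition"]
            counts: dict[str, int] = {}
            for token in comp.split("+"):
                m = re.match(r"(\d*)([A-Za-z][A-Za-z0-9]*)", token)
                k = int(m.group(1)) if m.group(1) else 1
                counts[m.group(2)] = counts.get(m.group(2), 0) + k
            diol_units = {
                mid: c for mid, c in counts.items() if mid in group_of_rep
            }
            total = sum(diol_units.values())
            if not total:
                continue
            for mid, c in diol_units.items():
                score[group_of_rep[mid]] += row["intensity"] * c / total
    return tuple(sorted(score.items(), key=lambda kv: (-kv[1], kv[0])))


def series_table(hits: Sequence[SeriesHit]) -> pd.DataFrame:
    """Series report export: one row per detected progression."""
    return pd.DataFrame(
        {
            "repeat_composition": [h.unit.label for h in hits],
            "repeat_mass": [h.unit.mass for h in hits],
            "n_members": [h.n_members for h in hits],
            "base_mz": [h.base_mz for h in hits],
            "member_indices": [";".join(map(str, h.member_indices)) for h in hits],
            "mean_abs_deviation": [h.mean_abs_deviation for h in hits],
        }
    )
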