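"""Peak-list annotation: match observed centroids against a candidate ion table.

Matching is tolerance-window based (ppm for reflector MALDI-TOF, absolute Da
for a unit-resolution ion trap).  Every candidate within the window is
reported — isobaric ambiguity is intrinsic to composition-level annotation —
with rank 1 given to the smallest absolute error; ties prefer compositions
with fewer distinct monomers, then fewer units, then the canonical string.
Intensity is carried through but never used for ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import MonomerLibrary
from .enumeration import enumerate_oligomers, DEFAULT_MAX_MASS, DEFAULT_MAX_UNITS
from .ionization import POSITIVE_ADDUCTS, build_ion_table

__all__ = [
    "MassTolerance",
    "PeakList",
    "match_peaks",
    "AnnotationReport",
    "annotate_run",
    "INSTRUMENT_DEFAULTS",
]


@dataclass(frozen=True)
class MassTolerance:
    """A symmetric match window, either relative (ppm) or absolute (Da)."""

    value: float
    unit: str = "ppm"  # "ppm" | "da"

    def __post_init__(self) -> None:
        if self.unit not in ("ppm", "da"):
            raise ValueError(f"tolerance unit must be 'ppm' or 'da', got {self.unit!r}")
        if self.value <= 0:
            raise ValueError("tolerance must be positive")

    def window_da(self, mz: float | np.ndarray) -> float | np.ndarray:
        """Half-width of the window in Da at a given m/z."""
        if self.unit == "ppm":
            return np.abs(mz) * self.value * 1e-6
        return self.value


#: Per-instrument defaults: acquisition window and match tolerance.
INSTRUMENT_DEFAULTS: Mapping[str, dict] = {
    "maldi_tof": {"window": (350.0, 4000.0), "tolerance": MassTolerance(10.0, "ppm")},
    "ion_trap": {"window": (100.0, 1000.0), "tolerance": MassTolerance(0.3, "da")},
    "generic": {"window": (0.0, float("inf")), "tolerance": MassTolerance(0.3, "da")},
}


@dataclass(frozen=True)
class PeakList:
    """A centroided spectrum: parallel m/z and intensity arrays.

    Peaks are kept sorted ascending in m/z (auto-sorted with a warning if
    supplied unsorted); intensities must be non-negative.
    """

    mz: np.ndarray
    intensity: np.ndarray
    instrument: str = "generic"
    tolerance: MassTolerance | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        if self.instrument not in INSTRUMENT_DEFAULTS:
            raise ValueError(
                f"unknown instrument {self.instrument!r}; known: {sorted(INSTRUMENT_DEFAULTS)}"
            )
        if mz.size and np.any(np.diff(mz) < 0):
            warnings.warn("peak list was not sorted by m/z; sorting", stacklevel=2)
            order = np.argsort(mz, kind="mergesort")
            mz, inten = mz[order], inten[order]
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if self.tolerance is None:
            object.__setattr__(
                self, "tolerance", INSTRUMENT_DEFAULTS[self.instrument]["tolerance"]
            )

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def window(self) -> tuple[float, float]:
        return INSTRUMENT_DEFAULTS[self.instrument]["window"]

    def with_tolerance(self, tolerance: MassTolerance) -> "PeakList":
        return replace(self, tolerance=tolerance)


_MATCH_COLUMNS = [
    "peak_index",
    "mz_observed",
    "intensity",
    "composition",
    "topology",
    "adduct",
    "formula",
    "mz_theoretical",
    "error_da",
    "error_ppm",
    "rank",
    "isobaric_note",
]


def match_peaks(
    peaks: PeakList,
    ions: pd.DataFrame,
    tolerance: MassTolerance | None = None,
) -> pd.DataFrame:
    """All (peak, candidate-ion) pairs within the tolerance window.

    ``error_da`` is signed, observed minus theoretical.  ``rank`` is per peak,
    1 = smallest |error|; ``isobaric_note`` lists, for rank-tied candidates at
    (numerically) identical theoretical m/z, how many candidates share that
    mass.  Peaks with no candidate are absent from the output (see
    :func:`annotate_run` for the unassigned list).
    """
    if ions.empty:
        raise ValueError("candidate ion table is empty")
    tol = tolerance or peaks.tolerance
    theo = ions["mz"].to_numpy()
    order = np.argsort(theo, kind="mergesort")
    theo_sorted = theo[order]
    rows = []
    for i, (mz_obs, inten) in enumerate(zip(peaks.mz, peaks.intensity)):
        half = float(tol.window_da(mz_obs))
        lo = np.searchsorted(theo_sorted, mz_obs - half, side="left")
        hi = np.searchsorted(theo_sorted, mz_obs + half, side="right")
        for j in order[lo:hi]:
            ion = ions.iloc[j]
            err = mz_obs - ion["mz"]
            rows.append(
                {
                    "peak_index": i,
                    "mz_observed": mz_obs,
                    "intensity": inten,
                    "composition": ion["composition"],
                    "topology": ion.get("topology", ""),
                    "adduct": ion["adduct"],
                    "formula": ion.get("formula", ""),
                    "mz_theoretical": ion["mz"],
                    "error_da": err,
                    "error_ppm": err / ion["mz"] * 1e6,
                    "rank": 0,
                    "isobaric_note": "",
                    "_n_distinct": ion.get("n_distinct", 0),
                    "_n_units": ion.get("n_units", 0),
                }
            )
    if not rows:
        return pd.DataFrame(columns=_MATCH_COLUMNS)
    df = pd.DataFrame(rows)
    df["_abs_err"] = df["error_da"].abs()
    df = df.sort_values(
        ["peak_index", "_abs_err", "_n_distinct", "_n_units", "composition", "adduct"],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("peak_index").cumcount() + 1
    # flag exact-isobar groups (identical theoretical m/z within 1e-9)
    key = df["mz_theoretical"].round(9)
    sizes = df.groupby(["peak_index", key])["composition"].transform("size")
    df.loc[sizes > 1, "isobaric_note"] = sizes[sizes > 1].map(
        lambda n: f"{n} isobaric candidates"
    )
    return df[_MATCH_COLUMNS]


@dataclass
class AnnotationReport:
    """Output of :func:`annotate_run`: matches plus unassigned peaks and
    summary counts."""

    matches: pd.DataFrame
    unassigned: pd.DataFrame
    summary: dict

    def top_matches(self) -> pd.DataFrame:
        """Rank-1 assignment per peak."""
        if self.matches.empty:
            return self.matches
        return self.matches[self.matches["rank"] == 1].reset_index(drop=True)


def annotate_run(
    peaks: PeakList,
    library: MonomerLibrary,
    max_units: int = DEFAULT_MAX_UNITS,
    max_mass: float = DEFAULT_MAX_MASS,
    adducts: Sequence[str] = POSITIVE_ADDUCTS,
    tolerance: MassTolerance | None = None,
) -> AnnotationReport:
    """Full pipeline for one spectrum: enumerate -> ionize -> match -> report."""
    oligomers = enumerate_oligomers(library, max_units=max_units, max_mass=max_mass)
    ions = build_ion_table(oligomers, adducts)
    matches = match_peaks(peaks, ions, tolerance)
    matched_idx = set(matches["peak_index"]) if not matches.empty else set()
    un_rows = [
        {"peak_index": i, "mz_observed": float(peaks.mz[i]), "intensity": float(peaks.intensity[i])}
        for i in range(len(peaks))
        if i not in matched_idx
    ]
    unassigned = pd.DataFrame(un_rows, columns=["peak_index", "mz_observed", "intensity"])
    n = len(peaks)
    summary = {
        "n_peaks": n,
        "n_assigned": len(matched_idx),
        "n_unassigned": n - len(matched_idx),
        "assignment_rate": (len(matched_idx) / n) if n else float("nan"),
        "n_candidate_ions": len(ions),
        "n_oligomers": len(oligomers),
    }
    return AnnotationReport(matches=matches, unassigned=unassigned, summary=summary)
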