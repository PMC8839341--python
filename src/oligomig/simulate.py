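"""Seeded synthetic MALDI and MSn spectra from a declared coating formulation.

The generator emulates what a positive-reflector MALDI spectrum of a
polyester coating extract looks like: singly charged adduct ions (sodium
dominant under NaTFA cationization) of linear/cyclic oligomers, homologous
series spaced by the repeat-unit mass, composition abundance following the
monomer proportions, plus chemical-noise peaks.  Intensity and noise laws
(log-normal signal jitter, uniform-m/z exponential-intensity noise) are
modelling inventions that exist to exercise ranking and robustness — real
MALDI intensities also reflect desorption/ionization efficiency, isotope
envelopes and detector effects, none of which are simulated.

All randomness flows from one explicit integer seed; mass accuracy is
specified as a 3-sigma envelope (errors drawn from N(0, accuracy/3)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .chem import MonomerLibrary, default_library
from .enumeration import NeutralOligomer, enumerate_oligomers
from .annotation import PeakList, INSTRUMENT_DEFAULTS
from .fragmentation import enumerate_fragments
from .ionization import Adduct, adduct_mz, get_adduct

__all__ = ["SyntheticFormulation", "simulate_maldi_peaklist", "simulate_msn_spectrum",
           "CM1_LIKE", "CM2_LIKE"]

#: MALDI with NaTFA cationization: spectra are sodiated (minor potassium);
#: ESI-like runs see all four positive adducts.
MALDI_ADDUCT_WEIGHTS: Mapping[str, float] = {"M+Na": 0.9, "M+K": 0.1}
LCMS_ADDUCT_WEIGHTS: Mapping[str, float] = {"M+H": 0.4, "M+Na": 0.3, "M+NH4": 0.2, "M+K": 0.1}


@dataclass(frozen=True)
class SyntheticFormulation:
    """A declared coating recipe driving the generator.

    ``proportions`` maps monomer id -> relative molar proportion (normalized
    internally).  ``fraction_cyclic`` reflects that most migrating oligomers
    are cyclic (no free end groups to bind them into the network).
    ``mass_accuracy_ppm``/``mass_accuracy_da`` are 3-sigma error envelopes;
    set both to 0 for exact masses.  ``noise_fraction`` is the expected share
    of noise peaks in the final list.
    """

    proportions: Mapping[str, float]
    fraction_cyclic: float = 0.8
    min_units: int = 2
    max_units: int = 8
    max_mass: float = 2000.0
    adduct_weights: Mapping[str, float] = field(default_factory=lambda: dict(MALDI_ADDUCT_WEIGHTS))
    mass_accuracy_ppm: float = 0.0
    mass_accuracy_da: float = 0.0
    noise_fraction: float = 0.0
    intensity_sigma: float = 0.3  # log-normal jitter, natural-log scale
    length_decay: float = 0.75  # per-unit abundance decay beyond min_units
    max_species: int = 60
    instrument: str = "maldi_tof"

    def normalized_proportions(self) -> dict[str, float]:
        total = float(sum(self.proportions.values()))
        if total <= 0 or any(v < 0 for v in self.proportions.values()):
            raise ValueError("proportions must be non-negative and sum to > 0")
        return {k: v / total for k, v in self.proportions.items()}


#: Gray-coating-like recipe: phthalic-type acid with a neopentyl glycol /
#: 1,6-hexanediol / butanediol mix, caprolactone additive.
CM1_LIKE = SyntheticFormulation(
    proportions={"PA": 0.50, "NPG": 0.25, "HD": 0.15, "BD": 0.06, "CL": 0.04},
)

#: White-coating-like recipe: phthalic-type acid with neopentyl glycol,
#: cyclohexanedimethanol and ethylene glycol.
CM2_LIKE = SyntheticFormulation(
    proportions={"PA": 0.50, "NPG": 0.30, "CHDM": 0.12, "EG": 0.08},
)

_GROUND_TRUTH_COLUMNS = [
    "peak_index", "kind", "composition", "topology", "adduct", "mz_true", "mz_observed",
    "intensity",
]


def _role(library: MonomerLibrary, mid: str) -> str:
    cls = library[mid].monomer_class
    if cls in ("diacid", "triacid"):
        return "acid"
    if cls == "hydroxyacid":
        return "hydroxyacid"
    return "ol"


def _copolymer_weight(
    o: NeutralOligomer,
    props: Mapping[str, float],
    library: MonomerLibrary,
    formulation: "SyntheticFormulation",
) -> float:
    """Relative abundance of one copolyester composition.

    Proportions are normalized within functional role (acids compete with
    acids, polyols with polyols), multiplied over units with the multinomial
    arrangement count, a topology factor, and a geometric decay in chain
    length — so homologous series stay visible out to long chains and diol
    substitution follows the declared diol ratio.
    """
    comp = o.composition
    role_total: dict[str, float] = {}
    for mid, _ in comp.monomer_counts:
        r = _role(library, mid)
        role_total[r] = sum(
            props.get(m2, 0.0) for m2 in props if _role(library, m2) == r
        )
    w = formulation.fraction_cyclic if comp.is_cyclic else (1.0 - formulation.fraction_cyclic)
    n = comp.n_units
    w *= formulation.length_decay ** max(0, n - formulation.min_units)
    # multinomial arrangement count over units
    arrangements = math.factorial(n)
    for mid, c in comp.monomer_counts:
        total = role_total[_role(library, mid)]
        q = props.get(mid, 0.0) / total if total > 0 else 0.0
        w *= q ** c
        arrangements //= math.factorial(c)
    return w * arrangements


def _homopolymer_weight(
    o: NeutralOligomer, p_additive: float, formulation: "SyntheticFormulation"
) -> float:
    """Abundance of a lactone homopolymer: the additive's overall proportion
    times topology and chain-length factors."""
    w = formulation.fraction_cyclic if o.composition.is_cyclic else (1.0 - formulation.fraction_cyclic)
    return p_additive * w * formulation.length_decay ** max(
        0, o.composition.n_units - formulation.min_units
    )


def simulate_maldi_peaklist(
    formulation: SyntheticFormulation,
    seed: int,
    library: MonomerLibrary | None = None,
) -> tuple[PeakList, pd.DataFrame]:
    """Generate one synthetic spectrum and its ground-truth table.

    Signal species are the feasible oligomers of the formulation's monomer
    subset within the unit range, weighted by their monomer proportions,
    topology mix and chain length, truncated to the ``max_species`` most
    abundant.  Every species emits one peak per adduct with non-zero weight
    in the adduct distribution (intensity scaled by that weight); peaks
    outside the instrument acquisition window are dropped.  Ground truth maps
    every retained peak to its composition+adduct or marks it as noise.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(seed)
    lib = library or default_library()
    props = formulation.normalized_proportions()
    for mid in props:
        if mid not in lib:
            raise KeyError(f"formulation references unknown monomer {mid!r}")
    # hydroxyacid additives (e.g. caprolactone) polymerize as their own
    # homologous family rather than inserting at random into the copolyester
    copoly_ids = [m for m in sorted(props) if _role(lib, m) != "hydroxyacid"]
    additive_ids = [m for m in sorted(props) if _role(lib, m) == "hydroxyacid"]
    oligomers: list[NeutralOligomer] = []
    weight_list: list[float] = []
    if copoly_ids:
        sub = lib.subset(copoly_ids, provenance="synthetic formulation")
        co_o: list[NeutralOligomer] = []
        co_w: list[float] = []
        for o in enumerate_oligomers(sub, max_units=formulation.max_units,
                                     max_mass=formulation.max_mass):
            if o.composition.n_units >= formulation.min_units:
                co_o.append(o)
                co_w.append(_copolymer_weight(o, props, lib, formulation))
        # the richness cap applies to the copolymer pool; declared additive
        # families always contribute their whole series
        arr = np.array(co_w)
        keep = np.argsort(-arr, kind="mergesort")[: formulation.max_species]
        keep = keep[arr[keep] > 0]
        oligomers.extend(co_o[i] for i in keep)
        weight_list.extend(float(arr[i]) for i in keep)
    for mid in additive_ids:
        sub = lib.subset([mid], provenance="synthetic additive")
        for o in enumerate_oligomers(sub, max_units=formulation.max_units,
                                     max_mass=formulation.max_mass):
            if o.composition.n_units >= formulation.min_units:
                w = _homopolymer_weight(o, props[mid], formulation)
                if w > 0:
                    oligomers.append(o)
                    weight_list.append(w)
    if not oligomers:
        raise ValueError("formulation yields no feasible oligomers")
    weights = np.array(weight_list)

    total_aw = float(sum(formulation.adduct_weights.values()))
    adducts = [
        (get_adduct(name), w / total_aw)
        for name, w in sorted(formulation.adduct_weights.items())
        if w > 0
    ]

    lo, hi = INSTRUMENT_DEFAULTS[formulation.instrument]["window"]
    records = []
    for o, w in zip(oligomers, weights):
        for adduct, aw in adducts:
            mz_true = o.mass + adduct.mass_delta
            sigma = (
                formulation.mass_accuracy_da / 3.0
                + mz_true * formulation.mass_accuracy_ppm * 1e-6 / 3.0
            )
            mz_obs = mz_true + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            if not (lo <= mz_obs <= hi):
                continue
            intensity = w * aw * np.exp(rng.normal(0.0, formulation.intensity_sigma))
            records.append(
                {
                    "kind": "signal",
                    "composition": o.composition.composition_string(),
                    "topology": o.composition.topology,
                    "adduct": adduct.name,
                    "mz_true": mz_true,
                    "mz_observed": mz_obs,
                    "intensity": intensity,
                }
            )
    if not records:
        raise ValueError("no signal peaks fall inside the acquisition window")
    # normalize signal intensities to a base peak of 100
    top = max(r["intensity"] for r in records)
    for r in records:
        r["intensity"] = 100.0 * r["intensity"] / top

    n_signal = len(records)
    if formulation.noise_fraction > 0:
        n_noise = int(round(
            formulation.noise_fraction / (1.0 - formulation.noise_fraction) * n_signal
        ))
        span_hi = min(hi, max(r["mz_observed"] for r in records) + 200.0)
        for _ in range(n_noise):
            records.append(
                {
                    "kind": "noise",
                    "composition": "",
                    "topology": "",
                    "adduct": "",
                    "mz_true": np.nan,
                    "mz_observed": rng.uniform(lo, span_hi),
                    "intensity": rng.exponential(2.0),
                }
            )

    records.sort(key=lambda r: r["mz_observed"])
    truth = pd.DataFrame(records)
    truth.insert(0, "peak_index", np.arange(len(records)))
    peaks = PeakList(
        mz=truth["mz_observed"].to_numpy(),
        intensity=truth["intensity"].to_numpy(),
        instrument=formulation.instrument,
        metadata={"seed": str(seed)},
    )
    return peaks, truth[_GROUND_TRUTH_COLUMNS]


def simulate_msn_spectrum(
    oligomer: NeutralOligomer,
    precursor_adduct: str | Adduct,
    seed: int,
    library: MonomerLibrary | None = None,
    detection_probability: float = 0.6,
    intensity_sigma: float = 0.5,
) -> tuple[float, pd.DataFrame]:
    """Synthetic product-ion list for one precursor.

    Returns ``(precursor_mz, products)``.  Products are sampled from the
    ester-cleavage candidates: the three heaviest candidates are always
    present (high-mass sequential losses dominate ion-trap spectra of these
    species), each remaining candidate appears with ``detection_probability``.
    Sodiated/ammoniated precursors yield an empty product table.
    """
    rng = np.random.default_rng(seed)
    lib = library or default_library()
    adduct = get_adduct(precursor_adduct)
    precursor_mz = adduct_mz(oligomer.mass, adduct)
    candidates = enumerate_fragments(oligomer, adduct, lib)
    rows = []
    n = len(candidates)
    for i, c in enumerate(candidates):
        always = i >= n - 3  # candidates are sorted ascending by m/z
        if always or rng.random() < detection_probability:
            rows.append(
                {
                    "mz": c.mz,
                    "intensity": float(np.exp(rng.normal(0.0, intensity_sigma))),
                    "assignment": c.description,
                }
            )
    products = pd.DataFrame(rows, columns=["mz", "intensity", "assignment"])
    return precursor_mz, products
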