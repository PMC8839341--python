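# Methods

## Scope and model

The package models polyester oligomers at **composition level**: a species is
a multiset of monomer counts plus a topology (linear or cyclic), never a
sequence. Positional isomers and isobaric monomers (the phthalic-acid isomers
PA/IPA/TPA; 1,4-/1,3-butanediol and 2-methyl-1,3-propanediol) are therefore
indistinguishable by construction — mass spectrometry cannot separate them
either, and chromatographic retention is out of scope. Outputs that depend on
identity carry isobaric-group annotations instead of a forced choice.

Mass arithmetic is purely monoisotopic. Atomic masses are hard-coded
IUPAC/CIAAW constants (≥ 9 decimals); an ester condensation removes exactly
one water (18.010565 Da). A linear *n*-mer has *n*−1 ester bonds, a ring has
*n*, so the cyclic form of any composition is exactly one water lighter than
the linear form. Hydroxyacids (caprolactone) are stored in the ring-opened
hydrated acid form (C₆H₁₂O₃) so the one-water-per-bond rule is uniform; the
lactone repeat then comes out at 114.068 Da as observed.

### Feasibility rules

Compositions are admitted when an ester chain/ring can exist:

* **cyclic** — every unit difunctional (diacid, diol, hydroxyacid) and the
  diacid and diol unit counts exactly equal; hydroxyacids insert freely and
  may cyclize alone (lactones). Tri-functional units are excluded from rings:
  a branched ring is under-determined at composition level.
* **linear** — |acid units − polyol units| ≤ 1 (either end may terminate in
  an acid or an alcohol); hydroxyacids insert freely; monools only as chain
  caps (≤ 2, off by default in enumeration). Tri-functional monomers count in
  the acid/ol tallies and are linear-only (off by default).

Enumeration is an exact recursive scan over count vectors with mass pruning
on the cyclic (lightest) bound; tests verify equality with a brute-force
oracle on small libraries. Defaults: ≤ 8 units (homologous series are
observed to n = 3–8) and ≤ 1000 Da (heavier species are not absorbed through
the gastrointestinal tract and are toxicologically disregarded).

## Tolerances and instrument conventions

| parameter | default | rationale |
|---|---|---|
| MALDI-TOF match tolerance | 10 ppm | reflector calibration accuracy |
| ion-trap match tolerance | 0.3 Da | unit-resolution ion trap |
| product-ion tolerance | 0.5 Da | product ions printed at integer m/z |
| series chaining tolerance | 0.2 Da | reflector MALDI centroid scatter |
| series minimum length | 3 members | two spacings = weakest credible series |
| MALDI window | m/z 350–4000 | acquisition range |
| ion-trap window | m/z 100–1000 | acquisition range |

A stated mass accuracy is treated as a **3σ envelope**: the synthetic
generator draws errors from N(0, accuracy/3). Comparisons against printed
one-decimal values round half-away-from-zero. Published ion-trap m/z values
carry instrument error; the benchmark table flags which rows agree with
arithmetic at the printed precision, which within ±0.3 Da, and which five
outlier rows only within ±0.5 Da — the package reproduces what arithmetic
supports and flags the rest rather than forcing agreement.

## Series detection and monomer inference

Candidate repeat units are every (diacid, diol) pair (minus two waters) plus
every hydroxyacid (minus one water), collapsed by mass. Series are greedy
nearest-peak chains anchored at the base peak: the *i*-th expected position
is base + *i*·Δ, so centroid errors do not compound along the chain; chains
end at the first gap, overlapping chains are allowed, and only chains of ≥ 3
members count. Anchored extrapolation rather than step-to-step chaining was
chosen because step differencing doubles the variance per comparison and
measurably loses members at realistic scatter. The limitation: in very dense
spectra, 3-member chance chains occur for almost any unit mass; inference
therefore reads only peaks above a 1% base-peak floor (the grass threshold an
analyst applies) and ranks by cumulative evidence.

Monomer-exchange deltas count peak pairs spaced by a diol mass difference
(+14.016 Da NPG→HD, +40.031 Da NPG→CHDM, −42.047 Da NPG→EG …); isobaric
pairs (Δ = 0) are undetectable and excluded.

`infer_monomer_set` merges supported repeat units by acid isobaric group into
candidate subsets scored by (series members explained, exchange-pair
confirmations). Within a subset, diols are ranked by the intensity-weighted
diol share of the rank-1 annotations of the series peaks — tall peaks are
dominated by the high-proportion diol, reproducing the analyst's intensity
reading. The ranking is ordinal only; no quantification is claimed.

## Fragmentation heuristic

Product ions of a protonated precursor are all non-empty sub-multisets of the
parent composition with water-equivalent losses from (units − 1) to
(units + 1), floored at zero — fully condensed chain, ring-like, or one extra
dehydration — plus the sequential water-loss ladder from the precursor
itself. This is combinatorics over compositions, not bond-resolved chemistry:
it reproduces every diagnostic ion interpreted for these coatings (149.0,
193.0, 235.1, 359.1, 383.1, 415.1) but also proposes candidates a
structure-aware model would prune. Sodiated and ammoniated precursors return
no fragments (the charge stays on the metal/ammonium; ion traps show no
useful dissociation for them). One reported fragment is deliberately
reassigned: m/z 383 computes as 2 acid + 1 NPG minus three waters,
protonated (383.11), and is reported as such.

## Safety rule

Only the summary Cramer heuristic is implemented: cyclic with ≥ 1 aromatic
diacid → class III (TTC 1.5 µg/kg bw/day); linear → class I (30 µg/kg
bw/day); everything else (e.g. cyclic lactone or aliphatic-only rings) →
*unresolved*, flagged for a full 33-question decision-tree evaluation rather
than guessed. Class II (9 µg/kg bw/day) exists as a constant but is never
assigned by the rule. The heuristic is documented as consistent with the
24-row benchmark table only; linear oligomers are only *mainly* class I in
general, so the rule must not be read as a Toxtree replacement.

## Synthetic data

The generator emulates a positive-reflector MALDI spectrum of a coating
extract. A declared formulation gives monomer proportions, a topology mix
(default 80% cyclic — species lacking free end groups migrate), unit range
2–8, and an adduct distribution (MALDI default Na 0.9 / K 0.1, reflecting
NaTFA cationization; an LC-MS preset mixes H/Na/NH₄/K). Species abundance is
the product of role-normalized monomer proportions (acids compete with
acids, diols with diols) with the multinomial arrangement count, a topology
factor, and a geometric chain-length decay (0.75 per unit); hydroxyacid
additives form their own homopolymer families outside the copolymer richness
cap, since caprolactone enters coatings as an additive with its own cyclic
series rather than by random co-insertion. Every retained species emits one
peak per non-zero-weight adduct. Intensity jitter is log-normal (σ = 0.3
natural-log units); noise peaks are uniform in m/z with exponential
intensity. All randomness flows from one explicit seed.

What passing tests show — and do not show: the generator produces the series
structure, adduct patterns, mass errors and grass of real spectra, so
recovery statistics demonstrate the algorithms' arithmetic and robustness.
It does not model desorption/ionization efficiency, isotope envelopes,
detector saturation or chromatographic elution, so recovery rates on real
instruments can be lower, and intensity-based proportion ranking on real
data remains ordinal at best.

## Numerical conventions and degenerate inputs

* Formula subtraction that would go negative raises; the empty formula has
  mass 0 and is rejected as a fragment or composition.
* Enumeration order is deterministic (mass, then canonical composition
  string, then topology); annotation ties break by fewer distinct monomers,
  then fewer units, then the canonical string.
* Unsorted peak lists are auto-sorted with a warning; negative intensities
  are errors. Exact composition isobars (e.g. 2 NPG vs BD + HD, identical
  formula) are reported together and flagged, never silently collapsed.
* "Correct assignment" in end-to-end checks: at zero mass error the true
  (composition, topology, adduct) must sit in the rank-1 tie set; at finite
  error it must be among the reported within-tolerance matches, since exact
  isobars make strict rank-1 ill-posed.

## Problem sizes

The statistical checks run at desk scale: the brute-force enumeration oracle
on ≤ 3-monomer libraries at ≤ 5 units; series robustness over 100 seeded
simulations at σ = tol/3; end-to-end annotation over 50 seeds (5 at zero
error) with ~100–160 peaks per spectrum; monomer-set recovery over 50 seeds
at 20% noise. The full default-library enumeration (17 monomers, ≈ 10⁵
compositions ≤ 1000 Da) runs once per session.

## Known limitations

* Composition-level fragmentation over-generates candidates; no intensity
  prediction.
* Greedy chaining can thread chance progressions in dense spectra; series
  evidence is cumulative, not per-chain proof.
* The default monomer library is an approximation — real formulations draw
  on a larger polyol pool; the library is user-extensible via CSV.
* The Cramer rule is a two-branch heuristic with an explicit unresolved
  class, not a decision-tree implementation.
* Charge states beyond ±1, isotope patterns, and average-mass arithmetic are
  unsupported by design.
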