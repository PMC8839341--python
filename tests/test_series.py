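"""Homologous-series detection, exchange deltas, and monomer-set inference."""

import numpy as np
import pytest

from oligomig.annotation import PeakList
from oligomig.series import (
    candidate_repeat_units,
    detect_exchange_deltas,
    detect_series,
    infer_monomer_set,
    series_table,
)


def peaklist(mzs, intensities=None):
    mzs = np.asarray(mzs, float)
    inten = np.ones_like(mzs) if intensities is None else np.asarray(intensities, float)
    return PeakList(mz=mzs, intensity=inten)


def unit_named(library, ids, label):
    units = candidate_repeat_units(library.subset(ids))
    (u,) = [u for u in units if u.label == label]
    return u


def test_repeat_unit_masses(library):
    pa_npg = unit_named(library, ["PA", "NPG"], "PA+NPG")
    assert pa_npg.mass == pytest.approx(234.0892, abs=5e-4)
    cl = unit_named(library, ["CL"], "CL")
    assert cl.mass == pytest.approx(114.0681, abs=5e-4)


def test_repeat_units_collapse_isobars(library):
    units = candidate_repeat_units(library.subset(["PA", "IPA", "TPA", "NPG"]))
    assert len(units) == 1
    assert set(units[0].acid_ids) == {"PA", "IPA", "TPA"}


def test_empty_library_has_no_units(library):
    assert candidate_repeat_units(library.subset(["NPG"])) == []


def test_planted_progression_recovered(library):
    u = unit_named(library, ["PA", "NPG"], "PA+NPG")
    mzs = [469.19, 703.28, 937.37, 1171.46]
    hits = detect_series(peaklist(mzs), u, tol=0.2, min_length=3)
    assert len(hits) == 1
    assert hits[0].n_members == 4
    assert hits[0].base_mz == pytest.approx(469.19)


def test_sodiated_caprolactone_series(library):
    """Pentamer/hexamer/heptamer lactone ring series, sodiated."""
    u = unit_named(library, ["CL"], "CL")
    hits = detect_series(peaklist([593.33, 707.40, 821.47]), u, tol=0.2, min_length=3)
    assert len(hits) == 1 and hits[0].n_members == 3


def test_random_peaks_rarely_chain(library):
    u = unit_named(library, ["PA", "NPG"], "PA+NPG")
    rng = np.random.default_rng(11)
    for _ in range(5):
        mzs = np.sort(rng.uniform(350, 2000, size=25))
        hits = detect_series(peaklist(mzs), u, tol=0.2, min_length=3)
        assert all(h.n_members >= 3 for h in hits)  # never crashes, sane output


def test_no_false_merging(library):
    """Two interleaved progressions with repeat masses > 2 tol apart stay apart."""
    u1 = unit_named(library, ["PA", "NPG"], "PA+NPG")  # 234.089
    u2 = unit_named(library, ["PA", "HD"], "PA+HD")  # 248.105
    base1, base2 = 400.0, 410.0
    mzs = sorted(
        [base1 + i * u1.mass for i in range(4)] + [base2 + i * u2.mass for i in range(4)]
    )
    hits1 = detect_series(peaklist(mzs), u1, tol=0.2, min_length=3)
    assert len(hits1) == 1
    got = [round(m, 2) for m in np.asarray(peaklist(mzs).mz)[list(hits1[0].member_indices)]]
    expected = [round(base1 + i * u1.mass, 2) for i in range(4)]
    assert got == expected


def test_exchange_deltas(library):
    sub = library.subset(["PA", "NPG", "HD", "CHDM", "EG"])
    # peaks embodying NPG->HD (+14.016), NPG->CHDM (+40.031), EG->NPG (+42.047)
    mzs = [449.121, 491.168, 505.184, 531.199]
    df = detect_exchange_deltas(peaklist(mzs), sub, tol=0.05)
    d = {(r.monomer_out, r.monomer_in): (r.delta, r.n_peak_pairs) for r in df.itertuples()}
    assert d[("NPG", "HD")][0] == pytest.approx(14.0157, abs=5e-4)
    assert d[("NPG", "HD")][1] >= 1
    assert d[("NPG", "CHDM")][0] == pytest.approx(40.0313, abs=5e-4)
    assert d[("NPG", "CHDM")][1] >= 1
    assert d[("EG", "NPG")][0] == pytest.approx(42.0470, abs=5e-4)
    assert d[("EG", "NPG")][1] >= 1
    # isobaric pairs (delta 0) are excluded entirely
    assert ("BD", "MPO") not in d and ("MPO", "BD") not in d


def test_exchange_needs_two_peaks(library):
    assert detect_exchange_deltas(peaklist([500.0]), library).empty


def test_infer_single_unit_spectrum(library):
    """A pure (acid+diol)_n ladder implicates exactly that pair."""
    u = unit_named(library, ["PA", "NPG"], "PA+NPG")
    mzs = [491.17 + i * u.mass for i in range(4)]
    results = infer_monomer_set(peaklist(mzs), library.subset(["PA", "NPG", "HD", "EG"]))
    top = results[0]
    assert ("PA",) in top.monomer_groups
    assert ("NPG",) in top.monomer_groups
    assert ("EG",) not in top.monomer_groups


def test_series_table_export(library):
    u = unit_named(library, ["PA", "NPG"], "PA+NPG")
    hits = detect_series(peaklist([469.19, 703.28, 937.37]), u)
    df = series_table(hits)
    assert list(df.columns) == [
        "repeat_composition", "repeat_mass", "n_members", "base_mz",
        "member_indices", "mean_abs_deviation",
    ]
    assert df.loc[0, "n_members"] == 3
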