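"""Peak matching against the candidate ion table."""

import numpy as np
import pytest

from oligomig.annotation import MassTolerance, PeakList, annotate_run, match_peaks
from oligomig.enumeration import enumerate_oligomers
from oligomig.ionization import build_ion_table


@pytest.fixture(scope="module")
def pa_npg_ions(library):
    oligs = enumerate_oligomers(library.subset(["PA", "NPG"]), max_units=6, max_mass=1000.0)
    return build_ion_table(oligs)


def peaklist(mzs, intensities=None, **kw):
    mzs = np.asarray(mzs, float)
    inten = np.ones_like(mzs) if intensities is None else np.asarray(intensities, float)
    return PeakList(mz=mzs, intensity=inten, **kw)


def test_sodiated_cyclic_tetramer_assignment(pa_npg_ions):
    peaks = peaklist([491.17])
    m = match_peaks(peaks, pa_npg_ions, MassTolerance(0.3, "da"))
    top = m[m["rank"] == 1].iloc[0]
    assert top["composition"] == "2NPG+2PA"
    assert top["topology"] == "cyclic"
    assert top["adduct"] == "M+Na"


def test_empty_peak_list(pa_npg_ions):
    m = match_peaks(peaklist([]), pa_npg_ions, MassTolerance(0.3, "da"))
    assert m.empty


def test_mixed_glycol_trimer_in_full_db(library, default_oligomers):
    ions = build_ion_table(default_oligomers, ["M+H"])
    m = match_peaks(peaklist([427.14]), ions, MassTolerance(0.3, "da"))
    labels = set(zip(m["composition"], m["topology"], m["adduct"]))
    assert ("EG+NPG+2PA", "cyclic", "M+H") in labels


def test_error_is_signed_observed_minus_theoretical(pa_npg_ions):
    m = match_peaks(peaklist([469.30]), pa_npg_ions, MassTolerance(0.3, "da"))
    row = m[(m["composition"] == "2NPG+2PA") & (m["adduct"] == "M+H")].iloc[0]
    assert row["error_da"] == pytest.approx(469.30 - 469.1857, abs=5e-4)
    assert row["error_da"] > 0


def test_tolerance_monotonicity(pa_npg_ions):
    peaks = peaklist([469.19, 491.17, 700.0])
    wide = match_peaks(peaks, pa_npg_ions, MassTolerance(0.5, "da"))
    narrow = match_peaks(peaks, pa_npg_ions, MassTolerance(0.05, "da"))
    wide_keys = set(zip(wide["peak_index"], wide["composition"], wide["adduct"]))
    narrow_keys = set(zip(narrow["peak_index"], narrow["composition"], narrow["adduct"]))
    assert narrow_keys <= wide_keys


def test_completeness_at_zero_error(library, pa_npg_ions):
    """Every planted ion m/z is matched at rank 1 when observed exactly."""
    sample = pa_npg_ions.sample(n=20, random_state=0).sort_values("mz")
    peaks = peaklist(sample["mz"].to_numpy())
    m = match_peaks(peaks, pa_npg_ions, MassTolerance(10.0, "ppm"))
    top = m[m["rank"] == 1]
    assert set(top["peak_index"]) == set(range(20))
    assert (top["error_da"].abs() < 1e-9).all()


def test_unsorted_peaks_warn_and_sort():
    with pytest.warns(UserWarning, match="not sorted"):
        p = peaklist([500.0, 400.0])
    assert list(p.mz) == [400.0, 500.0]


def test_negative_intensity_rejected():
    with pytest.raises(ValueError):
        peaklist([400.0], [-1.0])


def test_instrument_default_tolerances():
    assert peaklist([400.0], instrument="maldi_tof").tolerance == MassTolerance(10.0, "ppm")
    assert peaklist([400.0], instrument="ion_trap").tolerance == MassTolerance(0.3, "da")


def test_annotate_run_reports_unassigned(library):
    sub = library.subset(["PA", "NPG"])
    peaks = peaklist([469.19, 777.77])
    report = annotate_run(peaks, sub, tolerance=MassTolerance(0.3, "da"))
    assert report.summary["n_peaks"] == 2
    assert report.summary["n_assigned"] == 1
    assert list(report.unassigned["mz_observed"]) == [777.77]


def test_annotate_run_noise_smoke(library):
    rng = np.random.default_rng(7)
    mzs = np.sort(rng.uniform(360, 990, size=30))
    report = annotate_run(peaklist(mzs), library.subset(["PA", "NPG"]),
                          tolerance=MassTolerance(10.0, "ppm"))
    assert 0.0 <= report.summary["assignment_rate"] <= 1.0
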