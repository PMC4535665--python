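"""Scan averaging, recalibration, contaminant filtering, alignment and
isotope annotation."""

import numpy as np
import pandas as pd
import pytest

from lipidims.spectra_processing import (
    DEFAULT_STANDARDS,
    FeatureMatrix,
    PeakList,
    ProcessingParams,
    RecalibrationError,
    Scan,
    align_samples,
    annotate_isotopes,
    average_scans,
    filter_contaminants,
    ppm_group,
    read_peak_table,
    recalibrate,
)

PARAMS = ProcessingParams()


def make_scans(mz, intensity, indices):
    return [Scan(i, PeakList(np.array(mz, float), np.array(intensity, float)))
            for i in indices]


class TestAverageScans:
    def test_identical_scans_reproduce_input(self):
        mz = [400.1, 700.25, 900.5]
        inten = [5000.0, 8000.0, 12000.0]
        avg = average_scans(make_scans(mz, inten, range(20, 71)), PARAMS)
        np.testing.assert_allclose(avg.mz, mz, rtol=1e-12)
        np.testing.assert_allclose(avg.intensity, inten, rtol=1e-12)

    def test_cutoff_removes_strictly_below_2000(self):
        scans = make_scans([500.0, 600.0], [1999.0, 2000.0], range(20, 71))
        avg = average_scans(scans, PARAMS)
        assert list(avg.mz) == [600.0]

    def test_intermittent_peak_averaged_over_scan_count(self):
        # present at 6000 in 25 of 50 scans -> mean over 50 scans = 3000
        scans = []
        for i in range(20, 70):
            if i < 45:
                scans.append(Scan(i, PeakList(np.array([500.0]),
                                              np.array([6000.0]))))
            else:
                scans.append(Scan(i, PeakList(np.array([]), np.array([]))))
        avg = average_scans(scans, PARAMS)
        assert avg.intensity[0] == pytest.approx(3000.0)

    def test_out_of_range_scans_ignored(self):
        scans = make_scans([500.0], [5000.0], [20, 50, 70]) + \
            make_scans([500.0], [9e9], [1, 99])
        avg = average_scans(scans, PARAMS)
        assert avg.intensity[0] == pytest.approx(5000.0)

    def test_empty_range_errors(self):
        with pytest.raises(ValueError):
            average_scans(make_scans([500.0], [5000.0], [1, 2]), PARAMS)


class TestRecalibrate:
    @staticmethod
    def _peaks(extra_ppm=0.0, drift=None):
        mzs = np.array([s.expected_mz for s in DEFAULT_STANDARDS]
                       + [500.5, 786.6, 874.8])
        inten = np.full(len(mzs), 1e5)
        if drift is not None:
            mzs = mzs * (1 + drift(mzs) / 1e6)
        else:
            mzs = mzs * (1 + extra_ppm / 1e6)
        return PeakList(mzs, inten)

    def test_constant_shift_recovered(self):
        corrected, model = recalibrate(self._peaks(extra_ppm=10.0))
        res = model.residuals_ppm
        assert res["residual_ppm"].abs().max() <= 0.1
        assert model.intercept == pytest.approx(10.0, abs=0.1)

    def test_linear_drift_recovered(self):
        drift = lambda mz: 15.0 * (mz - 200.0) / 700.0  # 0 ppm at 200, 15 at 900
        corrected, model = recalibrate(self._peaks(drift=drift), model="linear")
        res = model.residuals_ppm
        assert res["residual_ppm"].abs().max() <= 1.0
        assert model.slope == pytest.approx(15.0 / 700.0, rel=0.05)

    def test_unshifted_input_near_identity(self):
        peaks = self._peaks()
        corrected, model = recalibrate(peaks)
        disp = np.abs(corrected.mz - peaks.mz) / peaks.mz * 1e6
        assert disp.max() <= 0.1

    def test_too_few_standards_raises_with_report(self):
        peaks = PeakList(np.array([500.0, 600.0]), np.array([1e4, 1e4]))
        with pytest.raises(RecalibrationError) as err:
            recalibrate(peaks)
        assert len(err.value.report) == len(DEFAULT_STANDARDS)
        assert not err.value.report["found"].any()


class TestFilterContaminants:
    def test_rejection_list_hit_removed(self):
        peaks = PeakList(np.array([391.2843, 876.8015]), np.array([1e4, 1e5]))
        out, log = filter_contaminants(peaks, rejection_list=[(391.2843, 0.01)])
        assert list(out.mz) == [876.8015]
        assert len(log) == 1 and "rejection" in log["reason"].iloc[0]

    def test_defect_window_removes_plasticizer_band(self):
        peaks = PeakList(np.array([391.2843, 876.8015]), np.array([1e4, 1e5]))
        out, _ = filter_contaminants(
            peaks, defect_windows=[((350.0, 450.0), (0.25, 0.32))])
        assert list(out.mz) == [876.8015]

    def test_lipid_defect_outside_windows_retained(self):
        peaks = PeakList(np.array([369.3516]), np.array([1e5]))
        out, _ = filter_contaminants(
            peaks, rejection_list=[(391.2843, 0.01)],
            defect_windows=[((350.0, 450.0), (0.25, 0.32))])
        assert len(out) == 1


def brute_force_single_linkage(mz, window_ppm):
    """Independent oracle: union-find over all pairs closer than the ppm
    window (relative to the smaller member)."""
    n = len(mz)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            lo, hi = sorted((mz[i], mz[j]))
            if (hi - lo) / lo * 1e6 <= window_ppm:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestAlign:
    def test_peaks_within_window_merge(self):
        samples = {
            "a": PeakList(np.array([800.0000]), np.array([1e4])),
            "b": PeakList(np.array([800.0080]), np.array([2e4])),
        }
        fm = align_samples(samples, PARAMS)
        assert fm.n_features == 1
        assert fm.features["coverage"].iloc[0] == 1.0

    def test_low_coverage_feature_dropped(self):
        samples = {}
        for i in range(10):
            mzs = [500.0] + ([700.0] if i < 5 else [])
            samples[f"s{i}"] = PeakList(np.array(mzs, float),
                                        np.full(len(mzs), 1e4))
        fm = align_samples(samples, PARAMS)
        assert fm.n_features == 1  # the 50 %-coverage peak is out
        assert fm.features["mz"].iloc[0] == pytest.approx(500.0)

    def test_max_intensity_kept_for_duplicate_peaks(self):
        samples = {
            "a": PeakList(np.array([800.000, 800.004]), np.array([1e4, 3e4])),
            "b": PeakList(np.array([800.002]), np.array([2e4])),
        }
        fm = align_samples(samples, PARAMS)
        assert fm.n_features == 1
        assert fm.intensities.loc["a"].iloc[0] == pytest.approx(3e4)

    @pytest.mark.parametrize("seed", range(5))
    def test_grouping_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        centers = np.sort(rng.uniform(200, 1000, size=rng.integers(10, 40)))
        centers = centers[np.diff(centers, prepend=0.0) / centers * 1e6 > 80]
        mz = np.sort(np.concatenate([
            c * (1 + rng.normal(0, 3e-6, size=rng.integers(1, 8)))
            for c in centers]))
        mine = [list(g) for g in ppm_group(mz, 22.0)]
        assert sorted(mine) == brute_force_single_linkage(mz, 22.0)


def planted_isotope_matrix(spacing=1.00336, ratio=0.55, present_frac=1.0,
                           n_samples=12):
    """Feature matrix with a parent at 850.786 and a satellite at
    parent + spacing, co-occurring in ``present_frac`` of samples."""
    parent, sat = 850.786, 850.786 + spacing
    features = pd.DataFrame(
        {"mz": [parent, sat, 500.25], "coverage": [1.0, 1.0, 1.0],
         "is_isotope": False, "isotope_of": ""},
        index=["F0", "F1", "F2"])
    n_present = int(round(present_frac * n_samples))
    inten = pd.DataFrame(
        {"F0": np.full(n_samples, 1e5),
         "F1": [1e5 * ratio if i < n_present else np.nan
                for i in range(n_samples)],
         "F2": np.full(n_samples, 5e4)},
        index=[f"s{i}" for i in range(n_samples)])
    return FeatureMatrix(inten, features)


class TestIsotopes:
    def test_planted_pair_flagged(self):
        fm = annotate_isotopes(planted_isotope_matrix(), PARAMS)
        assert fm.features.loc["F1", "is_isotope"]
        assert fm.features.loc["F1", "isotope_of"] == "F0"
        assert not fm.features.loc["F0", "is_isotope"]

    def test_doubly_charged_spacing_not_flagged(self):
        fm = annotate_isotopes(planted_isotope_matrix(spacing=0.50168), PARAMS)
        assert not fm.features["is_isotope"].any()

    def test_low_cooccurrence_not_flagged(self):
        fm = annotate_isotopes(planted_isotope_matrix(present_frac=0.20), PARAMS)
        assert not fm.features["is_isotope"].any()

    def test_implausible_ratio_not_flagged(self):
        # ratio 2.0 would require ~190 carbons at m/z 850
        fm = annotate_isotopes(planted_isotope_matrix(ratio=2.0), PARAMS)
        assert not fm.features["is_isotope"].any()


def test_read_peak_table_round_trip(tmp_path):
    df = pd.DataFrame({
        "sample_id": ["a", "a", "b"], "scan": [1, 2, 1],
        "mz": [500.1, 500.1, 600.2], "intensity": [1e4, 1.1e4, 2e4]})
    path = tmp_path / "peaks.csv"
    df.to_csv(path, index=False)
    scans = read_peak_table(path)
    assert set(scans) == {"a", "b"}
    assert len(scans["a"]) == 2
    assert scans["b"][0].peaks.mz[0] == pytest.approx(600.2)


def test_params_validation():
    with pytest.raises(ValueError):
        ProcessingParams(min_coverage=0.0)
    with pytest.raises(ValueError):
        ProcessingParams(align_ppm=-1.0)


def _b64(arr, dtype="<f8", compress=False):
    import base64
    import zlib

    raw = np.asarray(arr, dtype).tobytes()
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode()


def test_read_mzml_minimal_document(tmp_path):
    from lipidims.spectra_processing import read_mzml

    mz, inten = [500.25, 850.786], [3000.0, 5000.0]
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <run id="r"><spectrumList count="1">
  <spectrum index="0" id="scan=1" defaultArrayLength="2">
   <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>
   <binaryDataArrayList count="2">
    <binaryDataArray>
     <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
     <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
     <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
     <binary>{_b64(mz)}</binary>
    </binaryDataArray>
    <binaryDataArray>
     <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
     <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
     <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
     <binary>{_b64(inten, compress=True)}</binary>
    </binaryDataArray>
   </binaryDataArrayList>
  </spectrum>
 </spectrumList></run>
</mzML>"""
    path = tmp_path / "tiny.mzml"
    path.write_text(doc)
    scans = read_mzml(path)
    assert len(scans) == 1
    assert scans[0].polarity == "positive"
    np.testing.assert_allclose(scans[0].peaks.mz, mz)
    np.testing.assert_allclose(scans[0].peaks.intensity, inten)


def test_read_mzxml_minimal_document(tmp_path):
    from lipidims.spectra_processing import read_mzxml

    pairs = [500.25, 3000.0, 850.786, 5000.0]  # interleaved mz/intensity
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">
 <msRun scanCount="1">
  <scan num="3" polarity="+" peaksCount="2">
   <peaks precision="64" byteOrder="network" pairOrder="m/z-int"
          compressionType="none">{_b64(pairs, dtype=">f8")}</peaks>
  </scan>
 </msRun>
</mzXML>"""
    path = tmp_path / "tiny.mzxml"
    path.write_text(doc)
    scans = read_mzxml(path)
    assert len(scans) == 1
    assert scans[0].index == 3
    np.testing.assert_allclose(scans[0].peaks.mz, pairs[0::2])
    np.testing.assert_allclose(scans[0].peaks.intensity, pairs[1::2])
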