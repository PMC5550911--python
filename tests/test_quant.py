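"""Quantitation: SIC extraction, wavelet detection, fallback, alignment,
noise floor and spike normalization."""

import numpy as np
import pandas as pd
import pytest

from lfquant import (
    Chromatogram,
    MzWindow,
    QuantParams,
    RtWarp,
    SynthConfig,
    align_runs,
    apply_noise_floor,
    detect_peaks_cwt,
    extract_sic,
    fallback_integrate,
    fill_missing,
    generate_chromatogram_set,
    multipass_detect,
    normalize_spike,
    quantify_trace,
    read_chromatogram,
    write_chromatogram,
)
from lfquant.quant import MAD_SIGMA, QuantError

from conftest import gaussian_trace


class TestChromatogramType:
    def test_rt_must_strictly_increase(self):
        with pytest.raises(QuantError):
            Chromatogram([0.0, 1.0, 1.0], [0.0, 1.0, 0.0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(QuantError):
            Chromatogram([0.0, 1.0], [1.0, -2.0])

    def test_roundtrip_text_io(self, tmp_path):
        c = Chromatogram(np.arange(5.0), np.array([0.0, 1.0, 5.0, 1.0, 0.0]))
        path = tmp_path / "trace.txt"
        write_chromatogram(c, path)
        c2 = read_chromatogram(path)
        np.testing.assert_allclose(c2.rt, c.rt)
        np.testing.assert_allclose(c2.intensity, c.intensity)


class TestExtractSic:
    def test_matching_signal_passes_window(self):
        c = extract_sic([(10.0, [500.0], [100.0]), (11.0, [], [])], MzWindow(500.0, 10.0))
        assert c.intensity.tolist() == [100.0, 0.0]

    def test_12ppm_offset_excluded_at_10ppm(self):
        # 0.006 / 500 = 12 ppm > 10 ppm
        c = extract_sic(
            [(10.0, [500.006], [100.0]), (11.0, [500.004], [50.0])], MzWindow(500.0, 10.0)
        )
        assert c.intensity.tolist() == [0.0, 50.0]

    def test_two_matching_signals_sum(self):
        c = extract_sic(
            [(10.0, [500.001, 499.999], [60.0, 40.0]), (11.0, [], [])], MzWindow(500.0, 10.0)
        )
        assert c.intensity[0] == pytest.approx(100.0)

    def test_empty_series_rejected(self):
        with pytest.raises(QuantError):
            extract_sic([], MzWindow(500.0))


class TestDetectPeaksCwt:
    @pytest.mark.parametrize("sigma", [2.0, 5.0, 10.0, 20.0])
    def test_noiseless_gaussian_area_within_2pct_of_closed_form(self, flat_rt, sigma):
        y = gaussian_trace(flat_rt, 300.0, sigma, 1e4)
        peaks = detect_peaks_cwt(Chromatogram(flat_rt, y), 2.0, 80.0, 10.0)
        assert len(peaks) == 1
        true = 1e4 * sigma * np.sqrt(2 * np.pi)
        assert peaks[0].area == pytest.approx(true, rel=0.02)
        # trapezoid oracle over the full generated trace agrees
        assert peaks[0].area == pytest.approx(np.trapezoid(y, flat_rt), rel=0.02)

    def test_all_zero_trace_yields_no_peaks(self, flat_rt):
        assert detect_peaks_cwt(Chromatogram(flat_rt, np.zeros_like(flat_rt)), 2, 80, 10) == []

    def test_low_snr_peak_rejected_at_threshold_10(self, flat_rt):
        rng = np.random.default_rng(0)
        noise = np.abs(rng.normal(0, 100, flat_rt.size))  # half-normal baseline
        y = noise + gaussian_trace(flat_rt, 300.0, 4.0, 200.0)
        # oracle: MAD-based snr of the construction is ~5
        off = y[np.abs(flat_rt - 300.0) > 40]
        snr = y.max() / (MAD_SIGMA * np.median(np.abs(off - np.median(off))))
        assert 3 < snr < 8
        assert detect_peaks_cwt(Chromatogram(flat_rt, y), 2, 80, 10.0) == []

    def test_high_snr_peak_in_noise_detected_and_integrated(self, flat_rt):
        rng = np.random.default_rng(1)
        y = np.clip(rng.normal(0, 50, flat_rt.size), 0, None)
        y += gaussian_trace(flat_rt, 250.0, 5.0, 5e3)
        peaks = detect_peaks_cwt(Chromatogram(flat_rt, y), 2, 80, 10.0)
        assert len(peaks) == 1
        assert peaks[0].snr >= 10
        assert peaks[0].area == pytest.approx(5e3 * 5.0 * np.sqrt(2 * np.pi), rel=0.10)

    def test_trace_shorter_than_min_width_is_empty_result(self):
        rt = np.arange(0.0, 1.5, 0.5)
        assert detect_peaks_cwt(Chromatogram(rt, [0.0, 1.0, 0.0]), 5.0, 80.0) == []

    def test_peak_intervals_are_disjoint(self, flat_rt):
        y = gaussian_trace(flat_rt, 200.0, 4.0, 1e4) + gaussian_trace(flat_rt, 230.0, 4.0, 8e3)
        peaks = detect_peaks_cwt(Chromatogram(flat_rt, y), 2, 80, 10)
        assert len(peaks) == 2
        assert peaks[0].rt_end <= peaks[1].rt_start


class TestMultipass:
    def test_broad_and_narrow_resolved_in_different_passes(self, params, flat_rt):
        y = gaussian_trace(flat_rt, 200.0, 15.0, 1e4) + gaussian_trace(flat_rt, 450.0, 2.0, 1e4)
        peaks = multipass_detect(Chromatogram(flat_rt, y), params)
        assert len(peaks) == 2
        broad, narrow = peaks
        assert broad.pass_index < narrow.pass_index
        assert broad.area == pytest.approx(1e4 * 15.0 * np.sqrt(2 * np.pi), rel=0.02)
        assert narrow.area == pytest.approx(1e4 * 2.0 * np.sqrt(2 * np.pi), rel=0.02)

    def test_narrow_bump_inside_accepted_broad_peak_is_suppressed(self, params, flat_rt):
        y = gaussian_trace(flat_rt, 300.0, 15.0, 1e4) + gaussian_trace(flat_rt, 305.0, 2.0, 800.0)
        peaks = multipass_detect(Chromatogram(flat_rt, y), params)
        assert len(peaks) == 1
        assert peaks[0].pass_index == 0

    def test_empty_trace_gives_empty_list(self, params, flat_rt):
        assert multipass_detect(Chromatogram(flat_rt, np.zeros_like(flat_rt)), params) == []

    def test_pass_indices_recorded_and_intervals_disjoint(self, params, flat_rt):
        y = (
            gaussian_trace(flat_rt, 100.0, 12.0, 1e4)
            + gaussian_trace(flat_rt, 300.0, 3.0, 2e4)
            + gaussian_trace(flat_rt, 500.0, 6.0, 1.5e4)
        )
        peaks = multipass_detect(Chromatogram(flat_rt, y), params)
        assert len(peaks) == 3
        assert all(p.pass_index >= 0 for p in peaks)
        for a, b in zip(peaks, peaks[1:]):
            assert a.rt_end <= b.rt_start

    @pytest.mark.parametrize("sigma", [2.0, 3.0, 5.0, 8.0, 12.0, 16.0, 20.0])
    def test_oracle_equivalence_across_width_range(self, params, flat_rt, sigma):
        y = gaussian_trace(flat_rt, 300.0, sigma, 1e4)
        peaks = multipass_detect(Chromatogram(flat_rt, y), params)
        best = max(peaks, key=lambda p: p.area)
        assert best.area == pytest.approx(1e4 * sigma * np.sqrt(2 * np.pi), rel=0.02)


class TestFallback:
    def test_rectangle_integrates_exactly(self):
        rt = np.arange(5.0, 15.5, 0.5)
        pc = fallback_integrate(Chromatogram(rt, np.full(rt.size, 100.0)), halfwidth=7.0)
        assert pc.area == pytest.approx(1000.0)
        assert pc.method == "fallback"

    def test_all_zero_trace_gives_area_zero(self, flat_rt):
        pc = fallback_integrate(Chromatogram(flat_rt, np.zeros_like(flat_rt)), halfwidth=10.0)
        assert pc.area == 0.0

    def test_window_past_trace_end_is_clipped(self, flat_rt):
        y = gaussian_trace(flat_rt, 580.0, 5.0, 1e3)
        pc = fallback_integrate(Chromatogram(flat_rt, y), halfwidth=50.0)
        sel = flat_rt >= 530.0
        assert pc.area == pytest.approx(np.trapezoid(y[sel], flat_rt[sel]), rel=1e-9)

    def test_quantify_trace_falls_back_when_detection_fails(self, params, flat_rt):
        y = np.full(flat_rt.size, 5.0)  # flat: nothing for the CWT to find
        call = quantify_trace(Chromatogram(flat_rt, y), params)
        assert call.method == "fallback"


class TestAlignment:
    def test_identical_runs_give_identity_warps(self):
        anchors = pd.DataFrame({"a": [100.0, 300.0, 500.0], "b": [100.0, 300.0, 500.0]})
        warps = align_runs(anchors)
        t = np.linspace(50, 550, 11)
        for w in warps.values():
            assert np.max(np.abs(w(t) - t)) < 1e-9

    def test_uniform_shift_recovered(self):
        anchors = pd.DataFrame(
            {"a": [100.0, 300.0, 500.0], "b": [105.0, 305.0, 505.0], "c": [100.0, 300.0, 500.0]}
        )
        w = align_runs(anchors)["b"]
        t = np.linspace(100, 500, 9)
        assert np.allclose(w(t + 5.0), t, atol=1e-9)  # warp removes the +5 s shift

    def test_linear_drift_residuals_below_half_second(self):
        rng = np.random.default_rng(4)
        ref = np.sort(rng.uniform(60, 540, 12))
        runs = {}
        for i, (slope, off) in enumerate([(1.0, 0.0), (0.98, 10.0), (1.02, -10.0)]):
            runs[f"r{i}"] = slope * ref + off + rng.normal(0, 0.1, ref.size)
        anchors = pd.DataFrame(runs)
        warps = align_runs(anchors)
        reference = anchors.median(axis=1).to_numpy()
        for name, w in warps.items():
            resid = np.abs(w(anchors[name].to_numpy()) - reference)
            assert np.median(resid) < 0.5

    def test_non_monotone_anchor_pairs_rejected(self):
        anchors = pd.DataFrame({"a": [100.0, 300.0, 500.0], "b": [100.0, 500.0, 300.0]})
        with pytest.raises(QuantError):
            align_runs(anchors)

    def test_fewer_than_two_anchors_rejected(self):
        with pytest.raises(QuantError):
            align_runs(pd.DataFrame({"a": [100.0], "b": [100.0]}))


class TestFillMissing:
    def test_recovers_area_of_unfragmented_peptide(self, params):
        cfg = SynthConfig(n_replicates=2, seed=1)
        chroms, areas = generate_chromatogram_set(cfg, [(300.0, 3.0, 5e3)], shifts=[0.0, 5.0])
        # run B elutes 5 s late: native = reference + 5
        warp = RtWarp(np.array([5.0, 605.0]), np.array([0.0, 600.0]))
        call = fill_missing(chroms["rep2"], warp, expected_rt=300.0, params=params)
        assert call.method == "rt_fill"
        assert call.area == pytest.approx(areas[0], rel=0.05)

    def test_expected_rt_beyond_trace_gives_zero_area(self, params, flat_rt):
        chrom = Chromatogram(flat_rt, np.ones_like(flat_rt))
        call = fill_missing(chrom, RtWarp.identity(0, 600), expected_rt=900.0, params=params)
        assert call.area == 0.0

    def test_identity_warp_matches_fallback_at_expected_rt(self, params, flat_rt):
        y = gaussian_trace(flat_rt, 200.0, 4.0, 1e4)
        chrom = Chromatogram(flat_rt, y)
        a = fill_missing(chrom, RtWarp.identity(0, 600), expected_rt=200.0, params=params)
        b = fallback_integrate(chrom, params.fallback_halfwidth, center=200.0)
        assert a.area == pytest.approx(b.area, rel=1e-12)


class TestNoiseFloorAndSpike:
    def test_noise_floor_boundary(self):
        table = pd.DataFrame({"peptide": list("abc"), "replicate": ["r"] * 3, "area": [999.0, 1000.0, 0.0]})
        out = apply_noise_floor(table, floor=1000.0)
        assert np.isnan(out["area"].iloc[0])
        assert out["area"].iloc[1] == 1000.0
        assert np.isnan(out["area"].iloc[2])

    def test_spike_normalization_basic_and_unit_spike(self):
        t = pd.DataFrame(
            {
                "peptide": ["DRVYHPF", "pepA", "DRVYHPF", "pepA"],
                "replicate": ["r1", "r1", "r2", "r2"],
                "area": [2000.0, 4000.0, 1000.0, 2000.0],
            }
        )
        out = normalize_spike(t)
        assert out.loc[out["peptide"] == "pepA", "normalized_area"].tolist() == [2.0, 2.0]
        assert out.loc[out["peptide"] == "DRVYHPF", "normalized_area"].tolist() == [1.0, 1.0]

    def test_spike_drift_between_replicates_cancels(self):
        # replicate r2 measured 2x hotter overall; identical true amounts
        t = pd.DataFrame(
            {
                "peptide": ["DRVYHPF", "pepA", "DRVYHPF", "pepA"],
                "replicate": ["r1", "r1", "r2", "r2"],
                "area": [2000.0, 6000.0, 4000.0, 12000.0],
            }
        )
        out = normalize_spike(t)
        vals = out.loc[out["peptide"] == "pepA", "normalized_area"]
        assert vals.nunique() == 1

    def test_scale_invariance_property(self):
        rng = np.random.default_rng(0)
        areas = rng.uniform(1e3, 1e6, 6)
        t = pd.DataFrame(
            {
                "peptide": ["DRVYHPF", "p1", "p2"] * 2,
                "replicate": ["r1"] * 3 + ["r2"] * 3,
                "area": areas,
            }
        )
        base = normalize_spike(t)["normalized_area"]
        t2 = t.copy()
        t2.loc[t2["replicate"] == "r2", "area"] *= 7.3
        scaled = normalize_spike(t2)["normalized_area"]
        np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_missing_spike_names_the_replicate(self):
        t = pd.DataFrame({"peptide": ["DRVYHPF", "pepA"], "replicate": ["r1", "r2"], "area": [2000.0, 10.0]})
        with pytest.raises(QuantError, match="r2"):
            normalize_spike(t)


def test_quant_params_validation():
    with pytest.raises(QuantError):
        QuantParams(min_width_schedule=(2.0, 10.0))  # not decreasing
    with pytest.raises(QuantError):
        QuantParams(min_width_schedule=(20.0, 10.0), max_width=15.0)
    with pytest.raises(QuantError):
        MzWindow(-1.0)
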