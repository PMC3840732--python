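import json

import numpy as np
import pytest
from gradclean import Recording, evaluate, render_report, slice_harmonics
from gradclean.evaluation import (
    median_imaging_artifact,
    median_residual_activity,
    power_density_reduction,
    rms_ratios,
    snr_corrected,
)

RATE = 250.0


def test_slice_harmonics_fmrib_geometry():
    """TR 3000 ms with 21 slices puts the slice fundamental at exactly
    7 Hz and the harmonics at 14, 21, 28, 35 Hz."""
    f_vol, harmonics = slice_harmonics(3.0, 21)
    assert harmonics == pytest.approx([7.0, 14.0, 21.0, 28.0, 35.0])
    assert f_vol == pytest.approx(1.0 / 3.0)


class TestMedianImagingArtifact:
    def test_constant_channel_zero_range(self):
        rec = Recording(np.full((2, 5000), 9.0), RATE)
        out = median_imaging_artifact(rec, 36.0, (1000, 4000))
        assert out["median"] == 0.0

    def test_full_cycle_sinusoid_peak_to_peak_two(self):
        # 20-sample period hits both extrema exactly on the sample grid,
        # so every interval holding a full cycle has range exactly 2
        x = np.cos(2 * np.pi * np.arange(8000) / 20.0)
        rec = Recording(x[np.newaxis, :], RATE)
        out = median_imaging_artifact(rec, 36.0, (1000, 7000))
        assert out["median"] == pytest.approx(2.0, abs=1e-6)

    def test_interval_length_within_published_range(self):
        from gradclean.evaluation import ARTIFACT_INTERVAL_FACTOR
        assert 1.10 <= ARTIFACT_INTERVAL_FACTOR <= 1.20

    def test_baseline_from_non_acquisition_data(self):
        rng = np.random.default_rng(0)
        data = np.zeros((1, 6000))
        data[0, 2000:4000] = 100 * rng.standard_normal(2000)
        rec = Recording(data, RATE)
        out = median_imaging_artifact(rec, 36.0, (2000, 4000))
        assert out["baseline"]["median"] == 0.0
        assert out["median"] > 100.0


class TestRmsRatios:
    def test_identical_signals_ratio_one(self):
        x = np.random.default_rng(1).standard_normal((3, 1000))
        cu, uc = rms_ratios(x, x, x)
        assert cu["mean"] == pytest.approx(1.0)
        assert uc["mean"] == pytest.approx(1.0)

    def test_double_amplitude_ratio_two(self):
        x = np.random.default_rng(2).standard_normal((2, 1000))
        cu, _ = rms_ratios(x, 2 * x, x)
        assert cu["mean"] == pytest.approx(2.0)

    def test_offsets_do_not_matter(self):
        x = np.random.default_rng(3).standard_normal((2, 1000))
        cu, uc = rms_ratios(x + 100.0, x - 55.0, x + 7.0)
        assert cu["mean"] == pytest.approx(1.0)
        assert uc["mean"] == pytest.approx(1.0)


class TestSNR:
    def _with_power(self, p, n=10000, seed=0):
        x = np.random.default_rng(seed).standard_normal(n)
        x -= x.mean()
        return (x / x.std() * np.sqrt(p))[np.newaxis, :]

    def test_formula_s1_d2_gives_one(self):
        out = snr_corrected(self._with_power(2.0), self._with_power(1.0,
                                                                    seed=1))
        assert out["per_channel"][0] == pytest.approx(1.0, rel=1e-9)

    def test_formula_s4_d5_gives_four(self):
        out = snr_corrected(self._with_power(5.0), self._with_power(4.0,
                                                                    seed=2))
        assert out["per_channel"][0] == pytest.approx(4.0, rel=1e-9)

    def test_negative_noise_power_excluded_and_counted(self):
        corrected = np.vstack([self._with_power(2.0),
                               self._with_power(0.5, seed=3)])
        unimpaired = np.vstack([self._with_power(1.0, seed=4),
                                self._with_power(1.0, seed=5)])
        out = snr_corrected(corrected, unimpaired)
        assert out["n_positive"] == 1
        assert out["n_excluded"] == 1
        assert out["per_channel"][1] is None


class TestResidualActivity:
    def test_identical_content_zero_percent(self):
        x = np.random.default_rng(4).standard_normal((2, 10000))
        out = median_residual_activity(x, x, RATE)
        for band in out.values():
            assert band["median"] == 0.0

    def test_scaled_band_gives_fifty_percent(self):
        """1.5x the activity in every band is a 50% difference."""
        x = np.random.default_rng(5).standard_normal((1, 10000))
        out = median_residual_activity(1.5 * x, x, RATE)
        for band in out.values():
            assert band["median"] == pytest.approx(50.0, abs=1e-9)

    def test_band_edges(self):
        from gradclean.evaluation import BANDS
        assert list(BANDS.values()) == [(0.8, 4.0), (4.0, 8.0),
                                        (8.0, 12.0), (12.0, 24.0)]


class TestPowerDensityReduction:
    def test_identical_zero_db(self):
        x = np.random.default_rng(6).standard_normal((2, 8000))
        out = power_density_reduction(x, x, 7.0, 1.0 / 3, RATE)
        for entry in out.values():
            assert entry["mean_db"] == 0.0

    def test_tenth_magnitude_minus_twenty_db(self):
        x = np.random.default_rng(7).standard_normal((1, 8000))
        out = power_density_reduction(x, 0.1 * x, 7.0, 1.0 / 3, RATE)
        for entry in out.values():
            assert entry["mean_db"] == pytest.approx(-20.0, abs=1e-9)

    def test_harmonic_bins_near_targets(self):
        x = np.random.default_rng(8).standard_normal((1, 8000))
        out = power_density_reduction(x, x, 7.0, 1.0 / 3, RATE)
        for k in range(1, 6):
            entry = out[f"slice_h{k}"]
            assert abs(entry["freq_hz"] - 7.0 * k) < RATE / 8000


def brute_force_rms_ratio(orig, corr, unimp):
    """Independent per-channel loop implementation of the RMS ratios."""
    out = []
    for o, c, u in zip(orig, corr, unimp):
        rms = lambda v: np.sqrt(np.mean((v - np.mean(v)) ** 2))
        out.append((rms(c) / rms(u), rms(o) / rms(c)))
    return np.array(out)


def brute_force_power_reduction(orig, corr, freq, rate):
    out = []
    for o, c in zip(orig, corr):
        fo = np.abs(np.fft.rfft(o - o.mean()))
        fc = np.abs(np.fft.rfft(c - c.mean()))
        f = np.fft.rfftfreq(o.size, 1 / rate)
        b = int(np.argmin(np.abs(f - freq)))
        out.append(10 * np.log10((fc[b] / fo[b]) ** 2))
    return np.array(out)


def test_indicators_match_brute_force_on_random_fixture():
    rng = np.random.default_rng(9)
    orig = rng.standard_normal((4, 6000)) + rng.uniform(-5, 5, (4, 1))
    corr = 0.7 * orig + 0.1 * rng.standard_normal((4, 6000))
    unimp = rng.standard_normal((4, 3000))
    cu, uc = rms_ratios(orig, corr, unimp)
    expect = brute_force_rms_ratio(orig, corr, unimp)
    assert np.allclose(cu["per_channel"], expect[:, 0], atol=1e-9)
    assert np.allclose(uc["per_channel"], expect[:, 1], atol=1e-9)
    pdr = power_density_reduction(orig, corr, 7.0, 1.0 / 3, RATE)
    expect_db = brute_force_power_reduction(orig, corr, 14.0, RATE)
    assert np.allclose(pdr["slice_h2"]["per_channel_db"], expect_db,
                       atol=1e-9)


class TestEvaluate:
    def test_self_comparison_on_synthetic(self, small_synth):
        rec, _ = small_synth
        res = evaluate(rec, rec, n_slices_per_volume=21)
        assert res.rms_uncorrected_to_corrected["mean"] == pytest.approx(1.0)
        for entry in res.power_density_reduction.values():
            assert entry["mean_db"] == pytest.approx(0.0, abs=1e-12)

    def test_channel_subset_respected(self, small_synth):
        rec, _ = small_synth
        res = evaluate(rec, rec, channels=["Ch1"], n_slices_per_volume=21)
        assert res.channels == ["Ch1"]
        assert len(res.rms_corrected_to_unimpaired["per_channel"]) == 1

    def test_deterministic(self, small_synth):
        rec, _ = small_synth
        a = evaluate(rec, rec, n_slices_per_volume=21)
        b = evaluate(rec, rec, n_slices_per_volume=21)
        assert json.dumps(a.as_dict()) == json.dumps(b.as_dict())


class TestRenderReport:
    def test_single_column_and_json_roundtrip(self, small_synth):
        rec, _ = small_synth
        res = evaluate(rec, rec, n_slices_per_volume=21, label="self")
        text, doc = render_report([res])
        assert "self" in text
        assert "Median imaging artifact" in text
        parsed = json.loads(doc)
        assert parsed["results"][0]["label"] == "self"

    def test_side_by_side_labels_verbatim(self, small_synth):
        rec, _ = small_synth
        r1 = evaluate(rec, rec, n_slices_per_volume=21)
        r2 = evaluate(rec, rec, n_slices_per_volume=21)
        text, doc = render_report([(r1, "AAS run"), (r2, "FASTR run")])
        assert "AAS run" in text and "FASTR run" in text
        assert len(json.loads(doc)["results"]) == 2
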