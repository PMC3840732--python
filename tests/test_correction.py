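import numpy as np
import pytest
from scipy.fft import irfft, rfftfreq

import gradclean as g
from gradclean import (
    CorrectionConfig,
    EpochMatrix,
    compute_template,
    downsample,
    fft_shift,
    logistic_weight,
    run_sequence,
    solve_logistic_anchors,
    upsample,
)
from gradclean.averaging import AveragingMatrix, build_fastr_slice
from gradclean.correction import align_slices, align_subsample


def _bandlimited(n, lo=0.01, hi=0.2, seed=0):
    rng = np.random.default_rng(seed)
    f = rfftfreq(n)
    spec = ((f > lo) & (f < hi)) * np.exp(2j * np.pi * rng.random(f.size))
    x = irfft(spec, n=n)
    return x / x.std()


class TestResampling:
    def test_factor_one_is_identity(self):
        x = np.arange(20.0)
        assert np.array_equal(upsample(x, 1), x)
        assert np.array_equal(downsample(x, 1), x)

    def test_roundtrip_bandlimited(self):
        from scipy.signal.windows import tukey

        x = _bandlimited(16000) * tukey(16000, 0.1)
        z = downsample(upsample(x, 10), 10)
        rel = np.sqrt(np.mean((z - x) ** 2)) / x.std()
        assert rel < 1e-3

    def test_upsample_length_and_samples(self):
        x = _bandlimited(4000)
        y = upsample(x, 10)
        assert y.size == 40000
        # interior original samples are closely reproduced
        assert np.allclose(y[5000:35000:10], x[500:3500], atol=5e-4)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            upsample(np.zeros(10), 0)
        with pytest.raises(ValueError):
            downsample(np.zeros(10), -2)


class TestLogisticWeight:
    def test_printed_anchor_values(self):
        alpha, x0 = solve_logistic_anchors()
        assert logistic_weight(0.80, alpha, x0) == pytest.approx(0.50,
                                                                 abs=1e-12)
        assert logistic_weight(0.69, alpha, x0) == pytest.approx(0.10,
                                                                 abs=1e-12)

    def test_third_anchor_follows(self):
        """The two fitted parameters place 1% weight at 57% of the
        interval."""
        alpha, x0 = solve_logistic_anchors()
        assert logistic_weight(0.57, alpha, x0) == pytest.approx(0.01,
                                                                 abs=0.001)

    def test_parameter_values(self):
        alpha, x0 = solve_logistic_anchors()
        assert x0 == pytest.approx(0.80, abs=1e-12)
        assert alpha == pytest.approx(-np.log(9.0) / 0.11, rel=1e-12)


class TestSubsampleShift:
    @pytest.mark.parametrize("delta", [-0.45, -0.3, 0.0, 0.3, 0.45])
    def test_constructed_shift_recovered(self, delta):
        """A shift constructed by the FFT linear-phase rule is recovered
        with the opposite sign to within 0.01 samples."""
        base = _bandlimited(432, seed=3)
        D = np.stack([base, fft_shift(base, delta)])
        em = EpochMatrix(D, np.array([0, 432]), 360, 36)
        _, shifts = align_subsample(em, reference=0, tol=1e-3)
        assert shifts[1] == pytest.approx(-delta, abs=0.01)

    def test_identical_epoch_zero_shift(self):
        base = _bandlimited(432, seed=4)
        em = EpochMatrix(np.stack([base, base]), np.array([0, 432]), 360, 36)
        aligned, shifts = align_subsample(em, reference=0)
        assert shifts[1] == pytest.approx(0.0, abs=1e-3)
        assert np.array_equal(aligned.D[1], base)

    def test_non_finite_rejected(self):
        D = np.ones((2, 64))
        D[1, 3] = np.nan
        em = EpochMatrix(D, np.array([0, 64]), 64, 0)
        with pytest.raises(ValueError, match="non-finite"):
            align_subsample(em, reference=0)


class TestAlignSlices:
    def test_identical_epochs_zero_shift(self):
        seg = np.tile(_bandlimited(360, seed=5), 6)
        starts = np.arange(1, 5) * 360
        D = np.stack([seg[s - 36:s + 396] for s in starts])
        em = EpochMatrix(D, starts, 360, 36)
        _, shifts = align_slices(seg, em, reference=1, max_lag=10)
        assert np.array_equal(shifts, np.zeros(4, dtype=int))

    def test_delayed_epoch_recovered(self):
        base = np.tile(_bandlimited(360, seed=6), 10)
        seg = base.copy()
        # epoch at 720 delayed by 3 samples; epoch at 1440 is the reference
        seg[684:1116] = base[681:1113]
        starts = np.array([720, 1440, 2160])
        D = np.stack([seg[s - 36:s + 396] for s in starts])
        em = EpochMatrix(D, starts, 360, 36)
        aligned, shifts = align_slices(seg, em, reference=1, max_lag=10)
        assert shifts[0] == -3
        assert aligned.epoch_starts[0] == 723

    def test_boundary_shift_clamped(self):
        # slow sinusoid: the correlation grows monotonically toward the
        # (out-of-range) true lag, so the search clamps at its boundary
        base = np.sin(2 * np.pi * np.arange(3600) / 72.0)
        seg = base.copy()
        seg[684:1116] = base[664:1096]  # delayed by 20 > max_lag
        starts = np.array([720, 1440, 2160])
        D = np.stack([seg[s - 36:s + 396] for s in starts])
        em = EpochMatrix(D, starts, 360, 36)
        _, shifts = align_slices(seg, em, reference=1, max_lag=10)
        assert abs(shifts[0]) == 10


class TestComputeTemplate:
    def test_identity_matrix_reproduces_data(self):
        rng = np.random.default_rng(8)
        D = rng.standard_normal((5, 20))
        em = EpochMatrix(D, np.arange(5) * 20, 20, 0)
        A = AveragingMatrix(np.eye(5), "identity")
        out = compute_template(em, A, out_len=100)
        assert np.allclose(out, D.ravel(), atol=1e-12)

    def test_uniform_matrix_on_identical_epochs(self):
        epoch = np.sin(np.linspace(0, 7, 20))
        D = np.tile(epoch, (4, 1))
        em = EpochMatrix(D, np.arange(4) * 20, 20, 0)
        A = AveragingMatrix(np.full((4, 4), 0.25), "uniform")
        out = compute_template(em, A, out_len=80)
        assert np.allclose(out, np.tile(epoch, 4), atol=1e-12)

    @pytest.mark.parametrize("fill", ["zero", "linear"])
    def test_gap_fill_modes(self, fill):
        D = np.ones((2, 10))
        em = EpochMatrix(D, np.array([0, 20]), 10, 0)  # gap 10..20
        out = compute_template(em, AveragingMatrix(np.eye(2), "id"),
                               gap_fill=fill, out_len=30)
        gap = out[10:20]
        if fill == "zero":
            assert np.allclose(gap, 0.0)
        else:
            assert np.allclose(gap, 1.0)  # bridge between equal endpoints

    def test_dimension_mismatch_rejected(self):
        em = EpochMatrix(np.zeros((3, 5)), np.arange(3) * 5, 5, 0)
        with pytest.raises(ValueError, match="epochs"):
            compute_template(em, AveragingMatrix(np.eye(4), "id"))


@pytest.fixture(scope="module")
def prepared():
    spec = g.SyntheticSpec(n_v=6, n_channels=2, pre_duration=6.0,
                           post_duration=6.0, seed=21)
    rec, truth = g.generate(spec)
    ts = g.find_triggers(rec, "slice")
    return rec, truth, ts


class TestRunSequence:
    def test_empty_sequence_is_identity(self, prepared):
        rec, _, ts = prepared
        cleaned, artifact, _ = run_sequence(rec, ts, CorrectionConfig())
        assert np.array_equal(cleaned.data, rec.data)
        assert not np.any(artifact.data)

    def test_cut_paste_roundtrip(self, prepared):
        rec, _, ts = prepared
        cfg = CorrectionConfig(sequence=["cut", "paste"])
        cleaned, artifact, _ = run_sequence(rec, ts, cfg)
        assert np.allclose(cleaned.data, rec.data, atol=1e-9)

    def test_cut_upsample_downsample_paste_conserves(self, prepared):
        rec, _, ts = prepared
        cfg = CorrectionConfig(
            sequence=["cut", "upsample", "downsample", "paste"])
        cleaned, artifact, _ = run_sequence(rec, ts, cfg)
        resid = cleaned.data + artifact.data - rec.data
        rel = np.sqrt((resid ** 2).mean()) / np.sqrt((rec.data ** 2).mean())
        assert rel < 1e-9

    def test_conservation_for_full_sequence(self, prepared):
        rec, _, ts = prepared
        cfg = CorrectionConfig(
            sequence=["cut", "upsample", "align_slices", "align_subsample",
                      "template", "obs", "downsample", "paste", "lowpass",
                      "anc"],
            avg_matrix={"scheme": "allen", "block": 100}, obs_num_pcs=2,
            rng_seed=3)
        cleaned, artifact, _ = run_sequence(rec, ts, cfg)
        resid = cleaned.data + artifact.data - rec.data
        rel = np.sqrt((resid ** 2).mean()) / np.sqrt((rec.data ** 2).mean())
        assert rel < 1e-9

    def test_excluded_channels_untouched(self, prepared):
        rec, _, ts = prepared
        cfg = CorrectionConfig(sequence=["cut", "template", "paste"],
                               avg_matrix={"scheme": "fastr_slice"},
                               exclude_channels=["Ch2"])
        cleaned, artifact, _ = run_sequence(rec, ts, cfg)
        assert np.array_equal(cleaned.data[1], rec.data[1])
        assert not np.array_equal(cleaned.data[0], rec.data[0])

    def test_outside_region_bit_identical(self, prepared):
        rec, _, ts = prepared
        cfg = CorrectionConfig(
            sequence=["cut", "template", "paste", "lowpass", "anc"],
            avg_matrix={"scheme": "fastr_slice"})
        cleaned, _, _ = run_sequence(rec, ts, cfg)
        a, b = rec.acq_span
        pad = int(round(ts.median_spacing))
        assert np.array_equal(cleaned.data[:, :a - pad],
                              rec.data[:, :a - pad])
        assert np.array_equal(cleaned.data[:, b + pad:],
                              rec.data[:, b + pad:])

    def test_unknown_block_rejected(self, prepared):
        rec, _, ts = prepared
        with pytest.raises(ValueError, match="unknown correction block"):
            run_sequence(rec, ts, CorrectionConfig(sequence=["shazam"]))

    def test_unpaired_blocks_rejected(self, prepared):
        rec, _, ts = prepared
        with pytest.raises(ValueError, match="paste"):
            run_sequence(rec, ts, CorrectionConfig(sequence=["paste"]))
        with pytest.raises(ValueError, match="paired"):
            run_sequence(rec, ts, CorrectionConfig(sequence=["cut",
                                                             "upsample"]))

    def test_user_callable_supplies_matrix(self, prepared):
        rec, _, ts = prepared

        calls = []

        def my_matrix(state):
            calls.append(state.ch)
            return build_fastr_slice(ts.n_e, window=10)

        cfg = CorrectionConfig(sequence=["cut", my_matrix, "template",
                                         "paste"])
        cleaned, artifact, _ = run_sequence(rec, ts, cfg)
        assert calls == [0, 1]
        a, b = rec.acq_span
        # the artifact template removed most of the artifact power
        assert cleaned.data[0, a:b].std() < 0.2 * rec.data[0, a:b].std()


class TestVolumeGapCorrection:
    def test_no_gaps_is_identity(self):
        spec = g.SyntheticSpec(n_v=4, n_channels=1, seed=30)
        rec, _ = g.generate(spec)
        ts = g.find_triggers(rec, "slice")
        assert ts.volume_gap_after.size == 0
        cfg = CorrectionConfig(sequence=["cut", "remove_volume_artifact",
                                         "paste"])
        cleaned, _, _ = run_sequence(rec, ts, cfg)
        assert np.allclose(cleaned.data, rec.data, atol=1e-9)

    def test_gap_is_linearly_bridged(self, gap_synth):
        rec, truth = gap_synth
        ts = g.find_triggers(rec, "slice")
        assert ts.volume_gap_after.size == 5
        cfg = CorrectionConfig(sequence=["cut", "remove_volume_artifact",
                                         "paste"])
        cleaned, artifact, _ = run_sequence(rec, ts, cfg)
        # inside the first gap the data is now a straight line
        e = int(ts.volume_gap_after[0])
        g0 = int(ts.latencies[e]) + 36
        g1 = int(ts.latencies[e + 1])
        seg = cleaned.data[0, g0:g1]
        second_diff = np.diff(seg, n=2)
        assert np.abs(second_diff).max() < 1e-9
        # the volume transient that lived in the gap is gone
        assert seg.std() < truth.artifact[0, g0:g1].std()
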