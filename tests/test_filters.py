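"""Filter design, evaluation, cascading and application."""

import numpy as np
import pytest

from ecgkit.filters import (TransferFunction, apply_filter,
                            bilinear_discretize, cascade, design_butterworth,
                            design_fir, evaluate_response, read_coefficients,
                            write_coefficients)
from ecgkit.filters import unity
from ecgkit.presets import (bandpass_4th_analog, bandstop_16th_analog,
                            fir60_taps, lowpass_32nd_analog,
                            reduced_order_reference, sixteen_order_cascade)
from ecgkit.record import ECGRecord
from ecgkit.synthetic import SimulationConfig, generate_ecg


class TestButterworth:
    def test_bandpass_qrs_band(self):
        tf = design_butterworth("pass", 5.0, 15.0, 2, 360.0)
        center = abs(evaluate_response(tf, [np.sqrt(5 * 15)]))[0]
        edges = np.abs(evaluate_response(tf, [5.0, 15.0]))
        assert center >= 0.89
        np.testing.assert_allclose(edges, 0.707, atol=0.02)
        assert tf.is_stable()

    def test_bandstop_mains(self):
        tf = design_butterworth("stop", 49.0, 51.0, 2, 360.0)
        assert abs(evaluate_response(tf, [50.0]))[0] <= 0.1
        assert tf.is_stable()

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_butterworth("pass", 200.0, 250.0, 2, 360.0)

    def test_order_below_one_rejected(self):
        with pytest.raises(ValueError):
            design_butterworth("pass", 5.0, 15.0, 0, 360.0)


class TestFir:
    def test_highpass_nulls_dc_and_is_linear_phase(self):
        tf = design_fir("highpass", 0.5, 60, 360.0)
        assert tf.num.size == 61
        assert abs(np.sum(tf.num)) <= 1e-3
        np.testing.assert_allclose(tf.num, tf.num[::-1], atol=1e-9)

    def test_bandstop_notch_depth_and_passband(self):
        tf = design_fir("bandstop", (45.0, 55.0), 100, 360.0)
        assert tf.num.size == 101
        assert abs(evaluate_response(tf, [50.0]))[0] <= 0.1
        assert abs(evaluate_response(tf, [10.0]))[0] >= 0.9

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError, match="even"):
            design_fir("highpass", 0.5, 61, 360.0)

    def test_reference_60th_order_tap_vector_is_symmetric(self):
        taps = fir60_taps()
        assert taps.size == 61
        np.testing.assert_array_equal(taps, taps[::-1])
        assert taps[1] == pytest.approx(0.0004528)


class TestCascade:
    def test_unity_is_identity_element(self):
        h = design_butterworth("pass", 5.0, 15.0, 2, 360.0)
        combined = cascade(unity("z", 360.0), h)
        grid = np.linspace(1.0, 170.0, 50)
        np.testing.assert_allclose(
            np.abs(evaluate_response(combined, grid)),
            np.abs(evaluate_response(h, grid)), atol=1e-12)

    def test_degrees_add_for_reference_stages(self):
        combined = cascade(bandpass_4th_analog(), bandstop_16th_analog())
        assert combined.num.size - 1 == 20
        assert combined.den.size - 1 == 20

    def test_response_is_pointwise_product(self):
        a = design_butterworth("pass", 5.0, 15.0, 2, 360.0)
        b = design_butterworth("stop", 49.0, 51.0, 3, 360.0)
        grid = np.linspace(0.5, 175.0, 50)
        lhs = np.abs(evaluate_response(cascade(a, b), grid))
        rhs = np.abs(evaluate_response(a, grid)) * np.abs(evaluate_response(b, grid))
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_mixed_domain_rejected(self):
        with pytest.raises(ValueError, match="domain"):
            cascade(bandpass_4th_analog(),
                    design_butterworth("pass", 5, 15, 2, 360.0))

    def test_associativity_on_grid(self):
        a = design_butterworth("pass", 5.0, 15.0, 1, 360.0)
        b = design_butterworth("stop", 49.0, 51.0, 1, 360.0)
        c = design_fir("highpass", 0.5, 10, 360.0)
        grid = np.linspace(1.0, 170.0, 50)
        left = np.abs(evaluate_response(cascade(cascade(a, b), c), grid))
        right = np.abs(evaluate_response(cascade(a, cascade(b, c)), grid))
        np.testing.assert_allclose(left, right, atol=1e-9)


class TestEvaluateResponse:
    def test_unity_gain_everywhere(self):
        gains = evaluate_response(unity("z", 360.0), [1.0, 10.0, 100.0])
        np.testing.assert_allclose(gains, 1.0)

    def test_reduced_order_reference_at_dc(self):
        g = evaluate_response(reduced_order_reference(), [0.0])[0]
        assert g == pytest.approx(14 / 41)

    def test_bandpass_reference_at_dc(self):
        g = evaluate_response(bandpass_4th_analog(), [0.0])[0]
        assert g == pytest.approx(0.2066 / 0.1958)

    def test_pole_on_contour_flagged_with_frequency(self):
        # analog poles at s = +/- j*2*pi*5: evaluation at exactly 5 Hz hits one
        w0 = 2 * np.pi * 5.0
        tf = TransferFunction([1.0], [1.0, 0.0, w0 ** 2], "s")
        with pytest.raises(ZeroDivisionError, match="5.0"):
            evaluate_response(tf, [1.0, 5.0])

    def test_unstable_reference_is_detected(self):
        assert not lowpass_32nd_analog().is_stable()
        assert sixteen_order_cascade().is_stable()


class TestApplyFilter:
    def test_identity_passthrough(self, clean_record):
        record, _ = clean_record
        out = apply_filter(unity("z", record.fs), record)
        np.testing.assert_allclose(out.samples, record.samples)

    def test_zero_numerator_zeroes_output(self, clean_record):
        record, _ = clean_record
        tf = TransferFunction([0.0], [1.0], "z", record.fs)
        assert not np.any(apply_filter(tf, record).samples)

    def test_lowpass_keeps_1hz_rejects_100hz(self):
        fs, dur = 360.0, 10.0
        t = np.arange(int(fs * dur)) / fs
        tf = design_butterworth("pass", 0.2, 40.0, 4, fs)
        for f, check in [(1.0, "pass"), (100.0, "stop")]:
            rec = ECGRecord(np.sin(2 * np.pi * f * t), fs)
            out = apply_filter(tf, rec, zero_phase=True)
            # steady-state amplitude from the FFT bin of the middle segment
            mid = slice(int(2 * fs), int(8 * fs))
            amp = (np.abs(np.fft.rfft(out.samples[mid]))
                   / np.abs(np.fft.rfft(rec.samples[mid]))).max()
            spectrum_in = np.abs(np.fft.rfft(rec.samples[mid]))
            k = int(np.argmax(spectrum_in))
            gain = np.abs(np.fft.rfft(out.samples[mid]))[k] / spectrum_in[k]
            if check == "pass":
                assert gain == pytest.approx(1.0, rel=0.02)
            else:
                assert gain <= 10 ** (-20 / 20)

    def test_unstable_filter_rejected(self, clean_record):
        record, _ = clean_record
        tf = TransferFunction([1.0], [1.0, -2.0], "z", record.fs)
        with pytest.raises(ValueError, match="unstable"):
            apply_filter(tf, record)

    def test_fs_mismatch_rejected(self, clean_record):
        record, _ = clean_record
        tf = design_butterworth("pass", 5, 15, 2, 500.0)
        with pytest.raises(ValueError, match="fs"):
            apply_filter(tf, record)

    def test_output_length_preserved(self, clean_record):
        record, _ = clean_record
        tf = design_fir("highpass", 0.5, 60, record.fs)
        for zp in (False, True):
            assert apply_filter(tf, record, zero_phase=zp).n_samples == record.n_samples


class TestBaselineRemoval:
    def test_wander_suppressed_r_peaks_preserved(self):
        from ecgkit.pipeline import PipelineConfig

        cfg = SimulationConfig(fs=360.0, duration=30.0, heart_rate=60.0,
                               rr_jitter_sd=0.0, baseline_amplitude=0.5,
                               baseline_frequency=0.3, seed=5)
        record, truth = generate_ecg(cfg)
        clean_cfg = SimulationConfig(fs=360.0, duration=30.0, heart_rate=60.0,
                                     rr_jitter_sd=0.0, seed=5)
        clean, _ = generate_ecg(clean_cfg)

        order = PipelineConfig().resolved_baseline_order(record.fs)
        hp = design_fir("highpass", 0.5, order, record.fs)
        out = apply_filter(hp, record, zero_phase=True)

        # wander amplitude at 0.3 Hz before and after, via the FFT bin
        freqs = np.fft.rfftfreq(record.n_samples, 1 / record.fs)
        k = int(np.argmin(np.abs(freqs - 0.3)))
        before = np.abs(np.fft.rfft(record.samples))[k]
        after = np.abs(np.fft.rfft(out.samples))[k]
        assert after <= 0.1 * before

        r = truth.r_indices
        change = np.abs(out.samples[r] - clean.samples[r]) / clean.samples[r]
        assert np.max(change) <= 0.10


class TestBilinearAndCoefficientsIo:
    def test_bilinear_preserves_dc_gain(self):
        tf = reduced_order_reference()
        dz = bilinear_discretize(tf, 360.0)
        g_s = abs(evaluate_response(tf, [0.0]))[0]
        g_z = abs(evaluate_response(dz, [0.0]))[0]
        assert g_z == pytest.approx(g_s, rel=1e-9)

    def test_coefficient_csv_round_trip(self, tmp_path):
        tf = design_butterworth("pass", 5.0, 15.0, 2, 360.0)
        path = tmp_path / "coeffs.csv"
        write_coefficients(path, tf)
        back = read_coefficients(path)
        np.testing.assert_allclose(back.num, tf.num)
        np.testing.assert_allclose(back.den, tf.den)
        assert back.fs == tf.fs and back.domain == "z"
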