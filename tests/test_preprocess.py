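import numpy as np
import pytest
from scipy import signal

from oscillotap.montage import standard_positions
from oscillotap.preprocess import (
    FilterDesignError,
    ICAConvergenceError,
    STAGE_ORDER,
    average_reference,
    bandpass_notch,
    default_blink_detector,
    detect_bad_channels,
    downsample,
    ica_blink_removal,
    interpolate_spherical_spline,
    preprocess_pipeline,
    spherical_spline_matrix,
)
from oscillotap.simulate import ContinuousRecording, DEFAULT_EEG_LABELS, Event


def make_recording(data, fs=2000.0, labels=None, events=()):
    if labels is None:
        labels = tuple(DEFAULT_EEG_LABELS[: data.shape[0] - 1]) + ("EMG",)
    return ContinuousRecording(data=data, fs=fs, channel_labels=labels, events=events)


class TestDownsample:
    def test_sinusoid_amplitude_preserved(self):
        fs = 2000.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = make_recording(np.vstack([x, x]), fs, labels=("Cz", "EMG"))
        out = downsample(rec, 256.0)
        t2 = np.arange(out.n_samples) / out.fs
        ref = np.sin(2 * np.pi * 10.0 * t2)
        interior = slice(256, -256)
        amp = np.abs(out.data[0][interior]).max()
        assert abs(amp - 1.0) < 0.01
        assert np.abs(out.data[0][interior] - ref[interior]).max() < 0.01

    def test_event_time_preserved(self):
        rec = make_recording(np.zeros((2, 8000)), 2000.0, labels=("Cz", "EMG"),
                             events=(Event(4000, "ToneOnly", 70.0),))
        out = downsample(rec, 256.0)
        assert abs(out.events[0].sample / out.fs - 2.0) <= 0.5 / out.fs

    def test_high_frequency_attenuated(self):
        fs = 2000.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 500.0 * t)
        rec = make_recording(np.vstack([x, x]), fs, labels=("Cz", "EMG"))
        out = downsample(rec, 256.0)
        power_in = 0.5  # unit sinusoid
        power_out = np.mean(out.data[0] ** 2)
        assert 10 * np.log10(power_in / max(power_out, 1e-30)) > 40.0

    def test_upsampling_rejected(self):
        rec = make_recording(np.zeros((2, 100)), 256.0, labels=("Cz", "EMG"))
        with pytest.raises(ValueError):
            downsample(rec, 512.0)


class TestAverageReference:
    def test_channel_mean_is_zero_and_emg_untouched(self, rng):
        data = rng.standard_normal((9, 1000)) * 20
        rec = make_recording(data.copy(), 256.0)
        out = average_reference(rec)
        eeg = out.data[out.eeg_picks]
        assert np.abs(eeg.mean(axis=0)).max() < 1e-10
        assert np.array_equal(out.data[out.emg_index], data[-1])

    def test_identical_channels_zeroed(self):
        data = np.ones((5, 100))
        rec = make_recording(data, 256.0)
        out = average_reference(rec)
        assert np.abs(out.data[out.eeg_picks]).max() == 0.0

    def test_idempotent(self, rng):
        rec = make_recording(rng.standard_normal((9, 500)), 256.0)
        once = average_reference(rec)
        twice = average_reference(once)
        assert np.allclose(once.data, twice.data)

    def test_single_channel_rejected(self):
        rec = make_recording(np.zeros((2, 100)), 256.0, labels=("Cz", "EMG"))
        with pytest.raises(ValueError):
            average_reference(rec)


class TestBandpassNotch:
    def _tone(self, freq, fs=256.0, seconds=60.0):
        t = np.arange(int(seconds * fs)) / fs
        return np.sin(2 * np.pi * freq * t)

    def test_passband_tone_unity_gain_zero_lag(self):
        fs = 256.0
        x = self._tone(10.0, fs)
        rec = make_recording(np.vstack([x, x]), fs, labels=("Cz", "EMG"))
        y = bandpass_notch(rec).data[0]
        interior = slice(int(20 * fs), int(40 * fs))
        t = np.arange(len(x)) / fs
        # projection onto the complex carrier gives amplitude free of transients
        amp = 2 * np.abs(np.mean(y[interior] * np.exp(-2j * np.pi * 10.0 * t[interior])))
        assert 0.95 <= amp <= 1.05
        xc = signal.correlate(y[interior], x[interior])
        lags = signal.correlation_lags(len(x[interior]), len(x[interior]))
        assert lags[np.argmax(xc)] == 0

    def test_notch_attenuates_60hz(self):
        fs = 256.0
        x = self._tone(60.0, fs)
        rec = make_recording(np.vstack([x, x]), fs, labels=("Cz", "EMG"))
        y = bandpass_notch(rec).data[0]
        interior = slice(int(20 * fs), int(40 * fs))
        att = 10 * np.log10(np.mean(x[interior] ** 2) / np.mean(y[interior] ** 2))
        assert att >= 20.0

    def test_dc_offset_removed(self):
        fs = 256.0
        x = np.full(int(60 * fs), 100.0)
        rec = make_recording(np.vstack([x, x]), fs, labels=("Cz", "EMG"))
        y = bandpass_notch(rec).data[0]
        interior = slice(int(20 * fs), -int(20 * fs))
        assert abs(y[interior].mean()) < 1.0

    def test_zero_phase_preserves_pulse_symmetry(self):
        fs = 256.0
        n = int(120 * fs) + 1
        x = np.zeros(n)
        center = n // 2
        x[center - 10:center + 11] = signal.windows.hann(21)
        rec = make_recording(np.vstack([x, x]), fs, labels=("Cz", "EMG"))
        y = bandpass_notch(rec, notch=None).data[0]
        assert np.abs(y[:center] - y[center + 1:][::-1]).max() < 1e-6

    def test_invalid_passband_rejected(self):
        rec = make_recording(np.zeros((2, 1000)), 256.0, labels=("Cz", "EMG"))
        with pytest.raises(FilterDesignError):
            bandpass_notch(rec, passband=(0.1, 200.0))
        with pytest.raises(FilterDesignError):
            bandpass_notch(rec, passband=(0.0, 30.0))


@pytest.fixture(scope="module")
def conditioned_session():
    """Reduced session downsampled/referenced/filtered, ready for ICA."""
    import warnings

    from oscillotap.simulate import EffectSpec, SimConfig, generate_session

    cfg = SimConfig(
        n_participants=1, n_channels=35, fs_raw=512.0, trial_duration=5.0,
        n_trials_per_condition=2, rates=(70.0,), conditions=("Relaxing", "ToneOnly"),
        blink_rate=30.0, seed=3,
    )
    rec_raw = generate_session(cfg, 0)
    rec = downsample(rec_raw, 256.0)
    blink_mask = np.zeros(rec.n_samples, dtype=bool)
    dur = rec.annotations["blink_duration_samples"]
    for s in rec.annotations["blink_samples"]:
        blink_mask[s:s + dur] = True
    rec = bandpass_notch(average_reference(rec))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean, decomposition = ica_blink_removal(rec, random_state=0)
    return rec, clean, decomposition, blink_mask


class TestICA:
    def test_full_reconstruction_identity(self, conditioned_session, quiet_warnings):
        rec, _, _, _ = conditioned_session
        clean, _ = ica_blink_removal(rec, flagged=(), random_state=0)
        picks = rec.eeg_picks
        rel = (np.abs(clean.data[picks] - rec.data[picks]).max()
               / np.abs(rec.data[picks]).max())
        assert rel < 1e-6

    def test_one_blink_component_flagged(self, conditioned_session):
        _, _, decomposition, _ = conditioned_session
        assert len(decomposition.flagged) == 1

    def test_blink_variance_removed_frontal_preserved_central(self, conditioned_session):
        rec, clean, _, blink_mask = conditioned_session
        fp = rec.channel_labels.index("Fp1")
        cz = rec.channel_labels.index("Cz")
        frontal_reduction = 1 - (clean.data[fp][blink_mask].var()
                                 / rec.data[fp][blink_mask].var())
        assert frontal_reduction >= 0.80
        cz_change = abs(clean.data[cz][~blink_mask].var()
                        / rec.data[cz][~blink_mask].var() - 1)
        assert cz_change < 0.10

    def test_manual_flag_equals_detector_path(self, conditioned_session, quiet_warnings):
        rec, clean, decomposition, _ = conditioned_session
        manual, _ = ica_blink_removal(rec, flagged=decomposition.flagged,
                                      random_state=0)
        assert np.allclose(manual.data, clean.data)

    def test_flagging_everything_rejected(self, conditioned_session, quiet_warnings):
        rec, _, decomposition, _ = conditioned_session
        with pytest.raises(ICAConvergenceError):
            ica_blink_removal(rec, flagged=tuple(range(decomposition.n_components)),
                              random_state=0)


class TestSphericalSpline:
    @pytest.fixture(scope="class")
    def positions(self):
        return standard_positions(DEFAULT_EEG_LABELS)

    def test_constant_field_reproduced(self, positions):
        P = positions.array(DEFAULT_EEG_LABELS)
        W = spherical_spline_matrix(P[1:], P[:1])
        assert abs((W @ np.ones(len(P) - 1))[0] - 1.0) < 1e-3

    def test_leave_one_out_on_smooth_harmonic(self, positions):
        P = positions.array(DEFAULT_EEG_LABELS)
        field = P[:, 0] * P[:, 2] + 0.5 * P[:, 1]   # low-order spherical harmonic mix
        scale = np.abs(field).max()
        for i in range(0, len(P), 7):
            keep = [j for j in range(len(P)) if j != i]
            W = spherical_spline_matrix(P[keep], P[[i]])
            est = (W @ field[keep])[0]
            assert abs(est - field[i]) / scale < 0.05

    def test_empty_bad_set_is_identity(self, rng):
        data = rng.standard_normal((9, 100))
        rec = make_recording(data.copy(), 256.0)
        out = interpolate_spherical_spline(rec, [])
        assert np.array_equal(out.data, data)

    def test_good_channels_untouched(self, rng):
        labels = tuple(DEFAULT_EEG_LABELS[:8]) + ("EMG",)
        data = rng.standard_normal((9, 100))
        rec = make_recording(data.copy(), 256.0, labels=labels)
        out = interpolate_spherical_spline(rec, ["Fp1"])
        for i, l in enumerate(labels):
            if l not in ("Fp1",):
                assert np.array_equal(out.data[i], data[i])

    def test_too_few_good_channels_rejected(self, rng):
        labels = tuple(DEFAULT_EEG_LABELS[:5]) + ("EMG",)
        rec = make_recording(np.zeros((6, 50)), 256.0, labels=labels)
        with pytest.raises(ValueError):
            interpolate_spherical_spline(rec, list(labels[:2]))


class TestPipelineDriver:
    def test_stage_order_asserted_and_logged(self, small_session, quiet_warnings):
        _, rec = small_session
        clean, log = preprocess_pipeline(rec, bad_channels=("F3",), target_fs=256.0)
        assert tuple(log["stages"]) == STAGE_ORDER
        assert clean.fs == 256.0
        assert set(clean.channel_labels) == set(rec.channel_labels)

    def test_auto_bad_channel_detection_flags_dead_channel(self, rng):
        data = rng.standard_normal((17, 5000)) * 10
        data[3] *= 2000.0
        rec = make_recording(data, 512.0)
        assert rec.channel_labels[3] in detect_bad_channels(rec)
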