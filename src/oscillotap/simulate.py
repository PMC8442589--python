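"""Synthetic EEG/EMG session generator for paced finger tapping.

Emulates the statistical structure a movement-locked time-frequency analysis
assumes: a multichannel 10-20 montage riding on 1/f^alpha background noise,
band-limited power modulation (ERD/ERS) locked to tap onsets, stereotyped
blink transients with a fixed frontal topography, and an EMG channel carrying
a high-frequency burst at every tap.  Every draw is governed by a single seed
so that equal configurations produce bit-identical sessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "DEFAULT_EEG_LABELS",
    "EMG_LABEL",
    "EffectSpec",
    "SimConfig",
    "Event",
    "ContinuousRecording",
    "InvalidConfigError",
    "tap_times",
    "powerlaw_noise",
    "generate_session",
]


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# 64-channel 10-10 layout (all names resolvable in the standard montage).
DEFAULT_EEG_LABELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

EMG_LABEL = "EMG"

# Relative blink amplitude by electrode-name prefix; anything else gets a
# small far-field leak.  The topography is rank-1 by construction.
_BLINK_TOPOGRAPHY_WEIGHTS = {"Fp": 1.0, "AF": 0.7, "F": 0.35, "FT": 0.1, "FC": 0.1}
_BLINK_FARFIELD = 0.02


@dataclass(frozen=True)
class EffectSpec:
    """A movement-locked multiplicative modulation of band-limited power.

    ``gain`` < 1 is a desynchronization (ERD), ``gain`` > 1 a synchronization
    (ERS).  The modulation multiplies the power of the background in
    ``band`` by ``gain`` inside ``window`` (ms relative to each tap onset of
    ``condition``) on the listed channels.
    """

    condition: str
    band: tuple[float, float]
    window: tuple[float, float]
    gain: float
    channels: tuple[str, ...] = ("C3", "Cz", "FCz")

    def __post_init__(self):
        f_lo, f_hi = self.band
        if not (1.0 <= f_lo < f_hi <= 30.0):
            raise InvalidConfigError(
                f"effect band {self.band} must satisfy 1 <= f_lo < f_hi <= 30 Hz"
            )
        if self.gain <= 0:
            raise InvalidConfigError("effect gain must be positive")
        if self.window[0] >= self.window[1]:
            raise InvalidConfigError("effect window must have t_start < t_end")


@dataclass(frozen=True)
class SimConfig:
    """Full generative description of a synthetic tapping session.

    Defaults mirror the study design this pipeline targets: 64 EEG channels
    sampled at 2000 Hz, four 10 s trials per condition, three cue conditions
    each paced at 70 and 140 BPM, pink (1/f) background noise, blinks at a
    typical spontaneous rate, and an EMG burst at every tap.
    """

    n_participants: int = 20
    n_channels: int = 64
    fs_raw: float = 2000.0
    trial_duration: float = 10.0
    n_trials_per_condition: int = 4
    rates: tuple[float, ...] = (70.0, 140.0)
    conditions: tuple[str, ...] = ("Activating", "Relaxing", "ToneOnly")
    noise_exponent: float = 1.0
    noise_scale: float = 10.0           # background RMS per channel, uV
    erd_spec: tuple[EffectSpec, ...] = ()
    blink_rate: float = 15.0            # events per minute
    blink_amplitude: float = 150.0      # peak at Fp sites, uV
    emg_burst_ms: float = 100.0
    emg_burst_amplitude: float = 100.0  # burst RMS, uV
    tap_jitter_ms: float = 10.0
    inter_trial_gap: float = 2.0        # silent padding around trials, s
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise InvalidConfigError("n_participants must be >= 1")
        if self.n_channels < 1 or self.n_channels > len(DEFAULT_EEG_LABELS):
            raise InvalidConfigError(
                f"n_channels must be in [1, {len(DEFAULT_EEG_LABELS)}]"
            )
        if any(r <= 0 for r in self.rates):
            raise InvalidConfigError("all rates must be positive (BPM)")
        if self.fs_raw <= 2 * 30.0:
            raise InvalidConfigError("fs_raw must exceed twice the highest simulated frequency")
        for spec in self.erd_spec:
            if spec.band[1] >= self.fs_raw / 2:
                raise InvalidConfigError(
                    f"effect band {spec.band} exceeds Nyquist ({self.fs_raw / 2} Hz)"
                )
            if spec.condition not in self.conditions:
                raise InvalidConfigError(
                    f"effect condition {spec.condition!r} not among {self.conditions}"
                )

    @property
    def eeg_labels(self) -> tuple[str, ...]:
        return DEFAULT_EEG_LABELS[: self.n_channels]

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return self.eeg_labels + (EMG_LABEL,)


@dataclass(frozen=True)
class Event:
    """A tap onset: sample index into the recording plus its condition/rate."""

    sample: int
    condition: str
    rate: float


@dataclass
class ContinuousRecording:
    """Multichannel continuous data (uV) with channel metadata and tap events."""

    data: np.ndarray            # channels x samples
    fs: float
    channel_labels: tuple[str, ...]
    events: tuple[Event, ...]
    participant_id: int = 0
    annotations: dict = field(default_factory=dict)   # ground-truth metadata (e.g. blink samples)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.channel_labels = tuple(self.channel_labels)
        self.events = tuple(self.events)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel count does not match labels")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        samples = [ev.sample for ev in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("events must be sorted and strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise ValueError("event index out of data bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def eeg_picks(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.channel_labels) if l != EMG_LABEL])

    @property
    def emg_index(self) -> int | None:
        try:
            return self.channel_labels.index(EMG_LABEL)
        except ValueError:
            return None

    def replace(self, **kwargs) -> "ContinuousRecording":
        return dataclasses.replace(self, **kwargs)


def tap_times(rate: float, duration: float, jitter_sd: float = 0.0,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Nominal metronome onsets (s) at ``rate`` BPM over ``duration`` seconds.

    Onsets sit on the grid k * 60/rate for k = 0 .. floor(duration*rate/60)-1,
    each perturbed by Gaussian jitter with SD ``jitter_sd`` (ms); onsets
    jittered outside [0, duration) are dropped.
    """
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    n = int(np.floor(duration * rate / 60.0))
    onsets = np.arange(n) * (60.0 / rate)
    if jitter_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        onsets = onsets + rng.normal(0.0, jitter_sd / 1000.0, size=n)
        onsets = np.sort(onsets[(onsets >= 0) & (onsets < duration)])
    return onsets


def powerlaw_noise(n_samples: int, exponent: float, rng: np.random.Generator,
                   rms: float = 1.0, n_channels: int = 1) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise.

    The amplitude spectrum is |X(f)| proportional to f^(-exponent/2) with random
    phases, giving an exact target power-spectral slope of -exponent; each
    channel is scaled to the requested RMS.
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # zero-mean
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    scale = shaped.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    out = shaped / scale * rms
    return out[0] if n_channels == 1 else out


def _cosine_taper(n: int, ramp_samples: int) -> np.ndarray:
    """Flat window with raised-cosine ramps at both edges."""
    taper = np.ones(n)
    r = min(ramp_samples, n // 2)
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        taper[:r] = ramp
        taper[-r:] = ramp[::-1]
    return taper


def scale_band_power(trace: np.ndarray, fs: float, band: tuple[float, float],
                     window_samples: tuple[int, int], gain: float,
                     ramp_ms: float = 25.0) -> None:
    """In place, multiply band-limited power by ``gain`` inside a window.

    The band component of the trace is rescaled by sqrt(gain) within the
    window (a band-passed additive term), tapered by a 25 ms raised-cosine
    ramp so the modulation does not splatter spectrally.  Works for both
    ERD (gain < 1) and ERS (gain > 1) and is exactly calibrated at the
    window centre: band power there is gain times the background's.
    """
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    band_component = signal.sosfiltfilt(sos, trace)
    i0, i1 = window_samples
    i0 = max(i0, 0)
    i1 = min(i1, trace.shape[-1])
    if i1 <= i0:
        return
    taper = _cosine_taper(i1 - i0, int(round(ramp_ms / 1000.0 * fs)))
    trace[i0:i1] += (np.sqrt(gain) - 1.0) * taper * band_component[i0:i1]


def _blink_kernel(fs: float) -> np.ndarray:
    """Stereotyped 300 ms biphasic blink transient (unit peak)."""
    n = int(round(0.300 * fs))
    t = np.arange(n) / fs
    # dominant downstroke followed by a weaker rebound
    kernel = np.sin(np.pi * t / 0.300) ** 2 * np.cos(2 * np.pi * t / 0.300 * 0.75)
    return kernel / np.abs(kernel).max()


def blink_topography(labels: Sequence[str]) -> np.ndarray:
    """Fixed frontal weighting of the blink source across EEG channels."""
    weights = np.full(len(labels), _BLINK_FARFIELD)
    for i, label in enumerate(labels):
        for prefix, w in _BLINK_TOPOGRAPHY_WEIGHTS.items():
            if label.startswith(prefix) and not label[len(prefix):].startswith("p"):
                weights[i] = max(weights[i], w)
        if label.startswith("Fp"):
            weights[i] = 1.0
    return weights


def generate_session(config: SimConfig, participant_id: int = 0) -> ContinuousRecording:
    """Simulate one participant's continuous EEG+EMG tapping session.

    Trials are laid out sequentially (condition by condition, rate by rate)
    with ``inter_trial_gap`` seconds of plain background between them.  Tap
    events carry their condition and rate; every tap gets an EMG burst, and
    every :class:`EffectSpec` matching a tap's condition modulates band power
    around it on its channels.
    """
    fs = config.fs_raw
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF,
                                                        int(participant_id)]))
    gap = int(round(config.inter_trial_gap * fs))
    trial_len = int(round(config.trial_duration * fs))
    n_blocks = len(config.conditions) * len(config.rates) * config.n_trials_per_condition
    total = gap + n_blocks * (trial_len + gap)

    eeg_labels = config.eeg_labels
    n_eeg = len(eeg_labels)
    data = np.empty((n_eeg + 1, total))
    data[:n_eeg] = powerlaw_noise(total, config.noise_exponent, rng,
                                  rms=config.noise_scale, n_channels=n_eeg)
    # EMG rest activity: low-level broadband noise
    data[n_eeg] = rng.standard_normal(total) * (config.emg_burst_amplitude / 50.0)

    events: list[Event] = []
    cursor = gap
    for condition in config.conditions:
        for rate in config.rates:
            for _ in range(config.n_trials_per_condition):
                onsets = tap_times(rate, config.trial_duration,
                                   config.tap_jitter_ms, rng)
                for onset in onsets:
                    events.append(Event(cursor + int(round(onset * fs)), condition, rate))
                cursor += trial_len + gap
    events.sort(key=lambda ev: ev.sample)
    # enforce strict monotonicity (jitter could in principle collide)
    deduped: list[Event] = []
    for ev in events:
        if deduped and ev.sample <= deduped[-1].sample:
            ev = Event(deduped[-1].sample + 1, ev.condition, ev.rate)
        deduped.append(ev)
    events = deduped

    _apply_effects(data, eeg_labels, events, config, fs)
    blink_starts = _apply_blinks(data, eeg_labels, rng, config, fs, total)
    _apply_emg_bursts(data[n_eeg], events, rng, config, fs)

    return ContinuousRecording(
        data=data,
        fs=fs,
        channel_labels=config.channel_labels,
        events=tuple(events),
        participant_id=participant_id,
        annotations={"blink_samples": blink_starts,
                     "blink_duration_samples": int(round(0.300 * fs))},
    )


def _apply_effects(data, eeg_labels, events, config, fs):
    label_index = {l: i for i, l in enumerate(eeg_labels)}
    for spec in config.erd_spec:
        picks = [label_index[ch] for ch in spec.channels if ch in label_index]
        matching = [ev for ev in events if ev.condition == spec.condition]
        if not picks or not matching:
            continue
        w0 = spec.window[0] / 1000.0
        w1 = spec.window[1] / 1000.0
        for ch in picks:
            # one filter pass per channel, reused across events
            sos = signal.butter(4, spec.band, btype="bandpass", fs=fs, output="sos")
            band_component = signal.sosfiltfilt(sos, data[ch])
            factor = np.sqrt(spec.gain) - 1.0
            for ev in matching:
                i0 = ev.sample + int(round(w0 * fs))
                i1 = ev.sample + int(round(w1 * fs))
                i0 = max(i0, 0)
                i1 = min(i1, data.shape[1])
                if i1 <= i0:
                    continue
                taper = _cosine_taper(i1 - i0, int(round(0.025 * fs)))
                data[ch, i0:i1] += factor * taper * band_component[i0:i1]


def _apply_blinks(data, eeg_labels, rng, config, fs, total) -> tuple[int, ...]:
    if config.blink_rate <= 0:
        return ()
    kernel = _blink_kernel(fs) * config.blink_amplitude
    topo = blink_topography(eeg_labels)
    n_blinks = rng.poisson(config.blink_rate * total / fs / 60.0)
    starts = np.sort(rng.integers(0, max(total - kernel.size, 1), size=n_blinks))
    for start in starts:
        stop = min(start + kernel.size, total)
        seg = kernel[: stop - start] * (0.8 + 0.4 * rng.random())
        data[: len(eeg_labels), start:stop] += topo[:, None] * seg[None, :]
    return tuple(int(s) for s in starts)


def _apply_emg_bursts(emg, events, rng, config, fs):
    burst_len = int(round(config.emg_burst_ms / 1000.0 * fs))
    if burst_len < 4:
        return
    hi = min(500.0, 0.45 * fs)
    sos = signal.butter(4, [20.0, hi], btype="bandpass", fs=fs, output="sos")
    taper = _cosine_taper(burst_len, int(round(0.005 * fs)))
    for ev in events:
        stop = min(ev.sample + burst_len, emg.size)
        n = stop - ev.sample
        if n <= 4:
            continue
        burst = signal.sosfilt(sos, rng.standard_normal(burst_len))
        burst = burst / max(burst.std(), 1e-12) * config.emg_burst_amplitude
        emg[ev.sample:stop] += burst[:n] * taper[:n]
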