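"""Movement-locked epoching: EMG onset detection, segmentation, rejection.

Epochs are 1.5 s windows (-500 to +1000 ms) locked to movement onset as
detected on the EMG channel.  The pre-movement baseline window depends on
the pacing rate: at 70 BPM taps are far apart and -500..-300 ms is clean
pre-movement data, whereas at 140 BPM the previous tap (inter-tap interval
about 429 ms) would contaminate it, so -300..-100 ms is used instead.
Overlapping epochs are expected and allowed at the fast rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .simulate import ContinuousRecording, EMG_LABEL

__all__ = [
    "EpochSet",
    "detect_emg_onsets",
    "baseline_window_for",
    "segment",
    "reject_artifacts",
    "EPOCH_WINDOW_MS",
    "BASELINE_WINDOWS",
]

EPOCH_WINDOW_MS = (-500.0, 1000.0)
BASELINE_WINDOWS = {70.0: (-500.0, -300.0), 140.0: (-300.0, -100.0)}

REJECTION_REASONS = ("gradient", "absolute", "none")


@dataclass
class EpochSet:
    """Trials x channels x samples cube time-locked to movement onsets."""

    data: np.ndarray
    fs: float
    condition: str = ""
    rate: float = float("nan")
    t0_offset_ms: float = EPOCH_WINDOW_MS[0]
    epoch_length_ms: float = EPOCH_WINDOW_MS[1] - EPOCH_WINDOW_MS[0]
    baseline_window: tuple[float, float] | None = None
    channel_labels: tuple[str, ...] = ()
    rejected: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        expected = int(round(self.epoch_length_ms * self.fs / 1000.0))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epoch_length_ms} ms at {self.fs} Hz implies "
                f"{expected} samples, got {self.data.shape[2]}"
            )
        if not self.rejected:
            self.rejected = ["none"] * self.data.shape[0]
        if len(self.rejected) != self.data.shape[0]:
            raise ValueError("rejection mask length mismatch")
        bad = set(self.rejected) - set(REJECTION_REASONS)
        if bad:
            raise ValueError(f"unknown rejection reasons: {bad}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to movement onset."""
        n = self.data.shape[2]
        return self.t0_offset_ms + np.arange(n) * 1000.0 / self.fs

    @property
    def retained(self) -> np.ndarray:
        return np.array([r == "none" for r in self.rejected])

    @property
    def rejection_fraction(self) -> float:
        if self.n_trials == 0:
            return 0.0
        return 1.0 - self.retained.mean()

    def retained_data(self) -> np.ndarray:
        return self.data[self.retained]

    def eeg_channel_indices(self) -> np.ndarray:
        if not self.channel_labels:
            return np.arange(self.data.shape[1])
        return np.array([i for i, l in enumerate(self.channel_labels) if l != EMG_LABEL])

    def replace(self, **kwargs) -> "EpochSet":
        return dataclasses.replace(self, **kwargs)


def detect_emg_onsets(
    emg: np.ndarray,
    fs: float,
    threshold_sd: float = 8.0,
    min_gap_ms: float = 200.0,
    smooth_ms: float = 8.0,
    hold_ms: float = 20.0,
) -> np.ndarray:
    """Movement onsets from a single EMG trace by envelope thresholding.

    The rectified signal is smoothed with a centred moving average; the
    resting baseline (mean, SD) is estimated from the quiet half of the
    envelope (samples at or below its median).  An onset is the first sample
    where the envelope exceeds mean + threshold_sd * SD and stays above it on
    average for ``hold_ms`` (bursts are sustained; noise spikes are not),
    with successive onsets separated by at least ``min_gap_ms``.  Each
    accepted detection is snapped to the point of steepest envelope rise just
    after the crossing (compensated for the centred smoothing lag), which
    localises the burst edge even when near-threshold noise precedes it.
    """
    emg = np.asarray(emg, dtype=float)
    if emg.ndim != 1:
        raise ValueError("detect_emg_onsets expects a single-channel trace")
    if not np.all(np.isfinite(emg)):
        raise ValueError("EMG trace contains non-finite samples")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if emg.size == 0 or np.all(emg == emg.flat[0]):
        return np.array([], dtype=int)
    env = ndimage.uniform_filter1d(np.abs(emg), max(int(round(smooth_ms / 1000.0 * fs)), 1))
    quiet = env[env <= np.median(env)]
    threshold = quiet.mean() + threshold_sd * quiet.std()
    above = env > threshold
    if not above.any():
        return np.array([], dtype=int)
    crossings = np.where(above & ~np.roll(above, 1))[0]
    if above[0]:
        crossings = np.concatenate([[0], crossings[crossings != 0]])
    min_gap = int(round(min_gap_ms / 1000.0 * fs))
    hold = max(int(round(hold_ms / 1000.0 * fs)), 1)
    env_n = max(int(round(smooth_ms / 1000.0 * fs)), 1)
    denv = np.diff(env, prepend=env[0])
    refine = env_n + max(int(round(0.004 * fs)), 1)
    onsets = []
    last = -min_gap - 1
    for c in crossings:
        if c - last < min_gap:
            continue
        if env[c:c + hold].mean() <= threshold:
            continue
        w1 = min(c + refine, env.size)
        onset = c + int(np.argmax(denv[c:w1])) if w1 > c else c
        onset -= env_n // 2   # steepest rise of the centred envelope lags the edge
        onsets.append(max(onset, 0))
        last = c
    return np.array(onsets, dtype=int)


def baseline_window_for(rate: float, overrides: dict[float, tuple[float, float]] | None = None
                        ) -> tuple[float, float]:
    """Rate-dependent pre-movement baseline window (ms): 70 -> [-500, -300], 140 -> [-300, -100]."""
    table = dict(BASELINE_WINDOWS)
    if overrides:
        table.update({float(k): tuple(v) for k, v in overrides.items()})
    key = float(rate)
    if key not in table:
        raise ValueError(
            f"no baseline window defined for rate {rate} BPM; supply an override"
        )
    return table[key]


def segment(
    recording: ContinuousRecording,
    onsets: Sequence[int],
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    condition: str = "",
    rate: float = float("nan"),
    baseline_window: tuple[float, float] | None = None,
    apply_baseline: bool = True,
) -> EpochSet:
    """Cut onset-locked epochs out of continuous data.

    Epochs whose window is not fully inside the recording are dropped (the
    drop count is retrievable from ``len(onsets) - n_trials``).  When
    ``apply_baseline`` is set, the per-channel mean over the baseline window
    (defaulting to the rate's standard window) is subtracted from each epoch —
    the additive, epoch-level correction, distinct from the divisive
    time-frequency baseline applied later.
    """
    fs = recording.fs
    w0, w1 = window_ms
    start_off = int(round(w0 / 1000.0 * fs))
    n_samp = int(round((w1 - w0) / 1000.0 * fs))
    epochs = []
    for onset in onsets:
        i0 = int(onset) + start_off
        i1 = i0 + n_samp
        if i0 < 0 or i1 > recording.n_samples:
            continue
        epochs.append(recording.data[:, i0:i1])
    data = (np.stack(epochs) if epochs
            else np.empty((0, recording.n_channels, n_samp)))
    if baseline_window is None and apply_baseline and not np.isnan(rate):
        try:
            baseline_window = baseline_window_for(rate)
        except ValueError:
            baseline_window = None
    es = EpochSet(
        data=data,
        fs=fs,
        condition=condition,
        rate=rate,
        t0_offset_ms=w0,
        epoch_length_ms=w1 - w0,
        baseline_window=baseline_window,
        channel_labels=tuple(recording.channel_labels),
    )
    if apply_baseline and baseline_window is not None and es.n_trials:
        mask = (es.times >= baseline_window[0]) & (es.times < baseline_window[1])
        if mask.any():
            es.data -= es.data[:, :, mask].mean(axis=2, keepdims=True)
    return es


def reject_artifacts(
    epochs: EpochSet,
    grad_limit: float = 30.0,
    abs_limit: float = 150.0,
) -> EpochSet:
    """Mark artefactual trials: steep gradients or excessive within-segment range.

    A trial is rejected when on any EEG channel the adjacent-sample gradient
    exceeds ``grad_limit`` uV/ms (sample spacing 1000/fs ms, i.e. 3.906 ms at
    256 Hz), or the within-segment max-min range exceeds ``abs_limit`` uV.
    The gradient reason takes precedence when both rules fire.  EMG is
    exempt — its bursts legitimately dwarf EEG limits.
    """
    if epochs.n_trials == 0:
        return epochs
    dt_ms = 1000.0 / epochs.fs
    picks = epochs.eeg_channel_indices()
    eeg = epochs.data[:, picks, :]
    grad = np.abs(np.diff(eeg, axis=2)).max(axis=(1, 2)) / dt_ms
    span = (eeg.max(axis=2) - eeg.min(axis=2)).max(axis=1)
    reasons = []
    for g, s in zip(grad, span):
        if g > grad_limit:
            reasons.append("gradient")
        elif s > abs_limit:
            reasons.append("absolute")
        else:
            reasons.append("none")
    return epochs.replace(rejected=reasons)
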