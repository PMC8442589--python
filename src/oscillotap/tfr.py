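"""Single-trial complex Morlet time-frequency decomposition.

The bank spans 1-30 Hz in 30 linear steps.  The cycle count grows
logarithmically from 3 cycles at 1 Hz to 8 cycles at 30 Hz, trading temporal
precision at low frequencies for spectral precision at high ones.  Each
wavelet is a complex sinusoid under a Gaussian envelope of SD
cycles/(2*pi*f) seconds, truncated at +-4 SD and normalised to unit energy so
that white noise yields a flat power profile across the bank.

Power is |convolution|^2 computed per single trial via frequency-domain
multiplication, then averaged over retained trials and expressed in dB
relative to the mean pre-movement baseline power per frequency (divisive
baseline).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .epochs import EpochSet

__all__ = [
    "WaveletBank",
    "TFR",
    "build_wavelet_bank",
    "transform",
    "average_trials",
    "divisive_baseline_db",
    "ANALYSIS_WINDOW_MS",
]

ANALYSIS_WINDOW_MS = (-300.0, 800.0)

N_FREQS = 30
FREQ_RANGE = (1.0, 30.0)
CYCLE_RANGE = (3.0, 8.0)


@dataclass(frozen=True)
class WaveletBank:
    """The family of complex Morlet wavelets used for the decomposition."""

    frequencies: np.ndarray   # Hz, 30 linear steps 1..30
    cycles: np.ndarray        # log-spaced 3..8
    fs: float

    @property
    def gaussian_sd(self) -> np.ndarray:
        """Time-domain Gaussian SD per frequency, in seconds."""
        return self.cycles / (2.0 * np.pi * self.frequencies)

    def wavelet(self, index: int) -> np.ndarray:
        """Complex Morlet at frequency index, unit energy, support +-4 SD."""
        f = self.frequencies[index]
        sd = self.gaussian_sd[index]
        half = int(np.ceil(4.0 * sd * self.fs))
        t = np.arange(-half, half + 1) / self.fs
        w = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2.0 * sd ** 2))
        return w / np.sqrt(np.sum(np.abs(w) ** 2))

    @property
    def max_support(self) -> int:
        return 2 * int(np.ceil(4.0 * self.gaussian_sd[0] * self.fs)) + 1


def build_wavelet_bank(fs: float) -> WaveletBank:
    """Construct the 1-30 Hz bank: 30 linear frequencies, 3->8 log-spaced cycles."""
    if fs < 128:
        raise ValueError("sampling rate must be at least 128 Hz for a 30 Hz bank")
    frequencies = np.linspace(FREQ_RANGE[0], FREQ_RANGE[1], N_FREQS)
    cycles = np.exp(np.linspace(np.log(CYCLE_RANGE[0]), np.log(CYCLE_RANGE[1]), N_FREQS))
    return WaveletBank(frequencies=frequencies, cycles=cycles, fs=float(fs))


@dataclass
class TFR:
    """Time-frequency power with axis metadata.

    ``power`` is ``trials x channels x freqs x times`` for single-trial raw
    power (uV^2) or ``channels x freqs x times`` after trial averaging /
    dB baselining; ``kind`` records which.
    """

    power: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray                 # ms relative to movement onset
    fs: float
    kind: str = "raw"                 # "raw" (uV^2) or "db"
    baseline_window: tuple[float, float] | None = None
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if not np.all(np.isfinite(self.power)):
            raise ValueError("TFR contains non-finite power values")

    def crop(self, tmin: float, tmax: float) -> "TFR":
        """Restrict the time axis to [tmin, tmax] ms (inclusive)."""
        mask = (self.times >= tmin) & (self.times <= tmax)
        return dataclasses.replace(self, power=self.power[..., mask],
                                   times=self.times[mask])

    def channel(self, label: str) -> np.ndarray:
        idx = self.channel_labels.index(label)
        return self.power[..., idx, :, :]


def transform(epochs: EpochSet, bank: WaveletBank | None = None,
              channels: np.ndarray | None = None, output: str = "power") -> TFR:
    """Single-trial Morlet power via FFT convolution, on the epoch time grid.

    Output time step is one sample of the working rate (3.906 ms at 256 Hz).
    Epochs are zero-padded for the circular convolution; only retained trials
    are transformed.  ``output="complex"`` returns the raw convolution
    coefficients instead of their squared modulus.
    """
    if bank is None:
        bank = build_wavelet_bank(epochs.fs)
    if abs(bank.fs - epochs.fs) > 1e-9:
        raise ValueError("wavelet bank and epochs disagree on sampling rate")
    data = epochs.retained_data()
    if data.shape[0] == 0:
        raise ValueError("no retained trials to transform")
    if channels is None:
        channels = epochs.eeg_channel_indices()
    data = data[:, channels, :]
    n_trials, n_channels, n_samp = data.shape

    if output not in ("power", "complex"):
        raise ValueError("output must be 'power' or 'complex'")
    nfft = sp_fft.next_fast_len(n_samp + bank.max_support - 1)
    X = sp_fft.fft(data.reshape(-1, n_samp), n=nfft, axis=-1)
    dtype = complex if output == "complex" else float
    power = np.empty((n_trials, n_channels, bank.frequencies.size, n_samp), dtype=dtype)
    for k in range(bank.frequencies.size):
        w = bank.wavelet(k)
        half = (w.size - 1) // 2
        W = sp_fft.fft(w, n=nfft)
        conv = sp_fft.ifft(X * W[None, :], axis=-1)
        # 'same' alignment: discard the wavelet's leading half
        seg = conv[:, half:half + n_samp].reshape(n_trials, n_channels, n_samp)
        power[:, :, k, :] = seg if output == "complex" else np.abs(seg) ** 2

    return TFR(
        power=power,
        frequencies=bank.frequencies.copy(),
        times=epochs.times.copy(),
        fs=epochs.fs,
        kind="raw",
        channel_labels=tuple(np.asarray(epochs.channel_labels)[channels])
        if epochs.channel_labels else (),
    )


def average_trials(tfr: TFR) -> TFR:
    """Average single-trial power across trials (raw power only)."""
    if tfr.power.ndim != 4:
        raise ValueError("expected trials x channels x freqs x times power")
    return dataclasses.replace(tfr, power=tfr.power.mean(axis=0))


def divisive_baseline_db(tfr: TFR, baseline_window: tuple[float, float],
                         per_trial: bool = False) -> TFR:
    """Divisive dB baseline: 10*log10(P / mean baseline P) per channel & frequency.

    By default single-trial power is averaged across trials first and the
    average is divided by its own mean power over the baseline window
    (per channel and frequency); ``per_trial`` instead divides each trial by
    the trial-average baseline before averaging, which is equivalent up to
    the order of the log.
    """
    b0, b1 = baseline_window
    mask = (tfr.times >= b0) & (tfr.times < b1)
    if not mask.any():
        raise ValueError(f"baseline window {baseline_window} ms not inside epoch")
    if tfr.power.ndim == 4:
        avg = tfr.power.mean(axis=0)
    elif tfr.power.ndim == 3:
        avg = tfr.power
    else:
        raise ValueError("power must be 3- or 4-dimensional")
    base = avg[..., mask].mean(axis=-1)           # channels x freqs
    nonpos = np.argwhere(base <= 0)
    if nonpos.size:
        ch, fr = nonpos[0]
        raise ValueError(
            f"non-positive baseline power at channel index {ch}, "
            f"frequency {tfr.frequencies[fr]:.1f} Hz"
        )
    if per_trial and tfr.power.ndim == 4:
        db = 10.0 * np.log10(tfr.power / base[None, :, :, None]).mean(axis=0)
    else:
        db = 10.0 * np.log10(avg / base[:, :, None])
    return dataclasses.replace(tfr, power=db, kind="db",
                               baseline_window=(b0, b1))
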