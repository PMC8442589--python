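"""Calibration studies for the inference core.

Two simulation-based checks, used both by the test suite and by the
reproduction script:

* ``fwer_simulation`` — the family-wise error of the cluster test on
  exchangeable null data: many synthetic datasets with no true effect, each
  run through the full permutation machinery; the fraction with at least one
  significant cluster should sit in the binomial band around the nominal 5%.

* ``effect_recovery_simulation`` — statistical power at the signal level: per
  participant, oscillatory epochs are synthesised with a known band-limited
  power doubling in a known window for one condition, pushed through the
  Morlet transform and divisive dB baseline, and the per-participant
  condition differences are tested; recovery means a significant positive
  cluster whose bounding window overlaps the injected one.
"""

from __future__ import annotations

import numpy as np

from . import tfr as tfr_mod
from .clusterstats import ClusterPermutationTest
from .epochs import EpochSet
from .simulate import powerlaw_noise, scale_band_power

__all__ = ["fwer_simulation", "effect_recovery_simulation", "simulate_participant_tfr"]


def fwer_simulation(
    n_datasets: int = 200,
    n_participants: int = 20,
    grid: tuple[int, int] = (30, 140),
    n_permutations: int = 1000,
    alpha_cell: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical family-wise error rate of the cluster test under the null.

    Each dataset is ``n_participants`` iid Gaussian difference maps on the
    ``grid`` (exchangeable null: both conditions share one distribution, so
    the paired difference is symmetric about zero).  Returns the fraction of
    datasets with at least one significant cluster at the 95th/5th-percentile
    mass thresholds.
    """
    rng = np.random.default_rng(seed)
    false_positives = 0
    for _ in range(n_datasets):
        diffs = rng.standard_normal((n_participants,) + grid)
        res = ClusterPermutationTest(diffs).fit(
            n_permutations=n_permutations, alpha_cell=alpha_cell,
            seed=int(rng.integers(2 ** 31)),
        )
        if res.significant_clusters:
            false_positives += 1
    return false_positives / n_datasets


def simulate_participant_tfr(
    rng: np.random.Generator,
    gain: float = 1.0,
    band: tuple[float, float] = (16.0, 30.0),
    window_ms: tuple[float, float] = (0.0, 400.0),
    n_trials: int = 20,
    fs: float = 256.0,
    baseline_window: tuple[float, float] = (-500.0, -300.0),
    noise_exponent: float = 1.0,
    bank=None,
) -> np.ndarray:
    """One participant's condition-average dB map from synthetic epochs.

    Epochs are 1.5 s (-500..1000 ms) of 1/f noise on a single channel; when
    ``gain`` differs from 1, band power inside ``window_ms`` is multiplied by
    ``gain``.  The epochs go through the Morlet bank and the divisive dB
    baseline, and the trial-average map is cropped to the -300..800 ms
    analysis window.
    """
    if bank is None:
        bank = tfr_mod.build_wavelet_bank(fs)
    n_samp = int(round(1.5 * fs))
    t0 = -0.5
    data = powerlaw_noise(n_samp, noise_exponent, rng, rms=10.0, n_channels=n_trials)
    if gain != 1.0:
        i0 = int(round((window_ms[0] / 1000.0 - t0) * fs))
        i1 = int(round((window_ms[1] / 1000.0 - t0) * fs))
        for trial in data:
            scale_band_power(trial, fs, band, (i0, i1), gain)
    epochs = EpochSet(data=data[:, None, :], fs=fs)
    raw = tfr_mod.transform(epochs, bank)
    db = tfr_mod.divisive_baseline_db(raw, baseline_window)
    return db.crop(*tfr_mod.ANALYSIS_WINDOW_MS).power[0]  # freqs x times


def effect_recovery_simulation(
    n_runs: int = 50,
    n_participants: int = 20,
    gain: float = 2.0,
    band: tuple[float, float] = (16.0, 30.0),
    window_ms: tuple[float, float] = (0.0, 400.0),
    n_trials: int = 20,
    fs: float = 256.0,
    n_permutations: int = 1000,
    alpha_cell: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of simulated group studies recovering an injected ERS effect.

    Per run, each participant contributes two condition-average dB maps (one
    with the band-limited power multiplied by ``gain`` in the window, one
    without); the paired cluster permutation test is fitted, and the run
    counts as a recovery when some significant positive cluster's bounding
    window overlaps the injected band x window region.
    """
    rng = np.random.default_rng(seed)
    bank = tfr_mod.build_wavelet_bank(fs)
    recovered = 0
    for _ in range(n_runs):
        maps_a, maps_b = [], []
        for _ in range(n_participants):
            maps_a.append(simulate_participant_tfr(
                rng, gain=gain, band=band, window_ms=window_ms,
                n_trials=n_trials, fs=fs, bank=bank))
            maps_b.append(simulate_participant_tfr(
                rng, gain=1.0, n_trials=n_trials, fs=fs, bank=bank))
        model = ClusterPermutationTest(
            np.stack(maps_a), np.stack(maps_b),
            frequencies=bank.frequencies,
            times=None,
        )
        # reconstruct the cropped time axis in ms
        n_times = model.diffs.shape[2]
        times = tfr_mod.ANALYSIS_WINDOW_MS[0] + np.arange(n_times) * 1000.0 / fs
        model.times = times
        res = model.fit(n_permutations=n_permutations, alpha_cell=alpha_cell,
                        seed=int(rng.integers(2 ** 31)))
        if _overlaps_injection(res, band, window_ms):
            recovered += 1
    return recovered / n_runs


def _overlaps_injection(results, band, window_ms) -> bool:
    for c in results.significant_clusters:
        if c.sign <= 0:
            continue
        win = results.cluster_window(c)
        if (win["f_lo_hz"] <= band[1] and win["f_hi_hz"] >= band[0]
                and win["t_lo_ms"] <= window_ms[1] and win["t_hi_ms"] >= window_ms[0]):
            return True
    return False
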