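"""Continuous-data conditioning for movement-locked EEG analysis.

The driver applies, in this fixed order: bad-channel removal, downsampling
(anti-aliased polyphase resampling), common average reference, zero-phase
band-pass + notch filtering, ICA decomposition with blink-component removal
and inverse-ICA reconstruction, and finally spherical-spline interpolation of
the removed channels.  The EMG channel rides along unreferenced and
unfiltered (its usable band lies far above the EEG passband) but is
downsampled with the rest so event bookkeeping stays aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial import legendre
from scipy import signal, stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .montage import MontagePositions, standard_positions
from .simulate import ContinuousRecording, EMG_LABEL, Event, blink_topography

__all__ = [
    "FilterDesignError",
    "ICAConvergenceError",
    "ICADecomposition",
    "downsample",
    "average_reference",
    "bandpass_notch",
    "ica_blink_removal",
    "default_blink_detector",
    "detect_bad_channels",
    "spherical_spline_matrix",
    "interpolate_spherical_spline",
    "preprocess_pipeline",
    "STAGE_ORDER",
]

STAGE_ORDER = (
    "remove_bad_channels",
    "downsample",
    "average_reference",
    "filter",
    "ica",
    "reconstruct",
    "interpolate",
)


class FilterDesignError(ValueError):
    """Raised when a requested filter cannot be realised stably."""


class ICAConvergenceError(RuntimeError):
    """Raised when the ICA decomposition fails outright."""


def downsample(recording: ContinuousRecording, target_fs: float) -> ContinuousRecording:
    """Anti-alias filter and resample to ``target_fs``; event indices are rescaled."""
    if target_fs >= recording.fs:
        raise ValueError(f"target_fs {target_fs} must be below fs {recording.fs}")
    if target_fs <= 2 * 30.0:
        raise ValueError("target_fs must exceed twice the 30 Hz analysis band")
    frac = Fraction(target_fs / recording.fs).limit_denominator(10000)
    data = signal.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
    ratio = target_fs / recording.fs
    n_new = data.shape[1]
    events = tuple(
        Event(min(int(round(ev.sample * ratio)), n_new - 1), ev.condition, ev.rate)
        for ev in recording.events
    )
    annotations = dict(recording.annotations)
    for key in ("blink_samples",):
        if key in annotations:
            annotations[key] = tuple(int(round(s * ratio)) for s in annotations[key])
    if "blink_duration_samples" in annotations:
        annotations["blink_duration_samples"] = int(
            round(annotations["blink_duration_samples"] * ratio))
    return recording.replace(data=data, fs=float(target_fs), events=events,
                             annotations=annotations)


def average_reference(recording: ContinuousRecording) -> ContinuousRecording:
    """Re-reference EEG channels to their common average (EMG untouched)."""
    picks = recording.eeg_picks
    if picks.size < 2:
        raise ValueError("average reference requires at least 2 EEG channels")
    data = recording.data.copy()
    data[picks] -= data[picks].mean(axis=0, keepdims=True)
    return recording.replace(data=data)


def _check_sos_stable(sos: np.ndarray, what: str) -> None:
    _, poles, _ = signal.sos2zpk(sos)
    if poles.size and np.max(np.abs(poles)) >= 1.0 - 1e-12:
        raise FilterDesignError(f"{what} filter is unstable (pole on/outside unit circle)")


def bandpass_notch(
    recording: ContinuousRecording,
    passband: tuple[float, float] = (0.1, 30.0),
    notch: float | None = 60.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> ContinuousRecording:
    """Zero-phase (forward-backward) Butterworth band-pass plus IIR notch.

    The Butterworth is 4th order per pass (effective 8th after the dual
    pass), realised as second-order sections for stability at the 0.1 Hz
    edge.  Applied to EEG channels only.
    """
    lo, hi = passband
    nyq = recording.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise FilterDesignError(f"passband {passband} outside (0, {nyq}) Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=recording.fs, output="sos")
    _check_sos_stable(sos, "band-pass")
    data = recording.data.copy()
    picks = recording.eeg_picks
    # the 0.1 Hz edge has a seconds-long impulse response; extend the
    # forward-backward padding well beyond the default so boundary
    # transients settle inside the padding, not the data
    padlen = min(data.shape[1] - 1, int(round(10.0 * recording.fs)))
    data[picks] = signal.sosfiltfilt(sos, data[picks], axis=1, padlen=padlen)
    if notch is not None:
        if not (0 < notch < nyq):
            raise FilterDesignError(f"notch frequency {notch} outside (0, {nyq}) Hz")
        b, a = signal.iirnotch(notch, notch_q, fs=recording.fs)
        data[picks] = signal.filtfilt(b, a, data[picks], axis=1, padlen=padlen)
    return recording.replace(data=data)


@dataclass
class ICADecomposition:
    """An ICA factorisation of the EEG channel block.

    ``mixing @ unmixing`` is the identity on the retained subspace, so
    reconstructing from the full component set reproduces the input (up to
    the subspace projection when fewer components than channels are kept).
    """

    unmixing: np.ndarray        # components x channels
    mixing: np.ndarray          # channels x components
    activations: np.ndarray     # components x samples
    mean: np.ndarray            # per-channel mean removed before unmixing
    flagged: tuple[int, ...] = ()
    converged: bool = True
    channel_labels: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def reconstruct(self, exclude: Sequence[int] | None = None) -> np.ndarray:
        """Inverse ICA: channels x samples with ``exclude`` components zeroed."""
        exclude = self.flagged if exclude is None else tuple(exclude)
        acts = self.activations
        if exclude:
            acts = acts.copy()
            acts[list(exclude)] = 0.0
        return self.mixing @ acts + self.mean[:, None]


def default_blink_detector(
    decomposition: ICADecomposition,
    template: np.ndarray | None = None,
    corr_threshold: float = 0.8,
    kurtosis_threshold: float = 5.0,
) -> tuple[int, ...]:
    """Flag components whose scalp topography matches a frontal blink template.

    A component is flagged when |corr(topography, frontal template)| exceeds
    ``corr_threshold`` and its activation kurtosis exceeds
    ``kurtosis_threshold`` (blinks are sparse, heavy-tailed deflections).
    An automated surrogate for visual component inspection.
    """
    if template is None:
        template = blink_topography(decomposition.channel_labels)
    template = np.asarray(template, dtype=float)
    flagged = []
    for k in range(decomposition.n_components):
        topo = decomposition.mixing[:, k]
        if np.std(topo) == 0 or np.std(template) == 0:
            continue
        r = np.corrcoef(topo, template)[0, 1]
        kurt = stats.kurtosis(decomposition.activations[k], fisher=True)
        if abs(r) > corr_threshold and kurt > kurtosis_threshold:
            flagged.append(k)
    return tuple(flagged)


def ica_blink_removal(
    recording: ContinuousRecording,
    n_components: int | None = None,
    blink_detector: Callable[[ICADecomposition], Sequence[int]] | None = None,
    flagged: Sequence[int] | None = None,
    max_iter: int = 500,
    tol: float = 1e-3,
    random_state: int = 0,
    on_nonconvergence: str = "warn",
) -> tuple[ContinuousRecording, ICADecomposition]:
    """Decompose EEG channels with FastICA, zero blink components, reconstruct.

    ``flagged`` supplies a manual component list and bypasses the detector
    (the two paths produce identical reconstructions for the same set).  When
    ``n_components`` is None the numerical rank of the EEG block is used —
    after average referencing the data lose one rank, and whitening against
    a null direction would be singular.
    """
    picks = recording.eeg_picks
    X = recording.data[picks]
    if X.shape[1] <= X.shape[0]:
        raise ValueError("ICA requires many more samples than channels")
    if n_components is None:
        sv = np.linalg.svd(X - X.mean(axis=1, keepdims=True), compute_uv=False)
        n_components = int(np.sum(sv > sv[0] * 1e-10))
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=random_state,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(X.T).T  # components x samples
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    if not np.all(np.isfinite(sources)):
        raise ICAConvergenceError("ICA produced non-finite activations")
    if not converged:
        msg = (f"FastICA did not fully converge in {max_iter} iterations "
               f"(tol {tol}); decomposition retained, converged=False")
        if on_nonconvergence == "raise":
            raise ICAConvergenceError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    decomposition = ICADecomposition(
        unmixing=ica.components_,
        mixing=ica.mixing_,
        activations=sources,
        mean=ica.mean_,
        converged=converged,
        channel_labels=tuple(recording.channel_labels[i] for i in picks),
    )
    if flagged is None:
        detector = blink_detector or default_blink_detector
        flagged = tuple(detector(decomposition))
    else:
        flagged = tuple(flagged)
    if len(flagged) >= decomposition.n_components and decomposition.n_components > 0:
        raise ICAConvergenceError("blink detector flagged every component")
    decomposition.flagged = flagged

    data = recording.data.copy()
    data[picks] = decomposition.reconstruct()
    return recording.replace(data=data), decomposition


def detect_bad_channels(recording: ContinuousRecording, z_threshold: float = 5.0) -> tuple[str, ...]:
    """Flag EEG channels whose log-variance is a robust-z outlier."""
    picks = recording.eeg_picks
    logvar = np.log(recording.data[picks].var(axis=1) + 1e-30)
    med = np.median(logvar)
    mad = np.median(np.abs(logvar - med)) * 1.4826
    if mad == 0:
        return ()
    z = np.abs(logvar - med) / mad
    return tuple(recording.channel_labels[picks[i]] for i in np.where(z > z_threshold)[0])


def _gfun(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Perrin spherical-spline kernel g(cos gamma), Legendre series to degree n_terms."""
    n = np.arange(1, n_terms + 1)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1)) ** m
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4 * np.pi)


def spherical_spline_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    m: int = 4,
    n_terms: int = 20,
    lam: float = 1e-5,
) -> np.ndarray:
    """Interpolation operator mapping good-channel values to bad-channel estimates.

    Solves the regularised spline system on the unit sphere: the kernel matrix
    between good electrodes (ridge-regularised by ``lam``) together with the
    constant term, then evaluates the expansion at the bad electrode sites.
    Returns a (n_bad, n_good) matrix.
    """
    k = good_pos.shape[0]
    G = _gfun(good_pos @ good_pos.T, m, n_terms)
    Gb = _gfun(bad_pos @ good_pos.T, m, n_terms)
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G + lam * np.eye(k)
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    rhs = np.zeros((k + 1, k))
    rhs[:k, :] = np.eye(k)
    sol = np.linalg.solve(A, rhs)          # (k+1) x k : data -> [c; c0]
    return Gb @ sol[:k, :] + sol[k:k + 1, :]


def interpolate_spherical_spline(
    recording: ContinuousRecording,
    bad_channels: Sequence[str],
    positions: MontagePositions | None = None,
    m: int = 4,
    n_terms: int = 20,
    lam: float = 1e-5,
) -> ContinuousRecording:
    """Replace ``bad_channels`` with spherical-spline estimates from the rest."""
    bad_channels = list(bad_channels)
    if not bad_channels:
        return recording
    labels = list(recording.channel_labels)
    unknown = [c for c in bad_channels if c not in labels or c == EMG_LABEL]
    if unknown:
        raise ValueError(f"cannot interpolate channels: {unknown}")
    good = [l for l in labels if l != EMG_LABEL and l not in bad_channels]
    if len(good) < 4:
        raise ValueError("spherical-spline interpolation needs at least 4 good channels")
    if positions is None:
        positions = standard_positions(good + bad_channels)
    W = spherical_spline_matrix(positions.array(good), positions.array(bad_channels),
                                m=m, n_terms=n_terms, lam=lam)
    data = recording.data.copy()
    good_idx = [labels.index(l) for l in good]
    bad_idx = [labels.index(l) for l in bad_channels]
    data[bad_idx] = W @ data[good_idx]
    return recording.replace(data=data)


def preprocess_pipeline(
    recording: ContinuousRecording,
    bad_channels: Sequence[str] = (),
    target_fs: float = 256.0,
    passband: tuple[float, float] = (0.1, 30.0),
    notch: float | None = 60.0,
    auto_bad: bool = False,
    ica_components: int | None = None,
    blink_detector: Callable | None = None,
    ica_flagged: Sequence[int] | None = None,
    positions: MontagePositions | None = None,
    ica_random_state: int = 0,
) -> tuple[ContinuousRecording, dict]:
    """Run the full conditioning chain in its fixed order; returns (data, log).

    The log records every stage name in execution order plus per-stage
    bookkeeping (shapes, flagged components, bad channels); the order is
    asserted against :data:`STAGE_ORDER`.
    """
    log: dict = {"stages": [], "shapes": {}}

    bad = list(bad_channels)
    if auto_bad:
        bad += [c for c in detect_bad_channels(recording) if c not in bad]
    log["bad_channels"] = list(bad)
    if bad:
        keep = [i for i, l in enumerate(recording.channel_labels) if l not in bad]
        recording = recording.replace(
            data=recording.data[keep],
            channel_labels=tuple(recording.channel_labels[i] for i in keep),
        )
    log["stages"].append("remove_bad_channels")

    recording = downsample(recording, target_fs)
    log["stages"].append("downsample")
    log["shapes"]["downsampled"] = recording.data.shape

    recording = average_reference(recording)
    log["stages"].append("average_reference")

    recording = bandpass_notch(recording, passband=passband, notch=notch)
    log["stages"].append("filter")

    recording, decomposition = ica_blink_removal(
        recording,
        n_components=ica_components,
        blink_detector=blink_detector,
        flagged=ica_flagged,
        random_state=ica_random_state,
    )
    log["stages"].append("ica")
    log["stages"].append("reconstruct")
    log["ica_flagged"] = list(decomposition.flagged)
    log["ica_converged"] = decomposition.converged

    if bad:
        # restore the removed channels as spline estimates on the clean data
        full_labels = recording.channel_labels + tuple(bad)
        data = np.vstack([recording.data, np.zeros((len(bad), recording.n_samples))])
        recording = recording.replace(data=data, channel_labels=full_labels)
        recording = interpolate_spherical_spline(recording, bad, positions=positions)
    log["stages"].append("interpolate")

    assert tuple(log["stages"]) == STAGE_ORDER, "preprocessing stages ran out of order"
    log["ica_decomposition"] = decomposition
    return recording, log
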