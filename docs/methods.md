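# Methods

This note documents the models, parameters and numerical choices behind
`oscillotap`, and what the synthetic-data validation does and does not
establish about real recordings.

## Synthetic sessions

`simulate.generate_session` lays out trials sequentially: for every
condition × pacing rate, `n_trials_per_condition` trials of
`trial_duration` seconds separated by 2 s of plain background. Defaults
describe the study design the pipeline targets: 20 participants, 64 EEG
channels (10-10 labels) plus one EMG channel, 2000 Hz raw rate, four 10 s
trials per condition, three cue conditions (Activating, Relaxing, ToneOnly)
at 70 and 140 BPM.

* **Background** is 1/f^α noise (α = 1 by default, RMS 10 µV per channel),
  synthesized by spectral shaping: white noise is transformed, its amplitude
  spectrum multiplied by f^(−α/2) with the original random phases, and
  transformed back. The target log-log PSD slope is exact by construction.
* **Tap onsets** sit on the metronome grid k·60/rate with Gaussian jitter
  (SD 10 ms, a typical sensorimotor synchronization error); onsets jittered
  outside the trial are dropped. At 70 BPM a 10 s trial carries 11 taps, at
  140 BPM 23 — about 44 and 92 usable epochs per condition after edge
  trimming, matching the regime the analysis expects.
* **Band-power effects** (`EffectSpec`) multiply the power of a frequency
  band by `gain` inside a window around each matching tap. Implementation:
  the band-passed component of the background is scaled by √gain − 1 and
  added back inside the window, under a 25 ms raised-cosine taper. Because
  the added term is perfectly coherent with the band component, window band
  power is multiplied by exactly `gain` at the taper plateau, for ERD
  (gain < 1) and ERS (gain > 1) alike, and the calibration
  10·log₁₀(gain) dB is analytic.
* **Blinks** are a rank-1 artifact: one stereotyped 300 ms biphasic kernel
  (amplitude ≈150 µV), scaled by a fixed frontal topography (Fp = 1.0,
  AF = 0.7, F = 0.35, FC/FT = 0.1, far-field 0.02) and placed at Poisson
  times (15/min). Rank-1 structure is what gives ICA a well-posed component
  to find; ground-truth blink times are kept in `recording.annotations`.
* **EMG bursts** are 100 ms of 20–500 Hz band noise (RMS 100 µV against a
  2 µV rest floor), tapered 5 ms, starting exactly at each tap, so onset
  detection has known truth.

Equal configurations (including seed and participant id) produce
bit-identical sessions; participants are decorrelated through spawned seed
sequences.

What the generator does **not** emulate: volume-conducted correlation
structure between channels (channels are independent except for blink
topography and injected effects), non-stationary background, muscle/line
artifacts on EEG channels, heteroscedastic participants, or kinematics.
Passing tests therefore establish the *statistical* correctness of the
pipeline (calibration, error control, power, determinism), not robustness
to every real-world artifact class.

## Preprocessing

Fixed stage order, asserted by the driver: bad-channel removal → downsample
→ average reference → filter → ICA → reconstruct → spline interpolation.

* **Downsampling** to 256 Hz uses polyphase resampling with its built-in
  anti-alias filter; event indices are rescaled and rounded to the nearest
  sample (≤ half a sample of jitter).
* **Average reference** subtracts the per-sample mean of the EEG channels;
  the EMG channel is excluded (and is never filtered with the EEG passband,
  which would destroy its 20–500 Hz content).
* **Filtering**: 4th-order Butterworth band-pass 0.1–30 Hz as second-order
  sections (stable at the 0.1 Hz edge), applied forward-backward, i.e. an
  effective 8th-order zero-phase filter; plus a Q = 30 IIR notch at 60 Hz.
  Because the 0.1 Hz edge's impulse response spans seconds, the
  forward-backward padding is extended to 10 s so boundary transients decay
  inside the padding. Pole radii are checked at design time; an unstable or
  out-of-band design raises.
* **ICA blink removal** uses FastICA on the EEG block, with the component
  count defaulting to the numerical rank (average referencing removes one
  rank; whitening against a null direction would be singular). Blink
  components are flagged automatically — |correlation| of the mixing-column
  topography with the frontal blink template > 0.8 AND activation kurtosis
  > 5 — replacing the visual inspection a human operator would do; a manual
  component list overrides the detector and produces the identical
  reconstruction path. Reconstruction with nothing flagged reproduces the
  input to < 10⁻⁶ relative error. FastICA frequently reports
  non-convergence on largely Gaussian background (there is nothing
  non-Gaussian left to rotate); the decomposition is still valid for
  blink removal, so the default policy records `converged=False` and warns,
  with `on_nonconvergence="raise"` available where a hard failure is wanted.
* **Spherical-spline interpolation** follows the Perrin g-function approach
  on the unit sphere: kernel g(cos γ) = (1/4π) Σₙ (2n+1)/(n(n+1))^m Pₙ(cos γ)
  with order m = 4, Legendre truncation at degree 20, and ridge
  regularization λ = 10⁻⁵ on the good-electrode system. Electrode positions
  come from the bundled standard 10-05 montage, normalized to unit norm.
  Leave-one-out error on a smooth low-order spherical-harmonic field is
  < 5% across the 64-channel montage.

## Epoching and rejection

Epochs span −500…1000 ms around EMG onset (384 samples at 256 Hz). The EMG
onset detector thresholds the smoothed (8 ms) rectified envelope at
baseline mean + 8 SD — baseline estimated from the quiet half of the
envelope — requires the crossing to be sustained 20 ms on average, enforces
a 200 ms refractory gap, and snaps each detection to the steepest envelope
rise (compensating the centred-smoothing lag). On crisp-envelope bursts at
SNR 10 this localizes onsets to a few ms; stochastic band-noise bursts have
intrinsically fuzzier edges (median error still < 10 ms).

Epoch-level **additive** baseline correction (mean of the rate's baseline
window subtracted per channel) happens at segmentation; it is distinct from
the divisive TFR baseline below. Baseline windows are rate-specific:
−500…−300 ms at 70 BPM, −300…−100 ms at 140 BPM (at the fast rate the
previous tap, ~429 ms earlier, would contaminate the earlier window).
Overlapping epochs at 140 BPM are expected and permitted.

Rejection: a trial is dropped when any EEG channel shows an adjacent-sample
gradient above 30 µV/ms (sample spacing 1000/fs ms — 3.906 ms at 256 Hz, so
a 120 µV one-sample step is 30.7 µV/ms and rejected) or a within-segment
max − min range above 150 µV. The range reading of "absolute within-segment
difference" is the most literal one; gradient takes precedence when both
fire. EMG is exempt. Rejection is monotone under amplitude scaling.

## Time–frequency decomposition

30 center frequencies, linear 1…30 Hz; cycle counts log-spaced 3…8
(cᵢ = exp of a linear grid from ln 3 to ln 8), so the Gaussian SD per
frequency is c/(2πf) s. Wavelets are complex sinusoids under that Gaussian,
truncated at ±4 SD and normalized to **unit energy**, making white-noise
power flat across the bank. Convolution is frequency-domain multiplication
per single trial with zero padding, output on the native 256 Hz grid
(3.906 ms steps — the "4 ms" step of the analysis). Statistics are
restricted to −300…800 ms to stay clear of edge artifacts.

The **divisive baseline** averages single-trial power across retained
trials first, then divides by the average's mean power over the baseline
window per channel and frequency, and takes 10·log₁₀ (a per-trial division
variant is available). Multiplying window power by g shifts the interior
of that window by 10·log₁₀ g dB, exactly in the trivial identity and within
±0.2 dB through the full signal path.

**Known bias.** With zero padding, the expected raw power of stationary
noise at epoch position t is the background variance times the summed
squared wavelet taps overlapping the epoch. The baseline window lies at the
epoch's left edge, where that overlap is reduced (strongly at low
frequencies, whose wavelets are seconds long), so the grand-mean dB of pure
white noise is ≈ +0.47 dB rather than 0 — an exact, analytically predicted
consequence of edge handling, concentrated below ~5 Hz. The tests assert
the simulation against this analytic expectation. The bias is identical
across conditions and cancels exactly in the paired differences the
inference consumes.

## Cluster-based permutation inference

Per electrode and condition pair, participants' condition-average dB maps
are differenced and a repeated-measures t is computed per (frequency, time)
cell (df = n−1; zero-variance cells get a sign(mean)·10⁶ sentinel).
Cluster-forming threshold: per-cell two-sided α = 0.05 (the single most
consequential free parameter; exposed as `alpha_cell`). Clusters are
4-connected components per sign; the cluster statistic is mass (sum of t).
The null is built from 1000 within-participant sign flips — for a paired
design, flipping each participant's difference with probability ½ is the
exact exchangeability scheme — recording the most positive and most
negative cluster mass per permutation (0 when none forms). The whole flip
family reduces to one matrix product because sign flips leave per-cell sums
of squares unchanged.

Significance thresholds split the family α across the two tails: positive
clusters against the 97.5th percentile of the positive extremes, negative
against the 2.5th of the negative, giving a two-sided family-wise error of
5% (measured 0.035–0.06 over 200 exchangeable null datasets). Per-tail
95th/5th thresholds — which would control each tail at 5% but the family at
≈10% — remain available via `cluster_alpha=0.1`. Cluster p-values use the
add-one estimator (1 + #extremes ≥ mass)/(1 + n_perm).

Window statistics (MD, 95% CI, t, p, Cohen's d = MD/sd of the participant
values) are computed on the **dB-scale** per-participant means over the
cluster's bounding rectangle — matching how the reference per-subject
columns are tabulated — not on z-scored data; the participant-level
z-normalization (pooled mean/SD across all conditions' cells) is provided
as `zscore_normalize` for reporting, and can be applied before or after
extraction as the caller prefers.

## Validation problem sizes

The calibration studies run at sizes chosen to make their Monte-Carlo error
small relative to the bands being checked while staying comfortably
interactive: family-wise error over 200 null datasets (n = 20, 30×140
grid, 1000 permutations each; binomial 95% band 0.02–0.10 around 0.05);
power over 50 simulated group studies (n = 20 participants × 20 trials ×
two conditions, signal-level pipeline: synthetic epochs → Morlet →
divisive dB → permutation test). The power study deliberately runs at the
signal level on one channel per participant: the multichannel conditioning
stages are validated by their own unit tests and by the reduced cohort
pipeline test, and contribute nothing to the inference calibration being
measured. dB calibration is measured in the interior of the injected window
(inset by roughly one wavelet SD) because the wavelet's temporal smoothing
dilutes the window edges — a measurement-window choice, not a tolerance.

## Limitations

* Electrode-wise inference only: no spatial clustering across electrodes
  and no cross-electrode multiplicity correction (eight electrodes are
  tested separately, replicating the analysis design this package follows).
* The divisive baseline assumes positive baseline power; all-zero channels
  are an error, not a silent NaN.
* EDF input/output is not provided; recordings use a documented HDF5
  container (plus TSV event sidecars), which round-trips exactly.
* The ICA path assumes blinks are the dominant non-Gaussian frontal source;
  other artifact classes (muscle, line-noise components) are out of scope.
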