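"""Cluster-based permutation inference on paired time-frequency maps.

The design is paired: per participant, condition-average dB maps at one
electrode for two conditions.  At every (frequency, time) cell a repeated
measures t is computed on the paired differences; cells beyond the two-sided
per-cell critical value are grouped into 4-connected clusters separately by
sign, and each cluster's mass (sum of member t-values) is compared against a
null distribution of extreme cluster masses built from 1000 within-
participant sign flips (the exact exchangeability scheme for a paired
design).  Positive clusters are tested against the 95th percentile of the
most-positive-mass null, negative ones against the 5th percentile of the
most-negative-mass null — two one-sided tails.

The model/results interface follows the statsmodels convention:

>>> model = ClusterPermutationTest(diffs, freqs, times)   # doctest: +SKIP
>>> res = model.fit(n_permutations=1000, seed=7)          # doctest: +SKIP
>>> print(res.summary())                                  # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "PairedTFRSample",
    "Cluster",
    "WindowStats",
    "NullDistribution",
    "ClusterPermutationTest",
    "ClusterPermutationResults",
    "paired_t_map",
    "extract_clusters",
    "permutation_null",
    "window_stats",
    "zscore_normalize",
]

T_SENTINEL = 1e6   # stands in for +-inf at zero-variance cells

_FOUR_CONNECTIVITY = ndimage.generate_binary_structure(2, 1)


@dataclass
class PairedTFRSample:
    """Per-participant condition-average maps for one electrode and comparison."""

    a: np.ndarray            # participants x freqs x times, dB
    b: np.ndarray
    frequencies: np.ndarray | None = None
    times: np.ndarray | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("both conditions must share participants and axes")
        if self.a.shape[0] < 2:
            raise ValueError("paired inference needs at least 2 participants")

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b

    @property
    def n_participants(self) -> int:
        return self.a.shape[0]


def paired_t_map(diffs: np.ndarray) -> np.ndarray:
    """Repeated-measures t at every cell of participants x freqs x times differences.

    Zero-variance cells get sign(mean) * T_SENTINEL (0 if the mean is 0 too),
    standing in for the infinite t of a degenerate one-sample test.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    if not np.all(np.isfinite(diffs)):
        raise ValueError("differences contain non-finite values")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    if degenerate.any():
        t[degenerate] = np.sign(mean[degenerate]) * T_SENTINEL
    return t


@dataclass(frozen=True)
class Cluster:
    """A contiguous supra-threshold region of the t-map."""

    cells: tuple[tuple[int, int], ...]   # (freq_idx, time_idx)
    mass: float
    sign: int
    p_value: float | None = None

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """Bounding rectangle (f_lo, f_hi, t_lo, t_hi), inclusive indices."""
        fs = [c[0] for c in self.cells]
        ts = [c[1] for c in self.cells]
        return min(fs), max(fs), min(ts), max(ts)

    @property
    def size(self) -> int:
        return len(self.cells)


def _label_masses(mask: np.ndarray, tmap: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    labels, n = ndimage.label(mask, structure=_FOUR_CONNECTIVITY)
    if n == 0:
        return labels, np.empty(0), 0
    masses = ndimage.sum_labels(tmap, labels, index=np.arange(1, n + 1))
    return labels, masses, n


def extract_clusters(tmap: np.ndarray, df: int, alpha_cell: float = 0.05,
                     t_threshold: float | None = None) -> list[Cluster]:
    """Threshold the t-map two-sided and group significant cells into clusters.

    Positive and negative cells form separate clusters under 4-connectivity
    (diagonal contact does not join clusters); each cluster's mass is the sum
    of its member t-values.
    """
    if t_threshold is None:
        if not (0 < alpha_cell < 1):
            raise ValueError("alpha_cell must be in (0, 1)")
        t_threshold = stats.t.ppf(1 - alpha_cell / 2.0, df)
    clusters: list[Cluster] = []
    for sign, mask in ((1, tmap > t_threshold), (-1, tmap < -t_threshold)):
        labels, masses, n = _label_masses(mask, tmap)
        for lab in range(1, n + 1):
            cells = tuple(map(tuple, np.argwhere(labels == lab)))
            clusters.append(Cluster(cells=cells, mass=float(masses[lab - 1]), sign=sign))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


@dataclass(frozen=True)
class NullDistribution:
    """Extreme cluster masses under sign-flip permutation, with tail thresholds.

    ``cluster_alpha`` is the two-sided family-wise level: positive clusters
    are thresholded at the (1 - alpha/2) quantile of the most-positive-mass
    distribution and negative ones at the alpha/2 quantile of the
    most-negative-mass distribution, so the overall false-positive rate over
    both tails is alpha.
    """

    pos_extremes: np.ndarray       # most positive cluster mass per permutation
    neg_extremes: np.ndarray       # most negative
    threshold_pos: float
    threshold_neg: float
    n_permutations: int
    cluster_alpha: float = 0.05
    seed: int | None = None


def _permutation_tmaps(diffs: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t-maps for all sign-flip patterns at once.

    Flipping signs leaves each participant's squared value unchanged, so the
    per-cell sum of squares is constant across permutations and the whole
    family of t-maps reduces to one matrix product.
    """
    n = diffs.shape[0]
    flat = diffs.reshape(n, -1)
    sumsq = (flat ** 2).sum(axis=0)
    means = (flips @ flat) / n
    var = (sumsq[None, :] - n * means ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t[~np.isfinite(t)] = np.sign(means[~np.isfinite(t)]) * T_SENTINEL
    return t.reshape((flips.shape[0],) + diffs.shape[1:])


def permutation_null(
    diffs: np.ndarray,
    n_permutations: int = 1000,
    alpha_cell: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> NullDistribution:
    """Build the max-cluster-mass null by within-participant sign flips.

    Each permutation flips every participant's difference map with
    probability 1/2 (random exchange of the paired condition labels),
    recomputes the full t-map and its clusters, and records the most positive
    and most negative cluster masses (0 when no cluster of that sign forms).
    Thresholds split ``cluster_alpha`` across the two tails (alpha/2 each);
    set ``cluster_alpha=0.1`` for the looser 95th/5th per-tail percentiles.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants for exchangeable permutations")
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_threshold = stats.t.ppf(1 - alpha_cell / 2.0, n - 1)
    flips = rng.integers(0, 2, size=(n_permutations, n)) * 2 - 1
    tmaps = _permutation_tmaps(diffs, flips)
    pos = np.zeros(n_permutations)
    neg = np.zeros(n_permutations)
    for i in range(n_permutations):
        _, masses_p, np_ = _label_masses(tmaps[i] > t_threshold, tmaps[i])
        if np_:
            pos[i] = masses_p.max()
        _, masses_n, nn_ = _label_masses(tmaps[i] < -t_threshold, tmaps[i])
        if nn_:
            neg[i] = masses_n.min()
    tail = cluster_alpha / 2.0
    return NullDistribution(
        pos_extremes=pos,
        neg_extremes=neg,
        threshold_pos=float(np.percentile(pos, 100 * (1 - tail))),
        threshold_neg=float(np.percentile(neg, 100 * tail)),
        n_permutations=n_permutations,
        cluster_alpha=cluster_alpha,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass(frozen=True)
class WindowStats:
    """One-sample statistics of per-participant means over a cluster's window."""

    mean_difference: float
    ci95: tuple[float, float]
    t: float
    df: int
    p_value: float
    cohens_d: float
    participant_means: np.ndarray = field(repr=False, default=None)


def window_stats(diffs: np.ndarray, cluster_or_bounds, frequencies=None, times=None
                 ) -> WindowStats:
    """MD, CI95, t, p and Cohen's d over a cluster's bounding window.

    Each participant's difference map is averaged over the cluster's bounding
    rectangle in (frequency, time); the statistics are the one-sample t
    family on those per-participant values, with Cohen's d = MD / SD of the
    values.  ``cluster_or_bounds`` may be a :class:`Cluster`, an explicit
    (f_lo, f_hi, t_lo, t_hi) index tuple, or None to use per-participant
    scalars directly (diffs of shape (n,)).
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim == 1:
        values = diffs
    else:
        if isinstance(cluster_or_bounds, Cluster):
            f0, f1, t0, t1 = cluster_or_bounds.bounds
        else:
            f0, f1, t0, t1 = cluster_or_bounds
        values = diffs[:, f0:f1 + 1, t0:t1 + 1].mean(axis=(1, 2))
    n = values.size
    md = float(values.mean())
    sd = float(values.std(ddof=1))
    dfree = n - 1
    if sd == 0:
        return WindowStats(md, (md, md), 0.0 if md == 0 else np.sign(md) * T_SENTINEL,
                           dfree, 1.0 if md == 0 else 0.0,
                           0.0 if md == 0 else np.sign(md) * np.inf, values)
    se = sd / np.sqrt(n)
    t = md / se
    p = float(2 * stats.t.sf(abs(t), dfree))
    half = stats.t.ppf(0.975, dfree) * se
    return WindowStats(md, (md - half, md + half), float(t), dfree, p,
                       md / sd, values)


def zscore_normalize(condition_maps: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Participant-level z-normalisation pooled across all conditions and cells.

    ``condition_maps`` maps condition label -> participants x freqs x times.
    For each participant, the mean and SD pooled over every condition's cells
    are subtracted/divided, so each participant's pooled output has mean 0
    and SD 1.  Invariant under any positive affine rescaling of the input.
    """
    labels = list(condition_maps)
    arrays = [np.asarray(condition_maps[l], dtype=float) for l in labels]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all conditions must cover the same participants")
    out = {l: a.copy() for l, a in zip(labels, arrays)}
    for p in range(n):
        pooled = np.concatenate([a[p].ravel() for a in arrays])
        mu, sigma = pooled.mean(), pooled.std()
        if sigma == 0:
            raise ValueError(f"zero pooled SD for participant index {p}")
        for l in labels:
            out[l][p] = (out[l][p] - mu) / sigma
    return out


class ClusterPermutationTest:
    """Paired cluster-based permutation model for one electrode and comparison.

    Built either from the two condition stacks (participants x freqs x times
    each) or directly from their differences; ``fit`` runs the permutation
    scheme and returns a :class:`ClusterPermutationResults`.
    """

    def __init__(self, a: np.ndarray, b: np.ndarray | None = None,
                 frequencies: np.ndarray | None = None,
                 times: np.ndarray | None = None):
        a = np.asarray(a, dtype=float)
        if b is None:
            diffs = a
        else:
            sample = PairedTFRSample(a, b)
            diffs = sample.differences
        if diffs.ndim != 3:
            raise ValueError("expected participants x freqs x times data")
        if diffs.shape[0] < 2:
            raise ValueError("need at least 2 participants")
        self.diffs = diffs
        self.frequencies = (np.asarray(frequencies, dtype=float)
                            if frequencies is not None else np.arange(diffs.shape[1], dtype=float))
        self.times = (np.asarray(times, dtype=float)
                      if times is not None else np.arange(diffs.shape[2], dtype=float))

    @classmethod
    def from_sample(cls, sample: PairedTFRSample) -> "ClusterPermutationTest":
        return cls(sample.a, sample.b, sample.frequencies, sample.times)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str = "db",
                       participant_col: str = "participant",
                       condition_col: str = "condition",
                       freq_col: str = "frequency", time_col: str = "time",
                       conditions: tuple[str, str] | None = None
                       ) -> "ClusterPermutationTest":
        """Build from a long-format table of per-participant dB cells."""
        if conditions is None:
            conditions = tuple(pd.unique(df[condition_col]))
        if len(conditions) != 2:
            raise ValueError("exactly two conditions are required")
        stacks = []
        freqs = np.sort(df[freq_col].unique())
        times = np.sort(df[time_col].unique())
        participants = np.sort(df[participant_col].unique())
        for cond in conditions:
            sub = df[df[condition_col] == cond]
            cube = (sub.pivot_table(index=[participant_col, freq_col],
                                    columns=time_col, values=value_col)
                    .to_numpy()
                    .reshape(len(participants), len(freqs), len(times)))
            stacks.append(cube)
        return cls(stacks[0], stacks[1], freqs, times)

    @property
    def n_participants(self) -> int:
        return self.diffs.shape[0]

    def fit(self, n_permutations: int = 1000, alpha_cell: float = 0.05,
            cluster_alpha: float = 0.05,
            seed: int | None = None) -> "ClusterPermutationResults":
        df = self.n_participants - 1
        tmap = paired_t_map(self.diffs)
        clusters = extract_clusters(tmap, df=df, alpha_cell=alpha_cell)
        null = permutation_null(self.diffs, n_permutations=n_permutations,
                                alpha_cell=alpha_cell, cluster_alpha=cluster_alpha,
                                seed=seed)
        scored = []
        for c in clusters:
            if c.sign > 0:
                p = (1 + np.sum(null.pos_extremes >= c.mass)) / (1 + n_permutations)
            else:
                p = (1 + np.sum(null.neg_extremes <= c.mass)) / (1 + n_permutations)
            scored.append(dataclasses.replace(c, p_value=float(p)))
        return ClusterPermutationResults(
            model=self, tmap=tmap, clusters=scored, null=null,
            alpha_cell=alpha_cell, seed=seed,
        )


@dataclass
class ClusterPermutationResults:
    """Fitted cluster-permutation results: t-map, clusters, null, window stats."""

    model: ClusterPermutationTest
    tmap: np.ndarray
    clusters: list[Cluster]
    null: NullDistribution
    alpha_cell: float
    seed: int | None = None

    @property
    def significant_clusters(self) -> list[Cluster]:
        """Clusters whose mass exceeds the 95th/5th-percentile null thresholds."""
        out = []
        for c in self.clusters:
            if c.sign > 0 and c.mass > self.null.threshold_pos:
                out.append(c)
            elif c.sign < 0 and c.mass < self.null.threshold_neg:
                out.append(c)
        return out

    def window_stats(self, cluster: Cluster) -> WindowStats:
        return window_stats(self.model.diffs, cluster)

    def cluster_window(self, cluster: Cluster) -> dict:
        f0, f1, t0, t1 = cluster.bounds
        return {
            "f_lo_hz": float(self.model.frequencies[f0]),
            "f_hi_hz": float(self.model.frequencies[f1]),
            "t_lo_ms": float(self.model.times[t0]),
            "t_hi_ms": float(self.model.times[t1]),
        }

    def summary(self) -> str:
        """Readable report of the fit: thresholds and per-cluster statistics."""
        lines = [
            "Cluster-based permutation test (paired, sign-flip)",
            f"  participants: {self.model.n_participants}   "
            f"permutations: {self.null.n_permutations}   "
            f"per-cell alpha: {self.alpha_cell}",
            f"  null thresholds: mass > {self.null.threshold_pos:.2f} (pos), "
            f"mass < {self.null.threshold_neg:.2f} (neg)",
        ]
        sig = self.significant_clusters
        if not sig:
            lines.append("  no significant clusters")
            return "\n".join(lines)
        rows = []
        for c in sig:
            ws = self.window_stats(c)
            win = self.cluster_window(c)
            rows.append({
                "sign": "+" if c.sign > 0 else "-",
                "mass": round(c.mass, 2),
                "p": round(c.p_value, 4),
                "band_Hz": f"{win['f_lo_hz']:g}-{win['f_hi_hz']:g}",
                "window_ms": f"{win['t_lo_ms']:g}..{win['t_hi_ms']:g}",
                "MD_dB": round(ws.mean_difference, 2),
                "CI95": f"[{ws.ci95[0]:.2f}, {ws.ci95[1]:.2f}]",
                "t": round(ws.t, 2),
                "d": round(ws.cohens_d, 2),
            })
        lines.append(pd.DataFrame(rows).to_string(index=False))
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serialisable report bundle for one comparison."""
        report = {
            "n_participants": self.model.n_participants,
            "n_permutations": self.null.n_permutations,
            "alpha_cell": self.alpha_cell,
            "seed": self.seed,
            "threshold_pos": self.null.threshold_pos,
            "threshold_neg": self.null.threshold_neg,
            "clusters": [],
        }
        for c in self.significant_clusters:
            ws = self.window_stats(c)
            report["clusters"].append({
                "sign": c.sign,
                "mass": c.mass,
                "p_cluster": c.p_value,
                "n_cells": c.size,
                "window": self.cluster_window(c),
                "mean_difference_db": ws.mean_difference,
                "ci95": list(ws.ci95),
                "t": ws.t,
                "df": ws.df,
                "p": ws.p_value,
                "cohens_d": ws.cohens_d,
            })
        return report

    def plot_tmap(self, ax=None, outline_significant: bool = True):
        """Image of the t-map with significant clusters outlined."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        extent = (self.model.times[0], self.model.times[-1],
                  self.model.frequencies[0], self.model.frequencies[-1])
        im = ax.imshow(self.tmap, aspect="auto", origin="lower", extent=extent,
                       cmap="RdBu_r")
        if outline_significant:
            mask = np.zeros_like(self.tmap)
            for c in self.significant_clusters:
                for (fi, ti) in c.cells:
                    mask[fi, ti] = 1
            if mask.any():
                ax.contour(self.model.times, self.model.frequencies, mask,
                           levels=[0.5], colors="k", linewidths=1.0)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("frequency (Hz)")
        ax.figure.colorbar(im, ax=ax, label="t")
        return ax
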