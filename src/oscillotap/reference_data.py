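"""Published per-participant window averages used as recomputation fixtures.

These are the individual-subject mean dB differences (n = 20) inside each
time-frequency window that survived the cluster-based permutation test in
the finger-tapping-to-music EEG study this pipeline reimplements, one column
per significant comparison x electrode, split by pacing rate.  Feeding a
column to :func:`oscillotap.clusterstats.window_stats` reproduces the study's
reported group statistics (mean difference, 95% CI, t, Cohen's d).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["SLOW_70BPM", "FAST_140BPM", "reference_table", "reference_column"]

# 70 BPM (slow) pacing: column label -> 20 per-subject dB differences
SLOW_70BPM: dict[str, tuple[float, ...]] = {
    "Relaxing-ToneOnly FCz": (
        2.87, 1.02, 2.32, 0.77, 0.15, 2.10, 0.22, 0.51, -1.19, 0.80,
        2.25, -0.45, 0.36, -1.20, 5.83, 0.97, 1.51, 0.44, 7.58, -0.81,
    ),
    "Activating-Relaxing C4": (
        -3.70, -0.09, 0.13, 0.59, -3.28, -0.56, -0.97, -2.98, -3.54, -0.26,
        -3.84, -0.40, 1.62, -0.82, -4.57, -1.26, -0.16, -1.54, -1.82, 2.89,
    ),
    "Activating-Relaxing T7": (
        -2.01, 0.00, -0.45, -1.43, -5.03, -1.52, 1.17, 0.18, -5.74, 0.81,
        -0.42, 0.45, -1.28, -0.31, 2.59, -2.59, -3.83, -2.08, -1.41, -1.11,
    ),
}

# 140 BPM (fast) pacing
FAST_140BPM: dict[str, tuple[float, ...]] = {
    "Relaxing-ToneOnly FCz": (
        0.44, 0.62, -0.62, 2.46, -1.61, 0.30, 0.42, 0.68, 2.31, 1.15,
        1.64, 2.78, 0.23, 0.11, 10.12, 2.20, 0.44, -0.54, -0.16, -0.18,
    ),
    "Relaxing-ToneOnly Cz": (
        3.42, 0.55, 0.74, 1.14, -1.17, -1.02, 3.46, 0.06, -0.22, 0.66,
        1.19, 3.23, -0.26, -0.95, 5.27, 2.61, 3.28, 0.28, -0.42, -0.18,
    ),
    "Activating-Relaxing FC3": (
        0.69, 1.72, 0.46, 1.46, 2.15, -0.13, 4.16, -0.68, 0.35, -0.24,
        -0.09, 1.06, 3.85, -1.50, 4.68, 1.21, 1.01, 0.63, 0.04, -0.57,
    ),
    "Activating-Relaxing Cz": (
        1.24, -1.32, 0.43, -2.55, -3.10, 0.39, -2.05, -5.29, -1.24, 0.07,
        -3.44, -1.95, -2.79, 1.41, 1.12, -1.48, 0.20, -0.11, -0.50, 0.00,
    ),
}


def reference_table(rate: float) -> pd.DataFrame:
    """The per-subject reference columns for one pacing rate as a DataFrame (dB)."""
    table = {70.0: SLOW_70BPM, 140.0: FAST_140BPM}.get(float(rate))
    if table is None:
        raise ValueError(f"no reference table for rate {rate} BPM")
    return pd.DataFrame({k: np.asarray(v) for k, v in table.items()})


def reference_column(rate: float, comparison: str, electrode: str) -> np.ndarray:
    """One reference column, e.g. reference_column(70, 'Relaxing-ToneOnly', 'FCz')."""
    df = reference_table(rate)
    key = f"{comparison} {electrode}"
    if key not in df.columns:
        raise KeyError(f"no reference column {key!r} at {rate} BPM; "
                       f"available: {list(df.columns)}")
    return df[key].to_numpy()
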