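"""Standard 10-20/10-10 electrode positions on the unit sphere."""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np

__all__ = ["MontagePositions", "standard_positions"]


class MontagePositions(Mapping):
    """Channel label -> unit-sphere 3D coordinate.

    Positions are normalised to unit norm so the spherical-spline machinery
    can treat the scalp as a sphere.
    """

    def __init__(self, positions: Mapping[str, np.ndarray]):
        self._pos: dict[str, np.ndarray] = {}
        for label, xyz in positions.items():
            xyz = np.asarray(xyz, dtype=float)
            norm = np.linalg.norm(xyz)
            if norm == 0:
                raise ValueError(f"channel {label!r} has a zero position vector")
            self._pos[label] = xyz / norm

    def __getitem__(self, label: str) -> np.ndarray:
        return self._pos[label]

    def __iter__(self):
        return iter(self._pos)

    def __len__(self) -> int:
        return len(self._pos)

    def array(self, labels: Iterable[str]) -> np.ndarray:
        """Stack unit vectors for ``labels`` into an (n, 3) array."""
        missing = [l for l in labels if l not in self._pos]
        if missing:
            raise KeyError(f"channels without montage positions: {missing}")
        return np.stack([self._pos[l] for l in labels])


def standard_positions(labels: Iterable[str] | None = None) -> MontagePositions:
    """Load standard 10-05 positions (superset of 10-20) from mne's montage data."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    if labels is not None:
        labels = list(labels)
        missing = [l for l in labels if l not in pos]
        if missing:
            raise KeyError(f"labels not in the standard montage: {missing}")
        pos = {l: pos[l] for l in labels}
    return MontagePositions(pos)
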