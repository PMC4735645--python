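"""The Recording container: a multichannel time series with geometry.

A Recording bundles a channels x samples data matrix with its sampling rate,
channel labels, and per-channel 3-D positions in MNI millimetres. It is the
common currency between the simulator, the preprocessing stage, and file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """Multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values, arbitrary units.
    rate : float
        Sampling frequency in Hz.
    labels : list of str
        One identifier per channel.
    coords : ndarray, shape (n_channels, 3)
        Channel positions in MNI space, millimetres.
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    coords: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = list(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n_ch = self.data.shape[0]
        if len(self.labels) != n_ch:
            raise ValueError(
                f"{len(self.labels)} labels for {n_ch} data rows"
            )
        if self.coords.shape != (n_ch, 3):
            raise ValueError(
                f"coords must be ({n_ch}, 3), got {self.coords.shape}"
            )
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.data.shape[1] < 2 * self.rate:
            raise ValueError("recording must be at least 2 s long")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.rate
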