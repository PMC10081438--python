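"""Frequency-band definitions and the 5-second analysis window grid.

All connectome-level quantities in this package live on a regular grid of
non-overlapping windows (default 5 s). Frequency bands follow the standard
clinical iEEG split: theta 4-8 Hz, alpha 8-12 Hz, low beta 14-20 Hz, high
beta 20-30 Hz, gamma 30-70 Hz. Band membership of an FFT bin is half-open,
``low <= f < high``, so shared edges are never double counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Band", "BandSpec", "DEFAULT_BANDS", "WindowGrid"]


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"band {self.name!r}: low must be < high")


@dataclass(frozen=True)
class BandSpec:
    """Ordered collection of analysis bands."""

    bands: tuple = (
        Band("theta", 4.0, 8.0),
        Band("alpha", 8.0, 12.0),
        Band("beta_low", 14.0, 20.0),
        Band("beta_high", 20.0, 30.0),
        Band("gamma", 30.0, 70.0),
    )

    def __len__(self):
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self):
        return [b.name for b in self.bands]

    @property
    def max_edge(self) -> float:
        return max(b.high for b in self.bands)

    def bin_masks(self, freqs):
        """Boolean mask per band over an array of FFT bin frequencies."""
        freqs = np.asarray(freqs)
        return [(freqs >= b.low) & (freqs < b.high) for b in self.bands]


DEFAULT_BANDS = BandSpec()


@dataclass
class WindowGrid:
    """Regular tiling of a recording into fixed-length windows.

    Parameters
    ----------
    window_len : float
        Window length in seconds (default 5).
    start_times : ndarray
        Window start times in seconds, strictly increasing with spacing
        equal to ``window_len``.
    keep_mask : ndarray of bool
        Per-window retention flag; windows excluded (e.g. around ictal
        events) are False and carry missing markers downstream, never
        fabricated values.
    """

    window_len: float
    start_times: np.ndarray
    keep_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.start_times = np.asarray(self.start_times, dtype=float)
        if self.keep_mask is None:
            self.keep_mask = np.ones(self.start_times.size, dtype=bool)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if self.keep_mask.size != self.start_times.size:
            raise ValueError("keep_mask length must equal number of windows")
        if self.start_times.size > 1:
            d = np.diff(self.start_times)
            if np.any(d <= 0) or not np.allclose(d, self.window_len, rtol=1e-6):
                raise ValueError("start_times must increase with spacing window_len")

    @classmethod
    def regular(cls, duration: float, window_len: float = 5.0, t0: float = 0.0):
        n = int(np.floor(duration / window_len))
        return cls(window_len, t0 + window_len * np.arange(n))

    @property
    def n_windows(self) -> int:
        return self.start_times.size

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    def replace_mask(self, keep_mask) -> "WindowGrid":
        return WindowGrid(self.window_len, self.start_times.copy(), np.asarray(keep_mask, bool))
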