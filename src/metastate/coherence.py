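"""Windowed, band-resolved magnitude-squared coherence between all channel pairs.

The connectome stream is a tensor of shape (windows, channel-pairs, bands).
Within each analysis window the cross-spectrum is estimated by Welch's method
(1-s Hann segments, 50% overlap, nine segments per 5-s window), giving at
least 4 Hz resolution so the theta band is covered. Band values are the
unweighted mean of magnitude-squared coherence over FFT bins whose center
frequency lies in ``[low, high)``.

Windows overlapping an exclusion interval (e.g. one hour around ictal events)
are masked and carry NaN, never fabricated values. Re-referencing is assumed
to have happened upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal import get_window

from .bands import BandSpec, DEFAULT_BANDS, WindowGrid

__all__ = ["CoherenceTensor", "build_exclusion_mask", "pairwise_coherence"]

logger = logging.getLogger(__name__)


@dataclass
class CoherenceTensor:
    """values: (windows, pairs, bands); masked windows are NaN rows."""

    values: np.ndarray
    pair_index: list
    grid: WindowGrid
    bands: BandSpec = DEFAULT_BANDS

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)

    def kept_values(self) -> np.ndarray:
        return self.values[self.grid.keep_mask]


def build_exclusion_mask(event_intervals, grid: WindowGrid, pad: float = 3600.0) -> WindowGrid:
    """Mask every window overlapping ``[start - pad, end + pad]`` of any event.

    Parameters
    ----------
    event_intervals : sequence of (start_s, end_s)
        Event spans in seconds (e.g. ictal intervals from the clinical team).
    grid : WindowGrid
    pad : float
        Guard band in seconds applied symmetrically around each event
        (default one hour).

    Returns a new grid whose ``keep_mask`` is the AND of the existing mask
    with the exclusion; applying the same events twice is a no-op.
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    keep = grid.keep_mask.copy()
    w_start = grid.start_times
    w_end = grid.start_times + grid.window_len
    for start, end in event_intervals:
        if end < start:
            raise ValueError(f"event interval ({start}, {end}) has end < start")
        lo, hi = start - pad, end + pad
        keep &= ~((w_start < hi) & (w_end > lo))
    return grid.replace_mask(keep)


def _segment_fft(sig, nperseg, step, taper):
    """FFT of overlapping tapered segments: (channels, segments, freqs)."""
    n_ch, n = sig.shape
    n_seg = 1 + (n - nperseg) // step
    idx = step * np.arange(n_seg)[:, None] + np.arange(nperseg)[None, :]
    segs = sig[:, idx]                      # (ch, seg, nperseg)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    return np.fft.rfft(segs * taper, axis=-1)


def pairwise_coherence(
    signal,
    fs: float,
    grid: WindowGrid,
    bands: BandSpec = DEFAULT_BANDS,
    seg_len: float = 1.0,
    overlap: float = 0.5,
    pair_index=None,
) -> CoherenceTensor:
    """Magnitude-squared coherence for every channel pair in every window.

    Parameters
    ----------
    signal : ndarray (channels, samples)
    fs : float
        Sampling rate in Hz; must cover the highest band edge (Nyquist).
    grid : WindowGrid
        Masked windows are skipped (NaN in the output).
    bands : BandSpec
    seg_len, overlap : float
        Welch segmentation within each window (seconds, fraction).
    pair_index : optional list of (i, j)
        Restrict to these pairs; default all i<j pairs.

    Notes
    -----
    A channel with zero variance inside a window makes coherence undefined
    for its pairs; those entries are NaN and a warning is logged, per the
    missing-marker contract.
    """
    signal = np.asarray(signal, dtype=float)
    n_ch, n_samp = signal.shape
    if fs < 2 * bands.max_edge:
        raise ValueError(
            f"fs={fs} too low: band '{bands.bands[-1].name}' needs fs >= {2 * bands.max_edge}"
        )
    if pair_index is None:
        pair_index = list(combinations(range(n_ch), 2))
    nperseg = int(round(seg_len * fs))
    step = max(1, int(round(nperseg * (1 - overlap))))
    taper = get_window("hann", nperseg)
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    masks = bands.bin_masks(freqs)
    for b, m in zip(bands, masks):
        if not m.any():
            raise ValueError(f"band {b.name} has no FFT bins at fs={fs}")

    win_samp = int(round(grid.window_len * fs))
    ii = np.array([p[0] for p in pair_index])
    jj = np.array([p[1] for p in pair_index])
    out = np.full((grid.n_windows, len(pair_index), len(bands)), np.nan)
    warned = False

    for w in range(grid.n_windows):
        if not grid.keep_mask[w]:
            continue
        s0 = int(round(grid.start_times[w] * fs))
        if s0 < 0 or s0 + win_samp > n_samp:
            raise ValueError(f"window {w} extends beyond the signal")
        X = _segment_fft(signal[:, s0:s0 + win_samp], nperseg, step, taper)
        Sxx = np.mean(np.abs(X) ** 2, axis=1)            # (ch, freq)
        Sxy = np.mean(X[ii] * np.conj(X[jj]), axis=1)    # (pairs, freq)
        denom = Sxx[ii] * Sxx[jj]
        bad = ~(denom > 0)
        if bad.any() and not warned:
            logger.warning("zero-variance channel(s) in window %d: coherence undefined", w)
            warned = True
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(Sxy) ** 2 / denom
        coh[bad] = np.nan
        for k, m in enumerate(masks):
            out[w, :, k] = coh[:, m].mean(axis=1)

    kept = out[grid.keep_mask]
    finite = kept[np.isfinite(kept)]
    if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
        raise AssertionError("coherence outside [0, 1] beyond numerical slack")
    np.clip(out, 0.0, 1.0, out=out)
    return CoherenceTensor(out, pair_index, grid, bands)


def mean_coherence_matrix(coh: CoherenceTensor, n_channels: int, band=None) -> np.ndarray:
    """Channel x channel matrix of time-averaged coherence.

    ``band`` selects one band index; default averages across bands. Used as
    the similarity input to channel parcellation. Diagonal is 1.
    """
    vals = coh.kept_values()
    if band is None:
        v = np.nanmean(vals, axis=(0, 2))
    else:
        v = np.nanmean(vals[:, :, band], axis=0)
    M = np.eye(n_channels)
    for (i, j), x in zip(coh.pair_index, v):
        M[i, j] = M[j, i] = x
    return M
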