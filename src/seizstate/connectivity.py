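"""Sliding-window band-averaged coherence from multichannel ictal recordings.

Each seizure's intracranial EEG is re-referenced to a common average, cut into
overlapping windows (10 s window, 9 s step overlap by default), and for every
channel pair the magnitude-squared coherence is estimated per window with
Welch's method and averaged over the frequency bins of six canonical EEG
bands. The result is a non-negative ``n_windows x n_bands x n_pairs`` tensor
whose flattened windows are the columns the network-state factorization
consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.signal.windows import hann

logger = logging.getLogger(__name__)

#: delta through high gamma, the standard clinical iEEG band set
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 80.0),
    ("high_gamma", 80.0, 150.0),
)


@dataclass(frozen=True)
class BandSet:
    """Ordered set of frequency bands (name, f_lo, f_hi) in Hz."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        for name, lo, hi in self.bands:
            if not (0 <= lo < hi):
                raise ValueError(f"band {name!r}: need 0 <= f_lo < f_hi, got ({lo}, {hi})")

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def __len__(self) -> int:
        return len(self.bands)

    def usable(self, fs: float) -> "BandSet":
        """Drop bands whose upper edge exceeds the Nyquist frequency."""
        kept = tuple(b for b in self.bands if b[2] <= fs / 2)
        dropped = [b[0] for b in self.bands if b[2] > fs / 2]
        if dropped:
            logger.warning("dropping bands above Nyquist (%.1f Hz): %s", fs / 2, dropped)
        if not kept:
            raise ValueError(f"no band below Nyquist at fs={fs}")
        return BandSet(kept)


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window parameters, in seconds."""

    window_s: float = 10.0
    overlap_s: float = 9.0
    min_seizure_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_s < self.window_s):
            raise ValueError("need 0 <= overlap_s < window_s")

    @property
    def step_s(self) -> float:
        return self.window_s - self.overlap_s

    def n_windows(self, length_s: float) -> int:
        """Number of full windows in a record of ``length_s`` seconds."""
        if length_s < self.window_s:
            return 0
        return int(np.floor((length_s - self.window_s) / self.step_s)) + 1


@dataclass
class ConnectivityTensor:
    """Per-window band-averaged coherence for one seizure.

    ``values`` has shape (n_windows, n_bands, n_pairs); all entries lie in
    [0, 1]. Channel pairs are in fixed lexicographic (i < j) order.
    """

    values: np.ndarray
    window_start_s: np.ndarray
    band_names: list[str]
    channel_pairs: list[tuple[int, int]] = field(repr=False)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.values.shape[1] * self.values.shape[2]

    def flatten_windows(self) -> np.ndarray:
        """(feature_dim, n_windows) matrix: band-major, pair-minor features."""
        return self.values.reshape(self.n_windows, -1).T


def channel_pairs(n_channels: int) -> list[tuple[int, int]]:
    """Lexicographic (i, j) with i < j."""
    return list(combinations(range(n_channels), 2))


def common_average_reference(signals: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous cross-channel mean from every channel.

    Parameters
    ----------
    signals : (n_channels, n_samples) array

    Returns
    -------
    Re-referenced array of the same shape; the channel mean at every sample
    is zero.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[0] < 2:
        raise ValueError("common average reference requires >= 2 channels")
    if not np.all(np.isfinite(signals)):
        raise ValueError("non-finite samples in input")
    return signals - signals.mean(axis=0, keepdims=True)


def _welch_cross_spectra(x: np.ndarray, fs: float, nperseg: int, noverlap: int):
    """Welch auto/cross spectra for all channels at once.

    Returns (freqs, S) where S[a, b, f] is the averaged cross-spectral
    density between channels a and b (one-sided, Hann taper, constant
    detrend per segment) — identical up to scaling to what
    ``scipy.signal.csd`` computes with the same parameters; scaling cancels
    in coherence.
    """
    n_ch, n_samp = x.shape
    step = nperseg - noverlap
    n_seg = (n_samp - nperseg) // step + 1
    if n_seg < 1:
        raise ValueError("window shorter than one Welch segment")
    taper = hann(nperseg, sym=False)
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    segs = x[:, idx]                                # (n_ch, n_seg, nperseg)
    segs = segs - segs.mean(axis=-1, keepdims=True)  # constant detrend
    F = np.fft.rfft(segs * taper, axis=-1)           # (n_ch, n_seg, n_freq)
    # averaged cross-spectra over segments
    S = np.einsum("asf,bsf->abf", F, np.conj(F)) / n_seg
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, S


def sliding_band_coherence(
    signals: np.ndarray,
    fs: float,
    wcfg: WindowingConfig | None = None,
    bands: BandSet | None = None,
    *,
    welch_segment_s: float = 2.0,
    apply_car: bool = True,
) -> ConnectivityTensor:
    """Sliding-window, band-averaged magnitude-squared coherence.

    Windows are half-open ``[t, t + window_s)`` anchored at seizure onset,
    stepping by ``window_s - overlap_s``; a trailing partial window is
    discarded. Within each window coherence is estimated with Welch's method
    (``welch_segment_s`` Hann segments, 50% overlap) and averaged over the
    FFT bins with ``f_lo <= f < f_hi`` for each band.
    """
    wcfg = wcfg or WindowingConfig()
    bands = (bands or BandSet()).usable(fs)
    signals = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(signals)):
        raise ValueError("non-finite samples in input")
    if apply_car:
        signals = common_average_reference(signals)
    n_ch, n_samp = signals.shape
    length_s = n_samp / fs
    n_win = wcfg.n_windows(length_s)
    if n_win == 0:
        raise ValueError(
            f"record of {length_s:.1f}s shorter than one {wcfg.window_s:.0f}s window"
        )

    win_len = int(round(wcfg.window_s * fs))
    step_len = int(round(wcfg.step_s * fs))
    nperseg = min(int(round(welch_segment_s * fs)), win_len)
    noverlap = nperseg // 2

    pairs = channel_pairs(n_ch)
    pi = np.array([p[0] for p in pairs])
    pj = np.array([p[1] for p in pairs])

    values = np.empty((n_win, len(bands), len(pairs)))
    starts = np.empty(n_win)
    band_bins: list[np.ndarray] | None = None
    for w in range(n_win):
        s0 = w * step_len
        freqs, S = _welch_cross_spectra(signals[:, s0 : s0 + win_len], fs, nperseg, noverlap)
        if band_bins is None:
            band_bins = [
                np.flatnonzero((freqs >= lo) & (freqs < hi)) for _, lo, hi in bands.bands
            ]
            for (name, lo, hi), bins in zip(bands.bands, band_bins):
                if bins.size == 0:
                    raise ValueError(f"band {name!r} contains no FFT bins at fs={fs}")
        auto = np.real(np.einsum("iif->if", S))     # (n_ch, n_freq)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(S[pi, pj, :]) ** 2 / (auto[pi] * auto[pj])
        coh = np.nan_to_num(coh, nan=0.0)
        for b, bins in enumerate(band_bins):
            values[w, b, :] = coh[:, bins].mean(axis=1)
        starts[w] = s0 / fs

    values = np.clip(values, 0.0, 1.0)
    return ConnectivityTensor(values, starts, bands.names, pairs)


def build_feature_matrix(
    tensors: Sequence[ConnectivityTensor],
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-seizure tensors into one (feature_dim, total_windows) matrix.

    Returns the matrix and a ``window -> seizure index`` array. Column order
    preserves seizure order, then window order within each seizure.
    """
    if len(tensors) == 0:
        raise ValueError("empty tensor list")
    dims = {(t.values.shape[1], t.values.shape[2]) for t in tensors}
    if len(dims) > 1:
        raise ValueError(f"mismatched band/channel dimensions across seizures: {dims}")
    X = np.concatenate([t.flatten_windows() for t in tensors], axis=1)
    mapping = np.concatenate(
        [np.full(t.n_windows, i, dtype=int) for i, t in enumerate(tensors)]
    )
    return X, mapping
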