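"""Empirical mode decomposition with complete ensemble adaptive noise (CEEMDAN).

EMD iteratively sifts a series into intrinsic mode functions (IMFs):
oscillatory components with time-varying amplitude and frequency, obtained by
repeatedly subtracting the mean of the cubic-spline envelopes through the
local maxima and minima. Plain EMD suffers from mode mixing on noisy data;
CEEMDAN stabilises it by adding, at each decomposition stage, scaled IMFs of
an ensemble of white-noise realisations and averaging the first sifted mode
across the ensemble. By construction the IMFs plus the final residual sum
exactly to the input.

This implementation follows the standard formulation: sifting with mirrored
boundary extrema, an energy-ratio stopping criterion, and stage-wise noise
whose amplitude tracks the running residual's standard deviation.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["emd", "ceemdan"]

_NBSYM = 2  # extrema mirrored at each boundary


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints included)."""
    d = np.diff(x)
    # collapse zero slopes so plateaus register a single extremum
    nz = np.flatnonzero(d != 0)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    sgn = np.sign(d[nz])
    turn = np.flatnonzero(sgn[1:] != sgn[:-1])
    idx = nz[turn] + 1
    maxima = idx[sgn[turn] > 0]
    minima = idx[sgn[turn] < 0]
    return maxima, minima


def _mirror(pos: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to _NBSYM extrema about both record ends to anchor the spline."""
    k = min(_NBSYM, pos.size)
    lpos = -pos[:k][::-1]
    rpos = 2 * (n - 1) - pos[-k:][::-1]
    return (
        np.concatenate([lpos, pos, rpos]),
        np.concatenate([val[:k][::-1], val, val[-k:][::-1]]),
    )


def _mean_envelope(x: np.ndarray) -> np.ndarray | None:
    """Mean of upper/lower cubic-spline envelopes; None if too few extrema."""
    n = x.size
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    t = np.arange(n)
    pmax, vmax = _mirror(maxima, x[maxima], n)
    pmin, vmin = _mirror(minima, x[minima], n)
    upper = CubicSpline(pmax, vmax)(t)
    lower = CubicSpline(pmin, vmin)(t)
    return 0.5 * (upper + lower)


def _sift(x: np.ndarray, stop_ratio: float = 0.01, max_siftings: int = 30) -> np.ndarray | None:
    """Extract one IMF from ``x``; None if ``x`` is already monotone/trend-like."""
    h = x
    for _ in range(max_siftings):
        m = _mean_envelope(h)
        if m is None:
            return None if h is x else h
        h_new = h - m
        denom = float(np.dot(h, h))
        if denom <= 0 or float(np.dot(m, m)) / denom < stop_ratio:
            return h_new
        h = h_new
    return h


def emd(
    x: np.ndarray,
    max_imfs: int | None = None,
    stop_ratio: float = 0.01,
    max_siftings: int = 30,
) -> np.ndarray:
    """Decompose ``x`` into IMFs; returns an (n_imfs, n) array.

    The residual (trend) is not included; it is ``x - imfs.sum(axis=0)``.
    Raises on an all-constant input, which has no oscillatory content.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no intrinsic mode functions")
    imfs: list[np.ndarray] = []
    r = x.copy()
    while max_imfs is None or len(imfs) < max_imfs:
        imf = _sift(r, stop_ratio, max_siftings)
        if imf is None:
            break
        imfs.append(imf)
        r = r - imf
        maxima, minima = _local_extrema(r)
        if maxima.size + minima.size < 3:
            break
    if not imfs:
        raise ValueError("no intrinsic mode functions extracted")
    return np.vstack(imfs)


def ceemdan(
    x: np.ndarray,
    ensemble_size: int = 100,
    noise_strength: float = 0.2,
    seed: int | np.random.Generator = 0,
    max_imfs: int | None = None,
) -> np.ndarray:
    """Complete ensemble EMD with adaptive noise.

    Parameters
    ----------
    x : 1-D series.
    ensemble_size : number of white-noise realisations averaged per stage.
    noise_strength : noise sd as a fraction of the running residual's sd.
    seed : seed or Generator; fixes the noise ensemble.
    max_imfs : optional cap on the number of modes.

    Returns
    -------
    (n_imfs, n) array of IMFs. ``x - imfs.sum(axis=0)`` is the residual, and
    the reconstruction ``imfs.sum(axis=0) + residual`` equals ``x`` exactly.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant series has no intrinsic mode functions")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = x.size

    # precompute the IMFs of each unit-variance noise realisation once;
    # stage k reuses the k-th noise mode scaled to the running residual
    noise_imfs: list[np.ndarray] = []
    for _ in range(ensemble_size):
        w = rng.standard_normal(n)
        try:
            noise_imfs.append(emd(w))
        except ValueError:
            noise_imfs.append(np.zeros((1, n)))

    imfs: list[np.ndarray] = []
    r = x.copy()
    stage = 0
    while max_imfs is None or len(imfs) < max_imfs:
        r_sd = float(np.std(r))
        if r_sd == 0:
            break
        beta = noise_strength * r_sd
        acc = np.zeros(n)
        n_ok = 0
        for ni in noise_imfs:
            if stage < ni.shape[0]:
                perturbed = r + beta * ni[stage]
            else:
                perturbed = r
            mode = _sift(perturbed)
            if mode is not None:
                acc += mode
                n_ok += 1
        if n_ok == 0:
            break
        imf = acc / n_ok
        imfs.append(imf)
        r = r - imf
        stage += 1
        maxima, minima = _local_extrema(r)
        if maxima.size + minima.size < 3:
            break
    if not imfs:
        raise ValueError("no intrinsic mode functions extracted")
    return np.vstack(imfs)
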