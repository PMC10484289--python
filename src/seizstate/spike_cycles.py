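"""Circadian and multidien cycles of the interictal spike rate.

The hourly spike-rate series is decomposed with CEEMDAN into intrinsic mode
functions; the prominent, short-period modes are kept as "spike rate cycles",
each classified circadian (average period near one day) or multidien
(multi-day). Each cycle carries an instantaneous (Hilbert) phase with the
convention phi = 0 at the cycle peak, phi = +/-pi at the trough, and
phi in (-pi, 0) on the rising limb. Every seizure is then assigned the phase
of each cycle at its onset, with seizures excluded where the cycle is not
reliably defined (record edges, interpolated gaps, collapsed amplitude).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .emd import ceemdan, emd

__all__ = [
    "CycleConfig",
    "SpikeRateCycle",
    "SeizurePhases",
    "emd_decompose",
    "average_period",
    "instantaneous_phase",
    "select_prominent",
    "assign_seizure_phases",
    "extract_cycles",
]


@dataclass(frozen=True)
class CycleConfig:
    """Cycle-extraction parameters.

    ``min_power_fraction``: minimum share of total IMF variance to keep a mode.
    ``max_period_fraction``: keep periods up to this fraction of the record.
    ``merge_period_tol``: adjacent kept IMFs closer than this relative period
    difference are summed into one cycle.
    ``circadian_bounds``: average-period window (days) labelled circadian.
    ``min_envelope_fraction``: seizure phases are invalid where the analytic
    amplitude falls below this fraction of its median.
    """

    sample_interval_days: float = 1.0 / 24.0
    min_power_fraction: float = 0.05
    min_period_days: float = 0.8          # analysis targets circadian+ timescales
    max_period_fraction: float = 1.0 / 6.0
    merge_period_tol: float = 0.25
    circadian_bounds: tuple[float, float] = (0.8, 1.2)
    min_envelope_fraction: float = 0.10
    use_ceemdan: bool = True
    ensemble_size: int = 100
    noise_strength: float = 0.2
    emd_seed: int = 0
    max_gap_samples: int = 2
    min_samples: int = 100


@dataclass
class SpikeRateCycle:
    """One extracted oscillatory component of the spike rate."""

    samples: np.ndarray
    inst_phase: np.ndarray
    envelope: np.ndarray
    avg_period: float          # days
    timescale: str             # "circadian" | "multidien"
    power_fraction: float
    cycle_id: str = ""


@dataclass
class SeizurePhases:
    """Per-seizure phase of each cycle at onset, with a validity mask."""

    seizure_ids: list
    cycle_ids: list[str]
    phases: np.ndarray         # (n_seizures, n_cycles)
    valid: np.ndarray          # bool, same shape

    def phase_of(self, seizure_idx: int, cycle_idx: int) -> float | None:
        return float(self.phases[seizure_idx, cycle_idx]) if self.valid[seizure_idx, cycle_idx] else None


def _fill_small_gaps(rate: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate NaN runs of length <= max_gap; mask longer runs.

    Returns (filled series, mask of samples that remain unreliable). Long
    gaps are still interpolated so the decomposition sees a regular grid,
    but their samples are flagged and downstream phase assignments there are
    invalid.
    """
    rate = np.asarray(rate, dtype=float).copy()
    bad = ~np.isfinite(rate)
    masked = np.zeros(rate.size, dtype=bool)
    if bad.any():
        if bad.all():
            raise ValueError("spike-rate series is entirely missing")
        idx = np.flatnonzero(bad)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        good = np.flatnonzero(~bad)
        rate[bad] = np.interp(idx, good, rate[good])
        for run in splits:
            if run.size > max_gap:
                masked[run] = True
    return rate, masked


def emd_decompose(rate: Sequence[float], cfg: CycleConfig = CycleConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a regularly-sampled spike-rate series into IMFs.

    Missing samples (NaN) in runs of at most ``cfg.max_gap_samples`` are
    linearly interpolated; longer runs are interpolated but masked. Returns
    (imfs, gap_mask); the residual is ``rate_filled - imfs.sum(0)``.
    """
    rate = np.asarray(rate, dtype=float)
    if rate.size < cfg.min_samples:
        raise ValueError(f"series shorter than {cfg.min_samples} samples")
    filled, gap_mask = _fill_small_gaps(rate, cfg.max_gap_samples)
    if np.ptp(filled) == 0:
        raise ValueError("constant series has no cycles")
    if cfg.use_ceemdan:
        imfs = ceemdan(
            filled,
            ensemble_size=cfg.ensemble_size,
            noise_strength=cfg.noise_strength,
            seed=cfg.emd_seed,
        )
    else:
        imfs = emd(filled)
    return imfs, gap_mask


def average_period(samples: Sequence[float], sample_interval_days: float = 1.0 / 24.0) -> float:
    """Average period in days: twice the mean interval between zero crossings.

    Crossing times are refined by linear interpolation between samples. The
    series is demeaned first; at least 3 crossings are required.
    """
    x = np.asarray(samples, dtype=float)
    x = x - x.mean()
    s = np.sign(x)
    s[s == 0] = 1
    idx = np.flatnonzero(s[1:] != s[:-1])
    if idx.size < 3:
        raise ValueError("fewer than 3 zero crossings: period undefined")
    frac = x[idx] / (x[idx] - x[idx + 1])
    t_cross = (idx + frac) * sample_interval_days
    return float(2.0 * np.mean(np.diff(t_cross)))


def instantaneous_phase(samples: Sequence[float]) -> np.ndarray:
    """Analytic-signal phase in (-pi, pi]: 0 at peaks, +/-pi at troughs.

    The raw Hilbert angle of a cosine already satisfies the convention
    (negative and rising just before a peak), so no shift is applied.
    """
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    return np.angle(hilbert(x - x.mean()))


def _envelope(samples: np.ndarray) -> np.ndarray:
    x = samples - samples.mean()
    return np.abs(hilbert(x))


def select_prominent(
    imfs: np.ndarray,
    recording_len_days: float,
    cfg: CycleConfig = CycleConfig(),
) -> list[SpikeRateCycle]:
    """Keep the prominent short-period IMFs as spike-rate cycles.

    A mode is kept if its share of total IMF variance is at least
    ``cfg.min_power_fraction`` and its average period lies between
    ``cfg.min_period_days`` (sub-circadian noise modes are out of scope) and
    ``cfg.max_period_fraction * recording_len_days``. Adjacent kept modes
    whose periods differ by less than ``cfg.merge_period_tol`` (relative) are
    summed into a single cycle before re-estimating the period — EMD can
    split one physiological rhythm across neighbouring modes. Cycles are
    labelled circadian when the average period falls within
    ``cfg.circadian_bounds`` days, multidien otherwise.
    """
    imfs = np.atleast_2d(np.asarray(imfs, dtype=float))
    total_var = float(np.sum(np.var(imfs, axis=1)))
    if total_var == 0:
        return []
    kept: list[tuple[np.ndarray, float, float]] = []  # (samples, period, power)
    for imf in imfs:
        power = float(np.var(imf)) / total_var
        if power < cfg.min_power_fraction:
            continue
        try:
            period = average_period(imf, cfg.sample_interval_days)
        except ValueError:
            continue
        if not (cfg.min_period_days <= period <= cfg.max_period_fraction * recording_len_days):
            continue
        kept.append((imf, period, power))

    # merge adjacent kept modes with near-identical periods
    merged: list[tuple[np.ndarray, float, float]] = []
    for samples, period, power in kept:
        if merged:
            prev_samples, prev_period, prev_power = merged[-1]
            if abs(period - prev_period) / max(period, prev_period) < cfg.merge_period_tol:
                combined = prev_samples + samples
                try:
                    new_period = average_period(combined, cfg.sample_interval_days)
                except ValueError:
                    new_period = 0.5 * (period + prev_period)
                merged[-1] = (combined, new_period, prev_power + power)
                continue
        merged.append((samples, period, power))

    cycles = []
    lo, hi = cfg.circadian_bounds
    for i, (samples, period, power) in enumerate(merged):
        timescale = "circadian" if lo <= period <= hi else "multidien"
        cycles.append(
            SpikeRateCycle(
                samples=samples,
                inst_phase=instantaneous_phase(samples),
                envelope=_envelope(samples),
                avg_period=period,
                timescale=timescale,
                power_fraction=power,
                cycle_id=f"cycle{i}_{timescale}",
            )
        )
    return cycles


def extract_cycles(
    rate: Sequence[float],
    cfg: CycleConfig = CycleConfig(),
) -> tuple[list[SpikeRateCycle], np.ndarray]:
    """End-to-end: decompose the spike rate and return (cycles, gap_mask)."""
    rate = np.asarray(rate, dtype=float)
    recording_len_days = rate.size * cfg.sample_interval_days
    if recording_len_days < 2.0:
        warnings.warn("recording shorter than 2 days; multidien cycles unresolvable")
    imfs, gap_mask = emd_decompose(rate, cfg)
    return select_prominent(imfs, recording_len_days, cfg), gap_mask


def assign_seizure_phases(
    cycles: Sequence[SpikeRateCycle],
    onset_days: Sequence[float],
    seizure_ids: Sequence | None = None,
    gap_mask: np.ndarray | None = None,
    cfg: CycleConfig = CycleConfig(),
) -> SeizurePhases:
    """Phase of every cycle at each seizure onset (nearest sample).

    A (seizure, cycle) phase is invalid when the onset falls in a masked
    gap, within half the cycle's average period of either record edge, or
    where the cycle's analytic amplitude is below
    ``cfg.min_envelope_fraction`` of its median.
    """
    onset_days = np.asarray(onset_days, dtype=float)
    if seizure_ids is None:
        seizure_ids = list(range(onset_days.size))
    n_samples = cycles[0].samples.size if cycles else 0
    record_days = n_samples * cfg.sample_interval_days
    if np.any(onset_days < 0) or (n_samples and np.any(onset_days > record_days)):
        raise ValueError("seizure onset outside the recording span")

    phases = np.full((onset_days.size, len(cycles)), np.nan)
    valid = np.zeros_like(phases, dtype=bool)
    idx = np.clip(
        np.round(onset_days / cfg.sample_interval_days).astype(int), 0, max(n_samples - 1, 0)
    )
    for c, cyc in enumerate(cycles):
        half_period = 0.5 * cyc.avg_period
        env_floor = cfg.min_envelope_fraction * float(np.median(cyc.envelope))
        ok = (
            (onset_days >= half_period)
            & (onset_days <= record_days - half_period)
            & (cyc.envelope[idx] >= env_floor)
        )
        if gap_mask is not None:
            ok &= ~gap_mask[idx]
        phases[:, c] = cyc.inst_phase[idx]
        valid[:, c] = ok
    return SeizurePhases(list(seizure_ids), [c.cycle_id for c in cycles], phases, valid)
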