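"""Synthetic cohorts with known ground truth.

Emulates the statistical structure the downstream analyses assume, so every
stage has a recovery test without any external recording:

* a small library of non-negative, non-orthogonal connectivity basis
  patterns (one per seizure network state);
* an hourly interictal spike-rate series — baseline plus a noisy circadian
  oscillator, one or more frequency-jittered multidien oscillators, and
  broadband noise — with the ground-truth instantaneous phase of every
  cycle retained;
* seizures whose onset times carry a von Mises phase preference on a
  designated cycle, each seizure an ordered run-length sequence of states
  with log-normal durations; and
* planted modulations of state occurrence probability (von Mises-shaped in
  cycle phase) and of state duration (additive on the log scale, in cycle
  phase or in recording time).

Window-level features are emitted directly as W h(t) plus truncated Gaussian
noise — the quantity the factorization consumes — so ground truth stays
exact where the statistics live. An optional raw-signal mode synthesises
band-limited multichannel traces for end-to-end tests of the connectivity
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SynthConfig",
    "CycleTruth",
    "SynthSeizure",
    "GroundTruth",
    "Cohort",
    "generate_state_library",
    "generate_spike_rate",
    "generate_seizures",
    "simulate_cohort",
    "render_raw_signals",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth cohort parameters. ``seed`` fully determines all outputs."""

    n_channels: int = 8
    n_seizures: int = 300
    recording_days: float = 90.0
    state_library_size: int = 6
    band_count: int = 6
    window_noise_sd: float = 0.05
    # spike-rate model
    circadian_period: float = 1.0
    multidien_periods: tuple[float, ...] = (10.6,)
    period_jitter_frac: float = 0.1
    cycle_amplitudes: tuple[float, ...] | None = None  # per cycle; default 30 each
    baseline_rate: float = 100.0
    spike_noise_sd: float = 10.0
    amp_mod_frac: float = 0.0           # optional slow amplitude modulation
    amp_mod_period_days: float = 30.0
    # seizure timing
    seizure_phase_kappa: float = 2.0
    seizure_phase_mu: float = 0.0
    seizure_phase_cycle: int | None = None   # default: first multidien, else circadian
    # state composition
    occurrence_base_prob: float = 0.45
    occurrence_mod_amplitude: float = 0.4
    occurrence_mod_base_prob: float | None = None   # base prob of modulated states
    occurrence_mod: tuple[tuple[int, int, float, float], ...] = ()
    # (state, cycle_index | "time", peak-to-trough log-duration effect)
    duration_mod: tuple[tuple[int, object, float], ...] = ()
    duration_log_mean: float = float(np.log(15.0))
    duration_log_sd: float = 0.5
    window_s: float = 10.0
    step_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.circadian_period <= 0 or any(p <= 0 for p in self.multidien_periods):
            raise ValueError("all cycle periods must be > 0")
        if any(p <= self.circadian_period for p in self.multidien_periods):
            raise ValueError("multidien periods must exceed the circadian period")
        if not 0 <= self.period_jitter_frac <= 0.5:
            raise ValueError("period_jitter_frac must lie in [0, 0.5]")
        if self.seizure_phase_kappa < 0:
            raise ValueError("seizure_phase_kappa must be >= 0")
        for state, cyc, kappa, psi0 in self.occurrence_mod:
            if kappa < 0:
                raise ValueError("occurrence_mod kappa must be >= 0")
            if not (-np.pi < psi0 <= np.pi):
                raise ValueError("preferred phase must lie in (-pi, pi]")
        if self.state_library_size < 1:
            raise ValueError("state_library_size must be >= 1")

    @property
    def n_pairs(self) -> int:
        return comb(self.n_channels, 2)

    @property
    def feature_dim(self) -> int:
        return self.band_count * self.n_pairs

    @property
    def periods(self) -> tuple[float, ...]:
        """All cycle periods, circadian first."""
        return (self.circadian_period, *self.multidien_periods)

    @property
    def amplitudes(self) -> tuple[float, ...]:
        if self.cycle_amplitudes is not None:
            if len(self.cycle_amplitudes) != len(self.periods):
                raise ValueError("cycle_amplitudes must match the number of cycles")
            return tuple(self.cycle_amplitudes)
        return tuple(30.0 for _ in self.periods)

    @property
    def timing_cycle(self) -> int:
        if self.seizure_phase_cycle is not None:
            return self.seizure_phase_cycle
        return 1 if self.multidien_periods else 0

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per named stream, all derived from ``seed``."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


# stream ids so each operation's randomness is independent yet seed-determined
_S_LIBRARY, _S_RATE, _S_TIMES, _S_COMPOSE, _S_FEATURES, _S_RAW = range(6)


@dataclass
class CycleTruth:
    """Ground truth for one planted spike-rate cycle."""

    nominal_period: float
    phase_unwrapped: np.ndarray     # radians on the hourly grid
    amplitude: np.ndarray

    @property
    def phase(self) -> np.ndarray:
        """Wrapped to (-pi, pi]; 0 at the cycle peak."""
        return np.angle(np.exp(1j * self.phase_unwrapped))

    def phase_at(self, t_days: np.ndarray | float, dt_days: float = 1.0 / 24.0) -> np.ndarray:
        idx = np.clip(
            np.round(np.asarray(t_days) / dt_days).astype(int), 0, self.phase.size - 1
        )
        return self.phase[idx]


@dataclass
class SynthSeizure:
    """One generated seizure with its planted state progression."""

    id: int
    onset_day: float
    state_order: np.ndarray             # distinct states in visit order
    state_sequence: np.ndarray          # per-window labels
    durations: dict[int, int]
    features: np.ndarray                # (feature_dim, n_windows)

    @property
    def n_windows(self) -> int:
        return self.state_sequence.size

    def duration_s(self, window_s: float = 10.0, step_s: float = 1.0) -> float:
        return window_s + (self.n_windows - 1) * step_s


@dataclass
class GroundTruth:
    true_W: np.ndarray
    cycles: list[CycleTruth]
    seizure_phases: np.ndarray          # (n_seizures, n_cycles) at onset
    occurrence_mod: tuple
    duration_mod: tuple
    state_sequences: list[np.ndarray] = field(default_factory=list)


@dataclass
class Cohort:
    """Full synthetic dataset: spike rate, seizures and their ground truth."""

    config: SynthConfig
    time_days: np.ndarray
    spike_rate: np.ndarray
    seizures: list[SynthSeizure]
    truth: GroundTruth

    @property
    def onset_days(self) -> np.ndarray:
        return np.array([s.onset_day for s in self.seizures])


def generate_state_library(cfg: SynthConfig) -> np.ndarray:
    """Non-negative basis patterns, one unit-L2 column per state.

    Columns are sparse non-negative mixtures (each state emphasises a random
    subset of band-pair features); any column whose cosine similarity with an
    earlier column reaches 0.9 is redrawn, so states overlap but remain
    distinguishable — mirroring non-orthogonal factorization bases.
    """
    k = cfg.state_library_size
    d = cfg.feature_dim
    if d < k:
        raise ValueError(f"feature_dim {d} < requested library size {k}")
    rng = cfg.rng(_S_LIBRARY)

    def draw() -> np.ndarray:
        col = rng.exponential(1.0, size=d)
        support = rng.random(d) < 0.35            # sparse emphasis
        col = col * np.where(support, 1.0, 0.05)
        return col / np.linalg.norm(col)

    W = np.empty((d, k))
    for j in range(k):
        for _ in range(1000):
            col = draw()
            if j == 0 or np.max(W[:, :j].T @ col) < 0.9:
                break
        else:
            raise RuntimeError("could not draw a sufficiently distinct basis column")
        W[:, j] = col
    return W


def _jittered_phase(rng: np.random.Generator, period: float, jitter: float, n_days: float,
                    dt_days: float) -> np.ndarray:
    """Unwrapped phase advancing 2 pi per drawn oscillation period.

    Successive periods are drawn as period * (1 + U(-jitter, jitter)); the
    phase is the piecewise-linear interpolation through the cumulative
    oscillation boundaries, starting at a random initial phase.
    """
    n_osc = int(np.ceil(n_days / (period * (1 - jitter)))) + 2
    periods = period * (1 + rng.uniform(-jitter, jitter, size=n_osc))
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(0.0, n_days, dt_days)
    phi0 = rng.uniform(-np.pi, np.pi) if jitter > 0 else 0.0
    return phi0 + np.interp(t, bounds, _TWO_PI * np.arange(n_osc + 1))


def generate_spike_rate(
    cfg: SynthConfig,
) -> tuple[np.ndarray, np.ndarray, list[CycleTruth]]:
    """Hourly spike-rate series plus the ground-truth cycle phases.

    rate(t) = baseline + sum_c A_c(t) cos(theta_c(t)) + N(0, spike_noise_sd),
    clipped at zero. Returns (time_days, rate, cycles).
    """
    dt = 1.0 / 24.0
    rng = cfg.rng(_S_RATE)
    t = np.arange(0.0, cfg.recording_days, dt)
    if cfg.multidien_periods and cfg.recording_days < 2 * max(cfg.multidien_periods):
        import warnings

        warnings.warn("recording shorter than twice the longest multidien period")
    cycles: list[CycleTruth] = []
    rate = np.full(t.size, cfg.baseline_rate)
    for period, amp in zip(cfg.periods, cfg.amplitudes):
        theta = _jittered_phase(rng, period, cfg.period_jitter_frac, cfg.recording_days, dt)
        A = np.full(t.size, amp)
        if cfg.amp_mod_frac > 0:
            A = A * (1 + cfg.amp_mod_frac * np.cos(_TWO_PI * t / cfg.amp_mod_period_days))
        rate = rate + A * np.cos(theta)
        cycles.append(CycleTruth(period, theta, A))
    if cfg.spike_noise_sd > 0:
        rate = rate + rng.normal(0.0, cfg.spike_noise_sd, size=t.size)
    return t, np.clip(rate, 0.0, None), cycles


def _sample_onsets(cfg: SynthConfig, cycles: list[CycleTruth]) -> np.ndarray:
    """Seizure onset days: uniform proposals thinned by a von Mises phase weight."""
    rng = cfg.rng(_S_TIMES)
    kappa, mu = cfg.seizure_phase_kappa, cfg.seizure_phase_mu
    cyc = cycles[cfg.timing_cycle]
    margin = min(0.5 * cyc.nominal_period, 0.25 * cfg.recording_days)
    lo, hi = margin, cfg.recording_days - margin
    onsets: list[float] = []
    while len(onsets) < cfg.n_seizures:
        t = rng.uniform(lo, hi, size=4 * cfg.n_seizures)
        if kappa > 0:
            w = np.exp(kappa * (np.cos(cyc.phase_at(t) - mu) - 1.0))
            t = t[rng.random(t.size) < w]
        onsets.extend(t.tolist())
    return np.sort(np.array(onsets[: cfg.n_seizures]))


def _occurrence_probability(
    cfg: SynthConfig, state: int, phases: np.ndarray
) -> np.ndarray | float:
    """P(state included) given the seizure's cycle phases."""
    p = cfg.occurrence_base_prob
    for s, c, kappa, psi0 in cfg.occurrence_mod:
        if s == state:
            if cfg.occurrence_mod_base_prob is not None:
                p = cfg.occurrence_mod_base_prob
            phi = phases[c]
            p = p + cfg.occurrence_mod_amplitude * np.exp(kappa * np.cos(phi - psi0)) / np.exp(kappa)
    return float(np.clip(p, 0.0, 1.0))


def generate_seizures(
    cfg: SynthConfig,
    state_library: np.ndarray,
    cycles: list[CycleTruth],
) -> tuple[list[SynthSeizure], GroundTruth]:
    """Seizures as ordered run-length state sequences with planted modulations."""
    k = cfg.state_library_size
    n_cycles = len(cycles)
    for s, c, _, _ in cfg.occurrence_mod:
        if not (0 <= s < k) or not (0 <= c < n_cycles):
            raise ValueError(f"occurrence_mod refers to nonexistent state/cycle ({s}, {c})")
    for s, c, _ in cfg.duration_mod:
        if not (0 <= s < k) or (c != "time" and not (0 <= c < n_cycles)):
            raise ValueError(f"duration_mod refers to nonexistent state/cycle ({s}, {c})")

    onsets = _sample_onsets(cfg, cycles)
    phases = np.column_stack([c.phase_at(onsets) for c in cycles])
    rng = cfg.rng(_S_COMPOSE)
    rng_feat = cfg.rng(_S_FEATURES)

    seizures: list[SynthSeizure] = []
    for i, t0 in enumerate(onsets):
        phi = phases[i]
        # redraw on an empty composition: conditioning on >= 1 state preserves
        # the phase dependence of each state's inclusion law
        probs = np.array([_occurrence_probability(cfg, s, phi) for s in range(k)])
        for _ in range(200):
            include = rng.random(k) < probs
            if include.any():
                break
        else:
            include = np.zeros(k, dtype=bool)
            include[int(np.argmax(probs))] = True
        order = rng.permutation(np.flatnonzero(include))

        durations: dict[int, int] = {}
        for s in order:
            log_d = rng.normal(cfg.duration_log_mean, cfg.duration_log_sd)
            for ms, mc, eff in cfg.duration_mod:
                if ms == s:
                    if mc == "time":
                        log_d += eff * (t0 / cfg.recording_days - 0.5)
                    else:
                        log_d += 0.5 * eff * np.sin(phi[mc])
            durations[int(s)] = max(1, int(round(np.exp(log_d))))

        seq = np.concatenate([np.full(durations[int(s)], s, dtype=int) for s in order])
        scales = rng_feat.uniform(0.8, 1.2, size=seq.size)
        feats = state_library[:, seq] * scales
        if cfg.window_noise_sd > 0:
            feats = feats + rng_feat.normal(0.0, cfg.window_noise_sd, size=feats.shape)
            feats = np.clip(feats, 0.0, None)
        seizures.append(
            SynthSeizure(
                id=i,
                onset_day=float(t0),
                state_order=order,
                state_sequence=seq,
                durations=durations,
                features=feats,
            )
        )

    truth = GroundTruth(
        true_W=state_library,
        cycles=cycles,
        seizure_phases=phases,
        occurrence_mod=cfg.occurrence_mod,
        duration_mod=cfg.duration_mod,
        state_sequences=[s.state_sequence for s in seizures],
    )
    return seizures, truth


def simulate_cohort(cfg: SynthConfig) -> Cohort:
    """Full cohort: state library, spike rate with cycles, and seizures."""
    W = generate_state_library(cfg)
    t, rate, cycles = generate_spike_rate(cfg)
    seizures, truth = generate_seizures(cfg, W, cycles)
    return Cohort(config=cfg, time_days=t, spike_rate=rate, seizures=seizures, truth=truth)


def render_raw_signals(
    cfg: SynthConfig,
    seizure: SynthSeizure,
    fs: float = 250.0,
    band_edges: Sequence[tuple[float, float]] = ((1, 4), (4, 8), (8, 13), (13, 30), (30, 80), (80, 125)),
    coupling: float = 0.9,
) -> np.ndarray:
    """Optional raw-signal mode: multichannel traces realising a state sequence.

    Each state's basis column is interpreted as target pairwise coupling per
    band; channels share a band-limited common source (weight ~ coupling
    within the state's emphasised features) plus independent noise. Intended
    solely for end-to-end tests of the connectivity stage; the statistics
    modules never consume raw signals.
    """
    from scipy.signal import butter, sosfiltfilt

    rng = cfg.rng(_S_RAW)
    step = int(round(cfg.step_s * fs))
    win = int(round(cfg.window_s * fs))
    n_samp = win + (seizure.n_windows - 1) * step
    n_ch = cfg.n_channels
    out = np.zeros((n_ch, n_samp))
    nyq = fs / 2
    # per-state channel weights: which channels join the common source strongly
    weights = {}
    for s in np.unique(seizure.state_sequence):
        w = rng.uniform(0.2, 1.0, size=n_ch)
        weights[int(s)] = w
    for lo, hi in band_edges:
        hi = min(hi, 0.99 * nyq)
        if lo >= hi:
            continue
        sos = butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
        common = sosfiltfilt(sos, rng.standard_normal(n_samp))
        noise = sosfiltfilt(sos, rng.standard_normal((n_ch, n_samp)), axis=-1)
        # sample-level state labels from the window sequence (window starts step apart)
        labels = np.repeat(seizure.state_sequence, step)[:n_samp]
        if labels.size < n_samp:
            labels = np.concatenate([labels, np.full(n_samp - labels.size, labels[-1])])
        w_t = np.stack([weights[int(s)] for s in labels], axis=1)  # (n_ch, n_samp)
        out += coupling * w_t * common + (1 - coupling) * noise
    return out
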