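"""EMD decomposition, cycle selection, period/phase estimation, phase assignment."""

import numpy as np
import pytest

from seizstate import (
    CycleConfig,
    assign_seizure_phases,
    average_period,
    emd_decompose,
    instantaneous_phase,
    select_prominent,
)
from seizstate.emd import ceemdan, emd
from seizstate.spike_cycles import extract_cycles

HOURS = 1.0 / 24.0


def _days(n_days):
    return np.arange(0.0, n_days, HOURS)


class TestEMD:
    def test_reconstruction_completeness(self, rng):
        t = _days(30)
        x = np.cos(2 * np.pi * t) + 0.5 * np.cos(2 * np.pi * t / 7.0) + rng.normal(0, 0.3, t.size)
        imfs = emd(x)
        resid = x - imfs.sum(axis=0)
        assert np.max(np.abs(imfs.sum(axis=0) + resid - x)) < 1e-6 * np.ptp(x)

    def test_ceemdan_reconstruction_and_determinism(self, rng):
        t = _days(20)
        x = np.cos(2 * np.pi * t) + rng.normal(0, 0.3, t.size)
        a = ceemdan(x, ensemble_size=20, seed=3)
        b = ceemdan(x, ensemble_size=20, seed=3)
        assert np.array_equal(a, b)
        resid = x - a.sum(axis=0)
        assert np.max(np.abs(a.sum(axis=0) + resid - x)) < 1e-9

    def test_pure_cosine_concentrates_in_one_imf(self):
        t = _days(90)
        x = np.cos(2 * np.pi * t / 1.0)
        imfs = emd(x)
        share = np.var(imfs, axis=1) / np.var(x)
        assert share.max() >= 0.90

    def test_two_tone_separation(self):
        t = _days(90)
        x = np.cos(2 * np.pi * t) + np.cos(2 * np.pi * t / 10.6)
        imfs = emd(x)
        periods = []
        for imf in imfs:
            if np.var(imf) > 0.05 * np.var(x):
                periods.append(average_period(imf))
        assert any(abs(p - 1.0) / 1.0 < 0.15 for p in periods)
        assert any(abs(p - 10.6) / 10.6 < 0.15 for p in periods)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            emd(np.ones(500))

    def test_decompose_requires_min_length(self):
        with pytest.raises(ValueError):
            emd_decompose(np.random.default_rng(0).random(50))

    def test_gap_interpolation_and_masking(self):
        t = _days(30)
        x = np.cos(2 * np.pi * t) + 5.0
        x[100:102] = np.nan          # short gap: filled, unmasked
        x[300:310] = np.nan          # long gap: filled but masked
        imfs, mask = emd_decompose(x, CycleConfig(use_ceemdan=False))
        assert not mask[100:102].any()
        assert mask[300:310].all()
        assert np.all(np.isfinite(imfs))


class TestAveragePeriod:
    def test_unit_cosine(self):
        x = np.cos(2 * np.pi * _days(30))
        assert average_period(x) == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("period", [0.5, 1.0, 5.0, 20.0, 60.0])
    def test_unbiased_across_periods(self, period):
        t = _days(max(20 * period, 10))
        x = np.cos(2 * np.pi * t / period)
        assert average_period(x) == pytest.approx(period, rel=0.02)

    def test_chirp_period_within_range(self):
        t = _days(120)
        # period sweeping 8 -> 12 days
        inst_period = 8.0 + 4.0 * t / t[-1]
        phase = np.cumsum(2 * np.pi * HOURS / inst_period)
        x = np.cos(phase)
        assert 8.0 < average_period(x) < 12.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            average_period(np.ones(100))


class TestInstantaneousPhase:
    def test_zero_phase_at_cosine_peaks(self):
        t = _days(60)
        x = np.cos(2 * np.pi * t)
        phi = instantaneous_phase(x)
        peaks = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
        interior = peaks[(peaks > 48) & (peaks < t.size - 48)]
        assert np.all(np.abs(phi[interior]) < 0.05)

    def test_advances_two_pi_per_period(self):
        t = _days(60)
        phi = np.unwrap(instantaneous_phase(np.cos(2 * np.pi * t)))
        assert phi[24 * 30] - phi[24 * 29] == pytest.approx(2 * np.pi, rel=0.02)

    def test_nonfinite_rejected(self):
        x = np.cos(np.linspace(0, 20, 200))
        x[5] = np.inf
        with pytest.raises(ValueError):
            instantaneous_phase(x)


class TestSelectProminent:
    def test_long_period_mode_excluded(self):
        t = _days(90)
        imfs = np.vstack([np.cos(2 * np.pi * t / 1.0), np.cos(2 * np.pi * t / 40.0)])
        cycles = select_prominent(imfs, recording_len_days=90.0)
        assert [c.avg_period for c in cycles] == pytest.approx([1.0], rel=0.02)

    def test_low_power_mode_excluded(self):
        t = _days(90)
        imfs = np.vstack([np.cos(2 * np.pi * t), 0.05 * np.cos(2 * np.pi * t / 10.0)])
        cycles = select_prominent(imfs, recording_len_days=90.0)
        assert len(cycles) == 1 and cycles[0].timescale == "circadian"

    def test_planted_two_cycle_recovery_with_labels(self):
        rng = np.random.default_rng(8)
        t = _days(90)
        x = 30 * np.cos(2 * np.pi * t) + 30 * np.cos(2 * np.pi * t / 10.6) + 100
        x += rng.normal(0, 10, t.size)
        cfg = CycleConfig(ensemble_size=30, emd_seed=1)
        cycles, _ = extract_cycles(x, cfg)
        assert len(cycles) == 2
        by_scale = {c.timescale: c.avg_period for c in cycles}
        assert by_scale["circadian"] == pytest.approx(1.0, rel=0.15)
        assert by_scale["multidien"] == pytest.approx(10.6, rel=0.15)

    def test_near_period_modes_merged(self):
        t = _days(90)
        a = np.cos(2 * np.pi * t / 10.0)
        b = np.cos(2 * np.pi * t / 11.0)
        cycles = select_prominent(np.vstack([a, b]), recording_len_days=90.0)
        assert len(cycles) == 1  # periods differ by < 25%: summed into one cycle


class TestAssignSeizurePhases:
    def _one_cycle(self, n_days=60.0, period=1.0):
        t = _days(n_days)
        imfs = np.cos(2 * np.pi * t / period)[None, :]
        return select_prominent(imfs, n_days)[0]

    def test_seizure_at_peak_gets_zero_phase(self):
        cyc = self._one_cycle()
        sp = assign_seizure_phases([cyc], onset_days=[30.0])  # t=30 d is a peak
        assert sp.valid[0, 0]
        assert abs(sp.phases[0, 0]) < np.pi / 8

    def test_edge_seizures_invalid(self):
        cyc = self._one_cycle(period=10.0, n_days=60.0)
        sp = assign_seizure_phases([cyc], onset_days=[1.0, 30.0, 59.5])
        assert not sp.valid[0, 0] and not sp.valid[2, 0]
        assert sp.valid[1, 0]

    def test_masked_gap_invalid(self):
        cyc = self._one_cycle()
        gap = np.zeros(cyc.samples.size, dtype=bool)
        gap[24 * 30] = True
        sp = assign_seizure_phases([cyc], onset_days=[30.0, 20.0], gap_mask=gap)
        assert not sp.valid[0, 0]
        assert sp.valid[1, 0]

    def test_onset_outside_record_rejected(self):
        cyc = self._one_cycle()
        with pytest.raises(ValueError):
            assign_seizure_phases([cyc], onset_days=[100.0])

    def test_recovered_phases_match_ground_truth(self):
        from seizstate import SynthConfig, generate_spike_rate

        cfg = SynthConfig(
            n_channels=3, n_seizures=10, recording_days=90,
            multidien_periods=(10.6,), period_jitter_frac=0.05,
            spike_noise_sd=8.0, seed=17,
        )
        t, rate, truth_cycles = generate_spike_rate(cfg)
        cycles, gap = extract_cycles(rate, CycleConfig(ensemble_size=30, emd_seed=2))
        assert len(cycles) == 2
        onsets = np.linspace(12.0, 78.0, 40)
        sp = assign_seizure_phases(cycles, onsets, gap_mask=gap)
        # match extracted to planted cycles by period
        for c_idx, cyc in enumerate(cycles):
            tr = min(truth_cycles, key=lambda c: abs(c.nominal_period - cyc.avg_period))
            truth_phi = tr.phase_at(onsets)
            ok = sp.valid[:, c_idx]
            err = np.angle(np.exp(1j * (sp.phases[ok, c_idx] - truth_phi[ok])))
            assert np.mean(np.abs(err) <= np.pi / 8) >= 0.9
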