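import numpy as np
import pytest
from hypothesis import given, strategies as st

import phasetag as pt
from phasetag.coherency import PhaseTable, resultant_length

from conftest import make_trialset, synth_trialset


def _table(phases):
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    freqs = np.linspace(1.0, 15.0, phases.shape[1])
    return PhaseTable(phases=phases, freqs=freqs)


class TestExtractPhases:
    def test_grid_is_71_bins_from_1_to_15(self):
        f = pt.analysis_freqs()
        assert f.size == 71
        assert f[0] == 1.0 and f[-1] == 15.0
        assert np.allclose(np.diff(f), 0.2)

    def test_identical_cosine_trials_share_phase(self):
        fs = 1000.0
        t = np.arange(int(6.5 * fs)) / fs - 1.5
        data = np.tile(np.cos(2 * np.pi * 4.2 * t), (5, 1))
        ts = make_trialset(data, fs, onset=int(1.5 * fs))
        tab = pt.extract_phases(ts)
        j = np.argmin(np.abs(tab.freqs - 4.2))
        assert np.ptp(tab.phases[:, j]) < 1e-12

    def test_phase_offset_is_linear(self):
        fs, phi0 = 1000.0, 0.8
        t = np.arange(int(6 * fs)) / fs - 1.0
        data = np.stack(
            [np.cos(2 * np.pi * 4.2 * t), np.cos(2 * np.pi * 4.2 * t + phi0)]
        )
        ts = make_trialset(data, fs, onset=int(1.0 * fs))
        tab = pt.extract_phases(ts)
        j = np.argmin(np.abs(tab.freqs - 4.2))
        dphi = np.angle(np.exp(1j * (tab.phases[1, j] - tab.phases[0, j])))
        assert dphi == pytest.approx(phi0, abs=1e-9)

    def test_short_trials_rejected(self):
        ts = make_trialset(np.zeros((3, 3000)), fs=1000.0, onset=1000)
        with pytest.raises(ValueError, match="after onset"):
            pt.extract_phases(ts, window=5.0)


class TestCoherencyEstimators:
    def test_equal_phases_give_exactly_one(self):
        spec = pt.coherency(_table(np.full((10, 4), 0.7)))
        assert np.all(spec.values == pytest.approx(1.0, abs=1e-12))

    def test_uniformly_spaced_phases_give_zero(self):
        n = 8
        phases = np.tile(2 * np.pi * np.arange(n)[:, None] / n, (1, 3))
        spec = pt.coherency(_table(phases))
        assert np.all(spec.values < 1e-12)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pt.coherency(_table(np.zeros((1, 3))))

    def test_amplitude_invariance(self, schedule_fast):
        """Scaling any trial by a positive constant cannot move the spectrum."""
        ts = synth_trialset(
            20, schedule_fast, pt.correlated_like_response(),
            pt.NoiseModel(target_time_snr=0.5), seed=4,
        )
        scaled = ts.copy()
        scaled.data *= np.random.default_rng(0).uniform(0.1, 50.0, (ts.n_trials, 1))
        s0 = pt.coherency(pt.extract_phases(ts))
        s1 = pt.coherency(pt.extract_phases(scaled))
        np.testing.assert_allclose(s1.values, s0.values, atol=1e-12)

    def test_ci_fraction_bounds_and_perfect_lock(self):
        tab = _table(np.full((30, 3), -1.2))
        spec = pt.coherency(tab, estimator="ci_fraction")
        assert np.all(spec.values == pytest.approx(1.0, abs=1e-12))
        rng = np.random.default_rng(1)
        spec = pt.coherency(
            _table(rng.uniform(-np.pi, np.pi, (200, 5))), estimator="ci_fraction"
        )
        assert np.all((spec.values >= 0) & (spec.values <= 1))

    @given(
        st.integers(2, 40).flatmap(
            lambda n: st.lists(
                st.floats(-np.pi, np.pi, allow_nan=False), min_size=n, max_size=n
            )
        )
    )
    def test_resultant_length_bounded_and_one_iff_equal(self, phases):
        phases = np.asarray(phases)
        r = float(resultant_length(phases[:, None])[0])
        assert -1e-12 <= r <= 1 + 1e-12
        if np.ptp(phases) == 0:
            assert r == pytest.approx(1.0, abs=1e-12)
        elif np.ptp(np.angle(np.exp(1j * (phases - phases[0])))) > 1e-6:
            assert r < 1.0


class TestNullThreshold:
    def test_brute_force_oracle_matches_closed_form_at_134_trials(self):
        """95th pct of the uniform-phase resultant ~ sqrt(ln 20 / n)."""
        rng = np.random.default_rng(7)
        phases = rng.uniform(-np.pi, np.pi, (20_000, 134))
        oracle = np.percentile(resultant_length(phases, axis=1), 95)
        assert oracle == pytest.approx(np.sqrt(np.log(20) / 134), abs=0.004)
        assert oracle == pytest.approx(0.15, abs=0.01)

    def test_fast_path_matches_closed_form(self):
        for n in (50, 134, 534):
            nt = pt.null_threshold(n, B=3000, freqs=[4.2], seed=n)
            assert nt.thresholds[0] == pytest.approx(
                pt.rayleigh_threshold(n), abs=0.006
            )

    def test_timeseries_and_phase_paths_agree(self):
        f = [2.0, 4.2, 10.0]
        a = pt.null_threshold(50, B=400, freqs=f, seed=1, method="phase")
        b = pt.null_threshold(50, B=400, freqs=f, seed=2, method="timeseries", fs=250.0)
        # 2x Monte-Carlo standard error of a 95th percentile at B=400 ~ 0.012
        np.testing.assert_allclose(a.thresholds, b.thresholds, atol=0.025)

    def test_threshold_decreases_with_trial_count(self):
        t134 = pt.null_threshold(134, B=2000, freqs=[4.2], seed=0).thresholds[0]
        t534 = pt.null_threshold(534, B=2000, freqs=[4.2], seed=0).thresholds[0]
        assert t534 < t134

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            pt.null_threshold(1, B=500)
        with pytest.raises(ValueError):
            pt.null_threshold(50, B=50)


class TestDetectHarmonics:
    def _detection(self, seed=0, n=140):
        ts = synth_trialset(
            n, pt.StimulusSchedule(),
            pt.ResponseModel(harmonic_amps=(0.0, 1.0, 0.0, 0.5), phase_jitter_sd=1.5),
            pt.NoiseModel(target_time_snr=0.5), seed=seed,
        )
        spec = pt.coherency(pt.extract_phases(ts))
        null = pt.null_threshold(n, B=1000, seed=seed + 1)
        return spec, null

    def test_driven_even_harmonics_detected_with_small_p(self):
        spec, null = self._detection()
        det = pt.detect_harmonics(spec, null, 2.1)
        assert {2, 4} <= set(det.detected_harmonics)
        tab = det.table.set_index("harmonic")
        assert (tab.loc[[2, 4], "p_value"] < 0.05).all()

    def test_detected_iff_above_threshold(self):
        spec, null = self._detection(seed=3)
        det = pt.detect_harmonics(spec, null, 2.1)
        assert (
            det.table["detected"] == (det.table["coherency"] > det.table["threshold"])
        ).all()

    def test_half_bin_ties_resolve_to_lower_bin_with_offset(self):
        spec, null = self._detection(seed=5)
        det = pt.detect_harmonics(spec, null, 2.1)
        tab = det.table.set_index("harmonic")
        assert tab.loc[1, "bin_hz"] == pytest.approx(2.0)
        assert tab.loc[1, "offset_hz"] == pytest.approx(-0.1)
        assert tab.loc[2, "bin_hz"] == pytest.approx(4.2)  # even harmonics on-grid

    def test_exact_mode_evaluates_off_grid_harmonics(self):
        ts = synth_trialset(
            30, pt.StimulusSchedule(),
            pt.ResponseModel(harmonic_amps=(1.0,), phase_jitter_sd=0.0),
            pt.NoiseModel(white_sd=0.0, pink_sd=0.0, mains_amp=0.0), seed=0,
        )
        spec = pt.coherency(pt.extract_phases(ts))
        null = pt.null_threshold(30, B=500, seed=9)
        det = pt.detect_harmonics(spec, null, 2.1, mode="exact", trialset=ts)
        tab = det.table.set_index("harmonic")
        assert tab.loc[1, "bin_hz"] == pytest.approx(2.1)
        assert tab.loc[1, "coherency"] == pytest.approx(1.0, abs=1e-9)

    def test_harmonic_beyond_analysis_range_rejected(self):
        spec, null = self._detection(seed=6)
        with pytest.raises(ValueError, match="above the analysis range"):
            pt.detect_harmonics(spec, null, 2.1, K=8)

    def test_false_positive_rate_near_nominal_on_pure_noise(self):
        """At the 95th-percentile threshold ~5% of noise bins exceed it."""
        rng = np.random.default_rng(11)
        thr = pt.rayleigh_threshold(134)
        exceed = []
        for _ in range(50):
            r = resultant_length(rng.uniform(-np.pi, np.pi, (134, 71)))
            exceed.append(np.mean(r > thr))
        rate = np.mean(exceed)
        assert rate == pytest.approx(0.05, abs=0.015)


class TestPoolingAndSnr:
    def test_pooled_counts(self, schedule_fast, quiet_noise):
        resp = pt.ResponseModel(harmonic_amps=(0.0, 1.0))
        sets = [
            synth_trialset(134, schedule_fast, resp, pt.NoiseModel(), seed=i)
            for i in range(4)
        ]
        pooled = pt.pool_trials(sets)
        assert pooled.n_trials == 536

    def test_mismatched_sampling_rates_rejected(self, schedule, schedule_fast, quiet_noise):
        resp = pt.ResponseModel(harmonic_amps=(0.0, 1.0))
        a = synth_trialset(3, schedule, resp, quiet_noise, seed=0)
        b = synth_trialset(3, schedule_fast, resp, quiet_noise, seed=0)
        with pytest.raises(ValueError, match="sampling rates"):
            pt.pool_trials([a, b])

    def test_pooling_identical_participants_matches_within_participant(self, schedule_fast):
        resp = pt.ResponseModel(harmonic_amps=(0.0, 1.0), phase_jitter_sd=1.5)
        noise = pt.NoiseModel(target_time_snr=0.5)
        sets = [synth_trialset(80, schedule_fast, resp, noise, seed=i) for i in range(4)]
        pooled = pt.pool_trials(sets)
        c_pool = pt.coherency(pt.extract_phases(pooled)).at(4.2)
        c_each = [pt.coherency(pt.extract_phases(s)).at(4.2) for s in sets]
        # identical latency: pooled value sits inside the per-set spread
        assert min(c_each) - 0.05 <= c_pool <= max(c_each) + 0.05

    def test_coherency_snr_values(self):
        assert pt.coherency_snr(0.29, 0.08) == pytest.approx(3.625)
        assert pt.coherency_snr(0.15, 0.15) == pytest.approx(1.0)
        assert pt.coherency_snr(0.34, 0.15) == pytest.approx(2.2667, abs=1e-3)
        with pytest.raises(ValueError):
            pt.coherency_snr(0.3, 0.0)
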