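import numpy as np
import pytest

import phasetag as pt
from phasetag._dsp import bin_coefficient
from phasetag.synth import simulate_trials

from conftest import make_trialset, synth_trialset


class TestSquareWave:
    def test_toggles_between_disparity_levels_with_correct_period(self, schedule):
        w = pt.square_wave_disparity(schedule, pre_duration=1.0, stim_duration=5.0)
        pre = int(1.0 * schedule.fs)
        assert np.all(w[:pre] == 0.0)
        stim = w[pre:]
        assert set(np.unique(stim)) == {-0.05, 0.05}
        # 2.1 Hz square wave: two sign flips per period
        flips = np.sum(np.diff(np.sign(stim)) != 0)
        assert flips == pytest.approx(2 * 2.1 * 5.0, abs=1)

    def test_half_duty_has_even_harmonics_zero_and_odd_decreasing(self, schedule):
        # 10 s = 21 whole periods, so k*2.1 Hz sits exactly on the FFT grid
        w = pt.square_wave_disparity(schedule, pre_duration=0.0, stim_duration=10.0)
        mags = np.array(
            [np.abs(bin_coefficient(w, schedule.fs, k * 2.1)) for k in range(1, 9)]
        )
        assert np.all(mags[1::2] < 1e-12)  # even harmonics vanish
        odd = mags[0::2]
        assert np.all(np.diff(odd) < 0)  # strictly decreasing odd magnitudes

    def test_zero_amplitude_gives_zero_waveform(self):
        sch = pt.StimulusSchedule(disparity_amp=0.0)
        w = pt.square_wave_disparity(sch, pre_duration=1.0, stim_duration=5.0)
        assert np.all(w == 0.0)

    @pytest.mark.parametrize("duty", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_duty_rejected(self, duty):
        with pytest.raises(ValueError):
            pt.StimulusSchedule(duty=duty)

    def test_unresolvable_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            pt.StimulusSchedule(f0=2.1, fs=8.0)  # fewer than 4 samples/period


class TestGenerateTrial:
    def test_identical_seed_gives_identical_trial(self, schedule_fast):
        resp = pt.correlated_like_response()
        noise = pt.NoiseModel()
        t1 = pt.generate_trial(schedule_fast, resp, noise, seed=42)
        t2 = pt.generate_trial(schedule_fast, resp, noise, seed=42)
        np.testing.assert_array_equal(t1.samples, t2.samples)
        assert t1.onset_index == t2.onset_index

    def test_onset_and_duration_invariants(self, schedule_fast):
        t = pt.generate_trial(
            schedule_fast, pt.correlated_like_response(), pt.NoiseModel(), seed=0
        )
        assert t.pre_duration >= 1.0 - 1e-9
        assert t.post_duration >= 5.0 - 1e-9

    def test_harmonic_above_nyquist_rejected(self, schedule_fast):
        resp = pt.ResponseModel(harmonic_amps=tuple([0.0] * 59 + [1.0]))  # 60*2.1 Hz
        with pytest.raises(ValueError, match="Nyquist"):
            pt.generate_trial(schedule_fast, resp, pt.NoiseModel(), seed=0)

    def test_noiseless_zero_jitter_trials_are_phase_identical(self, schedule, quiet_noise):
        resp = pt.ResponseModel(
            harmonic_amps=(0.0, 1.0, 0.0, 0.5, 0.0, 0.25), phase_jitter_sd=0.0
        )
        ts = synth_trialset(8, schedule, resp, quiet_noise, seed=3)
        spec = pt.coherency(pt.extract_phases(ts))
        for f in (4.2, 8.4, 12.6):
            assert spec.at(f) == pytest.approx(1.0, abs=1e-9)


class TestSnrTargeting:
    def test_broadband_snr_within_five_percent_over_100_trials(self, schedule_fast):
        noise = pt.NoiseModel(target_time_snr=0.5)
        data, onset, resp, noi = simulate_trials(
            120, schedule_fast, pt.correlated_like_response(), noise,
            rng=1, return_parts=True,
        )
        w = slice(onset, onset + int(5.0 * schedule_fast.fs))
        realized = np.mean(resp[:, w] ** 2) / np.mean(noi[:, w] ** 2)
        assert realized == pytest.approx(0.5, rel=0.05)

    def test_bin_referenced_snr_realized_at_driven_harmonic(self, schedule_fast):
        noise = pt.NoiseModel(target_time_snr=0.5, snr_reference="bin", mains_amp=0.0)
        resp_model = pt.ResponseModel(harmonic_amps=(0.0, 1.0))
        data, onset, resp, noi = simulate_trials(
            200, schedule_fast, resp_model, noise, rng=2, return_parts=True
        )
        w = slice(onset, onset + int(5.0 * schedule_fast.fs))
        f = 2 * schedule_fast.f0
        p_sig = np.mean(np.abs(bin_coefficient(resp[:, w], schedule_fast.fs, f)) ** 2)
        p_noise = np.mean(np.abs(bin_coefficient(noi[:, w], schedule_fast.fs, f)) ** 2)
        assert p_sig / p_noise == pytest.approx(0.5, rel=0.1)

    def test_snr_target_requires_a_response(self, schedule_fast):
        with pytest.raises(ValueError, match="zero response"):
            simulate_trials(
                4, schedule_fast, pt.ResponseModel(harmonic_amps=(0.0,)),
                pt.NoiseModel(target_time_snr=0.5), rng=0,
            )


class TestBandPerturbation:
    def test_band_scaling_is_exact_and_post_onset_only(self, schedule_fast):
        """The perturbation is, by construction, the trial's own in-band
        noise scaled by 10^(dB/20) from onset onward and nothing else."""
        from phasetag._dsp import band_component

        args = (
            schedule_fast, pt.ResponseModel(harmonic_amps=(0.0,)),
            pt.NoiseModel(mains_amp=0.0),
        )
        pert = (pt.BandPerturbation(band=(8.0, 12.0), delta_db=1.0),)
        plain, onset, _, n_plain = simulate_trials(
            20, *args, (), rng=5, return_parts=True
        )
        _, _, _, n_pert = simulate_trials(20, *args, pert, rng=5, return_parts=True)
        comp = band_component(n_plain, schedule_fast.fs, 8.0, 12.0)
        gain = 10 ** (1.0 / 20.0)
        step = (np.arange(n_plain.shape[1]) >= onset).astype(float)
        np.testing.assert_allclose(
            n_pert, n_plain + (gain - 1.0) * comp * step, atol=1e-10
        )

    def test_realized_band_power_change_matches_delta_db(self, schedule_fast):
        from scipy.signal import periodogram

        pert = (pt.BandPerturbation(band=(8.0, 12.0), delta_db=1.0),)
        data, onset = simulate_trials(
            400, schedule_fast, pt.ResponseModel(harmonic_amps=(0.0,)),
            pt.NoiseModel(mains_amp=0.0), pert, rng=6,
        )
        fs = schedule_fast.fs
        n1s = int(fs)  # matched 1 s windows away from onset and trial edges
        f, p_pre = periodogram(data[:, onset - n1s : onset], fs, window="hann")
        f, p_post = periodogram(data[:, onset + n1s : onset + 2 * n1s], fs, window="hann")
        sel = (f >= 8.5) & (f <= 11.5)
        change = 10 * np.log10(p_post[:, sel].mean() / p_pre[:, sel].mean())
        assert change == pytest.approx(1.0, abs=0.35)

    def test_incoherent_perturbation_stays_below_noise_threshold(self, schedule_fast):
        pert = (pt.BandPerturbation(band=(8.0, 12.0), delta_db=1.0),)
        ts = synth_trialset(
            200, schedule_fast, pt.ResponseModel(harmonic_amps=(0.0,)),
            pt.NoiseModel(mains_amp=0.0), pert, seed=6,
        )
        spec = pt.coherency(pt.extract_phases(ts))
        thr = pt.rayleigh_threshold(200)
        in_band = (spec.freqs >= 8.0) & (spec.freqs <= 12.0)
        # a non-phase-locked power change must look like noise in phase space
        assert np.mean(spec.values[in_band] > thr) <= 2 / in_band.sum()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            pt.BandPerturbation(band=(12.0, 8.0), delta_db=1.0)


class TestGenerateDataset:
    def test_pooled_bookkeeping(self, schedule_fast, quiet_noise):
        sets = pt.generate_dataset(
            schedule_fast, pt.ResponseModel(harmonic_amps=(0.0, 1.0)), quiet_noise,
            n_participants=4, trials_per_condition=134, seed=0,
        )
        pooled = pt.pool_trials(sets)
        assert pooled.n_trials == 536
        assert len(set(pooled.participant_ids)) == 4

    def test_latency_spread_penalises_high_harmonics_more(self, schedule, quiet_noise):
        resp = pt.ResponseModel(
            harmonic_amps=(0.0, 1.0, 0.0, 0.0, 0.0, 1.0), phase_jitter_sd=0.0
        )
        lat = np.array([-0.02, -0.007, 0.007, 0.02])

        def pooled_coh(latencies):
            sets = pt.generate_dataset(
                schedule, resp, quiet_noise, n_participants=4,
                trials_per_condition=5, participant_latencies=latencies, seed=1,
            )
            spec = pt.coherency(pt.extract_phases(pt.pool_trials(sets)))
            return spec.at(4.2), spec.at(12.6)

        c2_0, c6_0 = pooled_coh(np.zeros(4))
        c2_s, c6_s = pooled_coh(lat)
        assert c2_0 == pytest.approx(1.0, abs=1e-9)
        assert c6_0 == pytest.approx(1.0, abs=1e-9)
        # the 20 ms spread costs far more coherency at 12.6 Hz than at 4.2 Hz
        assert (c6_0 - c6_s) > (c2_0 - c2_s)
        assert c2_s > 0.8 > c6_s


class TestInjectArtifact:
    def test_blink_exceeds_rejection_amplitude(self, schedule_fast):
        t = pt.generate_trial(
            schedule_fast, pt.ResponseModel(harmonic_amps=(0.0,)), pt.NoiseModel(), seed=0
        )
        bad = pt.inject_artifact(t, "blink", seed=1, blink_amp=300.0)
        assert np.ptp(bad.samples) > 200.0
        assert bad.good_flag  # flagging is preprocess's job

    def test_injection_does_not_mutate_the_input(self, schedule_fast):
        t = pt.generate_trial(
            schedule_fast, pt.ResponseModel(harmonic_amps=(0.0,)), pt.NoiseModel(), seed=0
        )
        before = t.samples.copy()
        pt.inject_artifact(t, "noisy", seed=1)
        np.testing.assert_array_equal(t.samples, before)

    def test_unknown_kind_rejected(self, schedule_fast):
        t = pt.generate_trial(
            schedule_fast, pt.ResponseModel(harmonic_amps=(0.0,)), pt.NoiseModel(), seed=0
        )
        with pytest.raises(ValueError, match="unknown artifact"):
            pt.inject_artifact(t, "cough", seed=1)
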