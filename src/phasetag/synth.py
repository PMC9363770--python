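"""Synthetic single-channel SSVEP trial generator.

Emulates a frequency-tagged stereogram experiment: each trial starts with a
1-1.5 s zero-disparity pre-period, then a depth plane alternates as a 50%
duty-cycle square wave at ``f0`` (default 2.1 Hz) for 5-6 s.  The simulated
neural response is phase-locked to stimulus onset and carried on harmonics of
``f0``; noise is a mixture of white, 1/f^gamma and mains components; optional
band-power perturbations emulate induced (non-phase-locked) oscillations.

Every stochastic operation takes an explicit seed or ``numpy.random.Generator``
and is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._dsp import band_component, bin_coefficient, pink_spectrum_shape, shaped_noise
from .trialset import Trial, TrialSet

CORRELATED = "correlated-like"
ANTICORRELATED = "anticorrelated-like"


# ----------------------------------------------------------------------
# parameter objects
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class StimulusSchedule:
    """Timing and geometry of the depth-alternation stimulus.

    f0 : alternation frequency in Hz.
    duty : fraction of each period spent at +disparity_amp.
    disparity_amp : disparity magnitude in degrees; the plane toggles
        between +amp and -amp.
    pre_range / stim_range : bounds (s) of the uniformly drawn zero-disparity
        pre-period and of the modulated stimulus period.
    fs : sampling rate in samples/s.
    """

    f0: float = 2.1
    duty: float = 0.5
    disparity_amp: float = 0.05
    pre_range: tuple[float, float] = (1.0, 1.5)
    stim_range: tuple[float, float] = (5.0, 6.0)
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not 0 < self.duty < 1:
            raise ValueError("duty must lie strictly between 0 and 1")
        if self.fs < 4 * self.f0:
            raise ValueError("fs resolves fewer than 4 samples per period")
        for name, (lo, hi) in (("pre_range", self.pre_range), ("stim_range", self.stim_range)):
            if not 0 < lo <= hi:
                raise ValueError(f"invalid {name}: {(lo, hi)}")


@dataclass(frozen=True)
class ResponseModel:
    """Phase-locked response carried on harmonics of the tag frequency.

    harmonic_amps[k-1] is the amplitude (uV) of harmonic k of f0;
    harmonic_phases are the corresponding onset-locked phases in radians.
    ``phase_jitter_sd`` is a per-trial zero-mean phase jitter (radians)
    common to every harmonic; ``latency`` is a propagation delay in seconds
    (a participant-level constant, so it shifts phase by 2 pi k f0 latency
    at harmonic k).
    """

    harmonic_amps: tuple[float, ...] = (0.0, 1.0, 0.0, 0.5, 0.0, 0.25)
    harmonic_phases: tuple[float, ...] | None = None
    phase_jitter_sd: float = 0.0
    latency: float = 0.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.harmonic_amps):
            raise ValueError("harmonic amplitudes must be non-negative")
        if self.harmonic_phases is not None and len(self.harmonic_phases) != len(
            self.harmonic_amps
        ):
            raise ValueError("harmonic_phases length must match harmonic_amps")
        if self.phase_jitter_sd < 0:
            raise ValueError("phase_jitter_sd must be non-negative")

    @property
    def phases(self) -> tuple[float, ...]:
        if self.harmonic_phases is None:
            return tuple(0.0 for _ in self.harmonic_amps)
        return self.harmonic_phases

    @property
    def max_harmonic(self) -> int:
        nz = [k + 1 for k, a in enumerate(self.harmonic_amps) if a > 0]
        return max(nz) if nz else 0

    @property
    def dominant_harmonic(self) -> int:
        if self.max_harmonic == 0:
            return 0
        return int(np.argmax(self.harmonic_amps)) + 1


def correlated_like_response(phase_jitter_sd: float = 1.5) -> ResponseModel:
    """Even-harmonic response typical of a correlated-stereogram condition.

    The default jitter makes the asymptotic inter-trial coherency
    exp(-sd^2/2) ~ 0.32 at the dominant (second) harmonic, the scale seen in
    human recordings of this paradigm.
    """
    return ResponseModel(
        harmonic_amps=(0.0, 1.0, 0.0, 0.5, 0.0, 0.25),
        phase_jitter_sd=phase_jitter_sd,
    )


def anticorrelated_like_response(phase_jitter_sd: float = 1.8) -> ResponseModel:
    """Weak first-harmonic response typical of an anticorrelated condition."""
    return ResponseModel(harmonic_amps=(1.0,), phase_jitter_sd=phase_jitter_sd)


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise: white + 1/f^gamma + mains interference.

    When ``target_time_snr`` is set the generator rescales so that the ratio
    of mean response power to mean noise power over the 5 s analysis window
    equals the target.  ``snr_reference`` selects what "noise power" means:

    - ``"broadband"``: total noise power in the window (the raw-recording
      SNR; noise is rescaled).
    - ``"bin"``: noise power inside the 0.2 Hz analysis bin at the dominant
      harmonic (the detection-theoretic SNR; the response is rescaled).
    """

    white_sd: float = 1.0
    pink_sd: float = 1.0
    pink_exponent: float = 1.0
    mains_freq: float = 50.0
    mains_amp: float = 0.3
    target_time_snr: float | None = None
    snr_reference: str = "broadband"

    def __post_init__(self) -> None:
        if min(self.white_sd, self.pink_sd, self.mains_amp) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.target_time_snr is not None and self.target_time_snr <= 0:
            raise ValueError("target_time_snr must be positive")
        if self.snr_reference not in ("broadband", "bin"):
            raise ValueError("snr_reference must be 'broadband' or 'bin'")


@dataclass(frozen=True)
class BandPerturbation:
    """A band-power change applied from stimulus onset onward.

    ``delta_db`` rescales the [f_lo, f_hi] Hz component of the noise after
    onset by 10**(delta_db/20) in amplitude, i.e. the band power changes by
    exactly ``delta_db`` dB relative to the pre-period.  With the default
    ``phase_locked=False`` the perturbed component is each trial's own noise,
    so its phase stays uniform across trials (an induced, incoherent
    oscillation).
    """

    band: tuple[float, float]
    delta_db: float
    phase_locked: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 <= f_lo < f_hi")


# ----------------------------------------------------------------------
# waveforms
# ----------------------------------------------------------------------
def square_wave_disparity(
    schedule: StimulusSchedule,
    pre_duration: float | None = None,
    stim_duration: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Disparity waveform (degrees per sample) for one trial.

    Zero during the pre-period, then +amp for the first ``duty`` fraction of
    each period and -amp for the rest.  Durations are drawn uniformly from
    the schedule's ranges when not given.
    """
    rng = np.random.default_rng(rng)
    if pre_duration is None:
        pre_duration = rng.uniform(*schedule.pre_range)
    if stim_duration is None:
        stim_duration = rng.uniform(*schedule.stim_range)
    n_pre = int(round(pre_duration * schedule.fs))
    n_stim = int(round(stim_duration * schedule.fs))
    t = np.arange(n_stim) / schedule.fs
    phase = (t * schedule.f0) % 1.0
    wave = np.where(phase < schedule.duty, schedule.disparity_amp, -schedule.disparity_amp)
    return np.concatenate([np.zeros(n_pre), wave])


# ----------------------------------------------------------------------
# trial synthesis
# ----------------------------------------------------------------------
def _response_matrix(
    t: np.ndarray,
    schedule: StimulusSchedule,
    response: ResponseModel,
    jitters: np.ndarray,
) -> np.ndarray:
    """Phase-locked response for each trial; rows differ only by jitter."""
    out = np.zeros((jitters.size, t.size))
    active = t >= 0
    ta = t[active]
    for k, (amp, phi) in enumerate(zip(response.harmonic_amps, response.phases), start=1):
        if amp == 0:
            continue
        f = k * schedule.f0
        base = 2 * np.pi * f * (ta - response.latency) + phi
        out[:, active] += amp * np.cos(base[None, :] + jitters[:, None])
    return out


def _noise_matrix(
    n_trials: int,
    n_samples: int,
    t: np.ndarray,
    fs: float,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.zeros((n_trials, n_samples))
    if noise.white_sd > 0:
        out += rng.normal(0.0, noise.white_sd, (n_trials, n_samples))
    if noise.pink_sd > 0:
        shape = pink_spectrum_shape(n_samples, fs, noise.pink_exponent)
        out += shaped_noise(rng, n_trials, n_samples, shape, noise.pink_sd)
    if noise.mains_amp > 0 and noise.mains_freq < fs / 2:
        # mains is not locked to trial onsets: random phase per trial
        theta = rng.uniform(0, 2 * np.pi, n_trials)
        out += noise.mains_amp * np.sin(
            2 * np.pi * noise.mains_freq * t[None, :] + theta[:, None]
        )
    return out


def _apply_perturbations(
    noise_mat: np.ndarray,
    t: np.ndarray,
    fs: float,
    perturbations: tuple[BandPerturbation, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    if not perturbations:
        return noise_mat
    out = noise_mat.copy()
    post = t >= 0
    for p in perturbations:
        gain = 10 ** (p.delta_db / 20.0)
        if not p.phase_locked:
            comp = band_component(noise_mat, fs, *p.band)
            out[:, post] += (gain - 1.0) * comp[:, post]
        else:
            if p.delta_db <= 0:
                raise ValueError("phase-locked perturbations require delta_db > 0")
            # one shared band-limited trace, identical phase in every trial
            shape = np.where(
                (np.fft.rfftfreq(t.size, 1 / fs) >= p.band[0])
                & (np.fft.rfftfreq(t.size, 1 / fs) <= p.band[1]),
                1.0,
                0.0,
            )
            base_power = np.mean(band_component(noise_mat, fs, *p.band)[:, post] ** 2)
            add_sd = np.sqrt((gain**2 - 1.0) * base_power)
            shared = shaped_noise(rng, 1, t.size, shape, add_sd)[0]
            out[:, post] += shared[post]
    return out


def simulate_trials(
    n_trials: int,
    schedule: StimulusSchedule,
    response: ResponseModel,
    noise: NoiseModel,
    perturbations: tuple[BandPerturbation, ...] = (),
    rng: np.random.Generator | int | None = None,
    latency_offset: float = 0.0,
    analysis_window: float = 5.0,
    return_parts: bool = False,
):
    """Generate a rectangular block of trials.

    Returns ``(data, onset_index)`` or, with ``return_parts``,
    ``(data, onset_index, response_part, noise_part)`` so tests can measure
    realised SNR directly.  Trial durations are drawn per trial from the
    schedule and the block is trimmed to the common window around onset.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng)
    if response.max_harmonic * schedule.f0 >= schedule.fs / 2:
        raise ValueError("highest response harmonic is at or above Nyquist")

    pre = rng.uniform(*schedule.pre_range, n_trials)
    stim = rng.uniform(*schedule.stim_range, n_trials)
    onset = int(math.floor(pre.min() * schedule.fs))
    n_post = int(math.floor(stim.min() * schedule.fs))
    n_samples = onset + n_post
    t = (np.arange(n_samples) - onset) / schedule.fs

    resp = replace(response, latency=response.latency + latency_offset)
    jitters = rng.normal(0.0, resp.phase_jitter_sd, n_trials)
    resp_mat = _response_matrix(t, schedule, resp, jitters)
    noise_mat = _noise_matrix(n_trials, n_samples, t, schedule.fs, noise, rng)

    n_win = int(round(analysis_window * schedule.fs))
    win = slice(onset, min(onset + n_win, n_samples))
    if noise.target_time_snr is not None:
        if resp.max_harmonic == 0:
            raise ValueError("cannot target an SNR with a zero response")
        p_resp = float(np.mean(resp_mat[:, win] ** 2))
        if noise.snr_reference == "broadband":
            p_noise = float(np.mean(noise_mat[:, win] ** 2))
            noise_mat *= np.sqrt(p_resp / (noise.target_time_snr * p_noise))
        else:  # "bin": reference noise power within the analysis bin
            f = resp.dominant_harmonic * schedule.f0
            p_bin = float(np.mean(np.abs(bin_coefficient(noise_mat[:, win], schedule.fs, f)) ** 2))
            p_sig = float(np.mean(np.abs(bin_coefficient(resp_mat[:, win], schedule.fs, f)) ** 2))
            resp_mat *= np.sqrt(noise.target_time_snr * p_bin / p_sig)

    noise_mat = _apply_perturbations(noise_mat, t, schedule.fs, perturbations, rng)
    data = resp_mat + noise_mat
    if return_parts:
        return data, onset, resp_mat, noise_mat
    return data, onset


def generate_trial(
    schedule: StimulusSchedule,
    response: ResponseModel,
    noise: NoiseModel,
    perturbations: tuple[BandPerturbation, ...] = (),
    seed: np.random.Generator | int | None = None,
    condition: str = "",
    participant_id: str = "",
) -> Trial:
    """One synthetic trial; identical seed gives an identical trial."""
    data, onset = simulate_trials(
        1, schedule, response, noise, perturbations, rng=seed
    )
    return Trial(
        samples=data[0],
        fs=schedule.fs,
        onset_index=onset,
        condition=condition,
        participant_id=participant_id,
    )


def generate_dataset(
    schedule: StimulusSchedule,
    responses: ResponseModel | dict[str, ResponseModel],
    noise: NoiseModel,
    n_participants: int = 4,
    trials_per_condition: int = 134,
    latency_spread: float = 0.0,
    participant_latencies: np.ndarray | None = None,
    perturbations: tuple[BandPerturbation, ...] = (),
    seed: np.random.Generator | int | None = None,
) -> list[TrialSet]:
    """One TrialSet per participant x condition.

    Per-participant latency offsets are drawn from N(0, latency_spread) (or
    given explicitly), emulating individual signal-propagation delays; they
    shift response phase proportionally to harmonic frequency, which is what
    penalises trial-level pooling at high harmonics.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(responses, ResponseModel):
        responses = {CORRELATED: responses}
    if participant_latencies is None:
        participant_latencies = rng.normal(0.0, latency_spread, n_participants)
    else:
        participant_latencies = np.asarray(participant_latencies, dtype=float)
        if participant_latencies.size != n_participants:
            raise ValueError("participant_latencies length mismatch")

    out = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        for cond, resp in responses.items():
            data, onset = simulate_trials(
                trials_per_condition,
                schedule,
                resp,
                noise,
                perturbations,
                rng=rng.spawn(1)[0],
                latency_offset=float(participant_latencies[p]),
            )
            out.append(
                TrialSet(
                    data=data,
                    fs=schedule.fs,
                    onset_index=onset,
                    conditions=np.full(trials_per_condition, cond),
                    participant_ids=np.full(trials_per_condition, pid),
                    good_flags=np.ones(trials_per_condition, bool),
                    meta={
                        "f0": schedule.f0,
                        "latency_offset_s": float(participant_latencies[p]),
                        "noise": {
                            "white_sd": noise.white_sd,
                            "pink_sd": noise.pink_sd,
                            "pink_exponent": noise.pink_exponent,
                            "mains_amp": noise.mains_amp,
                            "target_time_snr": noise.target_time_snr,
                            "snr_reference": noise.snr_reference,
                        },
                    },
                )
            )
    return out


def inject_artifact(
    trial: Trial,
    kind: str,
    seed: np.random.Generator | int | None = None,
    blink_amp: float = 300.0,
    blink_width: float = 0.15,
    noise_factor: float = 3.0,
) -> Trial:
    """Contaminate a trial with a blink-like transient or broadband noise.

    The returned trial's ``good_flag`` is untouched; deciding what to reject
    is the preprocessing stage's job.
    """
    rng = np.random.default_rng(seed)
    out = trial.copy()
    n = out.samples.size
    if kind == "blink":
        center = rng.uniform(0.2, 0.8) * n
        t = np.arange(n)
        out.samples = out.samples + blink_amp * np.exp(
            -0.5 * ((t - center) / (blink_width * trial.fs)) ** 2
        )
    elif kind == "noisy":
        mean = out.samples.mean()
        out.samples = mean + noise_factor * (out.samples - mean)
    else:
        raise ValueError(f"unknown artifact kind: {kind!r}")
    return out
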