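"""Inter-trial phase coherency with a bootstrapped white-noise null.

The statistic: take the FFT of the first 5 s of each onset-aligned trial,
keep only the phase angle at each 0.2 Hz bin between 1 and 15 Hz, and
summarise phase consistency across trials.  The default estimator is the
resultant length |mean_j exp(i phi_j)|: 1 when every trial has the same
phase, tending to 0 for uniform phases.

Significance comes from a bootstrap-style null: many synthetic datasets of
white-noise trials (or, equivalently, i.i.d. uniform phases -- noise phase is
uniform by principle, and the two paths are verified against each other in
the tests), matched in trial count to the data; the 95th percentile of the
null coherency per frequency is the noise threshold.  For uniform phases the
squared resultant of n trials is asymptotically Exp(mean 1/n), so the
threshold has the Rayleigh-test closed form sqrt(ln(1/alpha)/n) ~ 0.15 at
n = 134 and 0.08 at n = 534.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dsp import bin_coefficient
from .trialset import TrialSet

DEFAULT_WINDOW = 5.0  # seconds of post-onset signal entering the FFT
DEFAULT_FMIN = 1.0
DEFAULT_FMAX = 15.0


def analysis_freqs(
    fmin: float = DEFAULT_FMIN, fmax: float = DEFAULT_FMAX, window: float = DEFAULT_WINDOW
) -> np.ndarray:
    """The analysis grid: fmin..fmax in steps of 1/window (0.2 Hz for 5 s)."""
    df = 1.0 / window
    k0 = int(round(fmin / df))
    k1 = int(round(fmax / df))
    return np.round(np.arange(k0, k1 + 1) * df, 10)


@dataclass
class PhaseTable:
    """Per-trial phase angles on the analysis grid; amplitudes discarded."""

    phases: np.ndarray  # (n_trials, n_freqs), radians in (-pi, pi]
    freqs: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]


@dataclass
class CoherencySpectrum:
    values: np.ndarray
    freqs: np.ndarray
    estimator: str
    n_trials: int

    def at(self, freq: float) -> float:
        return float(self.values[_nearest_bin(self.freqs, freq)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_hz": self.freqs, "coherency": self.values})


@dataclass
class NullThreshold:
    """Per-frequency noise threshold plus the retained null sample."""

    thresholds: np.ndarray  # (n_freqs,)
    freqs: np.ndarray
    null_samples: np.ndarray  # (B, n_freqs)
    n_trials: int
    percentile: float
    method: str
    seed: object = None

    @property
    def B(self) -> int:
        return self.null_samples.shape[0]

    def at(self, freq: float) -> float:
        return float(self.thresholds[_nearest_bin(self.freqs, freq)])

    def p_value(self, freq: float, observed: float) -> float:
        """Null exceedance probability of an observed coherency value."""
        null = self.null_samples[:, _nearest_bin(self.freqs, freq)]
        return float((1 + np.sum(null >= observed)) / (null.size + 1))


def rayleigh_threshold(n_trials: int, percentile: float = 95.0) -> float:
    """Closed-form large-n null quantile of the resultant length.

    For n i.i.d. uniform phases, n*R^2 is asymptotically Exp(1), so the
    q-quantile of R is sqrt(-ln(1-q)/n) (clipped to 1).
    """
    q = percentile / 100.0
    return float(min(1.0, np.sqrt(-np.log(1.0 - q) / n_trials)))


# ----------------------------------------------------------------------
def extract_phases(
    trialset: TrialSet,
    window: float = DEFAULT_WINDOW,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
) -> PhaseTable:
    """Phase of each trial's FFT on the analysis grid.

    Exactly ``window`` seconds from stimulus onset enter the FFT (remaining
    samples are discarded), which makes the bin spacing 1/window.
    """
    x = trialset.post_window(window)
    n = x.shape[1]
    spec = np.fft.rfft(x, axis=-1)
    freqs = analysis_freqs(fmin, fmax, window)
    fft_freqs = np.fft.rfftfreq(n, d=1.0 / trialset.fs)
    df = fft_freqs[1]
    idx = np.round(freqs / df).astype(int)
    if not np.allclose(fft_freqs[idx], freqs, atol=1e-9):
        raise ValueError("analysis grid is not representable at this fs/window")
    return PhaseTable(phases=np.angle(spec[:, idx]), freqs=freqs)


def phase_at(trialset: TrialSet, freq: float, window: float = DEFAULT_WINDOW) -> np.ndarray:
    """Per-trial phase at an arbitrary (possibly off-grid) frequency."""
    x = trialset.post_window(window)
    return np.angle(bin_coefficient(x, trialset.fs, freq))


def resultant_length(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.abs(np.mean(np.exp(1j * phases), axis=axis))


def _ci_fraction(phases: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """1 - (confidence-interval width of the phase angles)/(full circle).

    The interval is the circular mean +/- the empirical (1-alpha) quantile of
    absolute phase deviations from it.
    """
    mean_dir = np.angle(np.mean(np.exp(1j * phases), axis=0))
    dev = np.angle(np.exp(1j * (phases - mean_dir[None, :])))
    half = np.quantile(np.abs(dev), 1.0 - alpha, axis=0)
    return 1.0 - half / np.pi


def coherency(
    table: PhaseTable, estimator: str = "resultant_length", alpha: float = 0.05
) -> CoherencySpectrum:
    """Inter-trial coherency per frequency.

    estimator="resultant_length" (default): magnitude of the mean unit
    phasor.  estimator="ci_fraction": one minus the phase-angle confidence
    interval expressed as a fraction of the full circle.
    """
    if table.n_trials < 2:
        raise ValueError("coherency needs at least 2 trials")
    if estimator == "resultant_length":
        values = resultant_length(table.phases)
    elif estimator == "ci_fraction":
        values = _ci_fraction(table.phases, alpha)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return CoherencySpectrum(
        values=np.clip(values, 0.0, 1.0),
        freqs=table.freqs,
        estimator=estimator,
        n_trials=table.n_trials,
    )


# ----------------------------------------------------------------------
def null_threshold(
    n_trials: int,
    B: int = 10_000,
    percentile: float = 95.0,
    freqs: np.ndarray | None = None,
    seed: np.random.Generator | int | None = None,
    method: str = "phase",
    fs: float = 1000.0,
    window: float = DEFAULT_WINDOW,
    estimator: str = "resultant_length",
) -> NullThreshold:
    """Noise threshold from B synthetic white-noise datasets of n trials.

    method="phase" draws i.i.d. uniform phases directly (fast path, exact
    under the uniform-phase principle); method="timeseries" simulates full
    white-noise trials and pushes them through the FFT phase extraction.
    The two agree within Monte-Carlo error (tested, not assumed).
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = analysis_freqs(window=window)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))

    if method == "phase":
        samples = np.empty((B, freqs.size))
        for j in range(freqs.size):  # chunked to bound memory at B x n
            phases = rng.uniform(-np.pi, np.pi, (B, n_trials))
            if estimator == "resultant_length":
                samples[:, j] = resultant_length(phases, axis=1)
            else:
                samples[:, j] = _ci_fraction(phases.T)
    elif method == "timeseries":
        n = int(round(window * fs))
        fft_freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        idx = np.round(freqs * window).astype(int)
        if not np.allclose(fft_freqs[idx], freqs, atol=1e-9):
            raise ValueError("freqs not on the FFT grid for this fs/window")
        samples = np.empty((B, freqs.size))
        for b in range(B):
            x = rng.standard_normal((n_trials, n))
            ph = np.angle(np.fft.rfft(x, axis=-1)[:, idx])
            if estimator == "resultant_length":
                samples[b] = resultant_length(ph)
            else:
                samples[b] = _ci_fraction(ph)
    else:
        raise ValueError(f"unknown method {method!r}")

    thr = np.percentile(samples, percentile, axis=0)
    return NullThreshold(
        thresholds=thr,
        freqs=freqs,
        null_samples=samples,
        n_trials=n_trials,
        percentile=percentile,
        method=method,
        seed=seed if isinstance(seed, int) else None,
    )


# ----------------------------------------------------------------------
@dataclass
class HarmonicDetection:
    """Detection decisions at the first K harmonics of the tag frequency."""

    f0: float
    table: pd.DataFrame  # harmonic, target_hz, bin_hz, offset, coherency, threshold, detected, p
    mode: str

    @property
    def detected_harmonics(self) -> list[int]:
        return [int(k) for k in self.table.loc[self.table["detected"], "harmonic"]]


def detect_harmonics(
    spectrum: CoherencySpectrum,
    null: NullThreshold,
    f0: float,
    K: int = 6,
    mode: str = "nearest",
    trialset: TrialSet | None = None,
    window: float = DEFAULT_WINDOW,
) -> HarmonicDetection:
    """Compare coherency against the noise threshold at harmonics k*f0.

    mode="nearest": evaluate at the nearest analysis bin (ties resolved
    toward the lower bin) and report the frequency offset.  mode="exact":
    evaluate the phase DFT exactly at k*f0, which requires the original
    ``trialset``.  A coherency above the threshold at a harmonic carries
    p < 1 - percentile/100 by construction; exact p-values are null
    exceedance ranks.
    """
    if null.n_trials != spectrum.n_trials:
        raise ValueError("null threshold trial count does not match the data")
    rows = []
    fmax = float(spectrum.freqs.max())
    for k in range(1, K + 1):
        target = k * f0
        if target > fmax + 1e-9:
            raise ValueError(f"harmonic {k} ({target} Hz) above the analysis range")
        if mode == "nearest":
            j = _nearest_bin(spectrum.freqs, target)
            f_used = float(spectrum.freqs[j])
            value = float(spectrum.values[j])
        elif mode == "exact":
            if trialset is None:
                raise ValueError("mode='exact' needs the trialset")
            f_used = target
            value = float(resultant_length(phase_at(trialset, target, window)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        thr = null.at(f_used)
        rows.append(
            {
                "harmonic": k,
                "target_hz": target,
                "bin_hz": f_used,
                "offset_hz": f_used - target,
                "coherency": value,
                "threshold": thr,
                "detected": value > thr,
                "p_value": null.p_value(f_used, value),
            }
        )
    return HarmonicDetection(f0=f0, table=pd.DataFrame(rows), mode=mode)


def pool_trials(trialsets: list[TrialSet]) -> TrialSet:
    """Concatenate trials across participants; every trial keeps weight 1.

    Requires identical sampling rates; the pooled set is trimmed to the
    common pre/post window.  The noise threshold must be recomputed at the
    pooled trial count.
    """
    if not trialsets:
        raise ValueError("nothing to pool")
    fs = trialsets[0].fs
    if any(ts.fs != fs for ts in trialsets):
        raise ValueError("mismatched sampling rates")
    pre = min(ts.onset_index for ts in trialsets)
    post = min(ts.n_samples - ts.onset_index for ts in trialsets)
    data = np.concatenate(
        [ts.data[:, ts.onset_index - pre : ts.onset_index + post] for ts in trialsets]
    )
    return TrialSet(
        data=data,
        fs=fs,
        onset_index=pre,
        conditions=np.concatenate([ts.conditions for ts in trialsets]),
        participant_ids=np.concatenate([ts.participant_ids for ts in trialsets]),
        good_flags=np.concatenate([ts.good_flags for ts in trialsets]),
        meta={"pooled_from": len(trialsets)},
    )


def coherency_snr(coherency_value: float, threshold_value: float) -> float:
    """Coherency SNR: observed coherency over the noise threshold."""
    if threshold_value <= 0:
        raise ValueError("threshold must be positive")
    return coherency_value / threshold_value


def _nearest_bin(freqs: np.ndarray, freq: float) -> int:
    # np.argmin returns the first minimum, so a half-bin tie resolves to the
    # lower frequency; the offset is reported alongside.
    return int(np.argmin(np.abs(np.asarray(freqs) - freq)))
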