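"""Morlet-wavelet time-frequency analysis: ERSP, ITC and bootstrap masks.

ERSP (event-related spectral perturbation) is the trial-averaged wavelet
power expressed in dB relative to the pre-onset baseline, per frequency;
ITC is the resultant length of the per-trial wavelet phases per cell.
Significance masking resamples baseline latencies (a per-cell, uncorrected
bootstrap, the convention of the common EEG toolboxes this mirrors).

Default wavelets use n_cycles = 1.5 * f / f_min, i.e. a constant spectral
bandwidth sigma_f = 2/3 Hz across the map.  That keeps 1 Hz-spaced cells
spectrally separable (a band-interior cell sees >98% of a band-limited
power change) while the temporal width sigma_t ~ 0.24 s leaves enough
independent samples in a 1 s pre-onset baseline to estimate per-frequency
baseline power tightly.  Cells whose wavelet support crosses the stimulus onset
or a band edge are excluded from baseline statistics and band summaries (the
smearing there is a property of the wavelet, not of the data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len

from ._dsp import bin_coefficient
from .coherency import resultant_length, _nearest_bin
from .trialset import TrialSet

ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 30.0)
DEFAULT_BANDS = {"alpha": ALPHA_BAND, "beta": BETA_BAND}


@dataclass
class TimeFreqMap:
    """A time x frequency grid of ERSP (dB) or ITC values.

    ``values`` has shape (n_freqs, n_times); ``times`` are seconds relative
    to onset.  ``mask``, when set by :func:`significance_mask`, flags the
    cells that are significant at the chosen level.  Private ``_trial_*``
    arrays retain the per-trial baseline statistics the bootstrap needs.
    """

    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray
    kind: str  # "ersp_db" | "itc"
    baseline_window: tuple[float, float]
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    _trial_baseline: np.ndarray | None = None  # (n_trials, n_freqs, n_base_times)
    _baseline_ref: np.ndarray | None = None  # (n_freqs,)

    def sigma_f(self) -> np.ndarray:
        return self.freqs / np.asarray(self.meta["n_cycles"])

    def sigma_t(self) -> np.ndarray:
        return np.asarray(self.meta["n_cycles"]) / (2 * np.pi * self.freqs)


@dataclass
class BandSummary:
    name: str
    band: tuple[float, float]
    mean_delta_db: float | None
    significant: bool | None
    n_cells: int


def _cycles(freqs: np.ndarray, n_cycles) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if n_cycles is None:
        return 1.5 * freqs / freqs.min()
    if np.isscalar(n_cycles):
        return np.full(freqs.size, float(n_cycles))
    return np.asarray(n_cycles, dtype=float)


def _wavelet_transform(
    data: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    cycles: np.ndarray,
    sel: np.ndarray,
):
    """Yield per-frequency complex wavelet coefficients at selected samples.

    Boundary handling: trials are zero-padded and each coefficient is
    renormalised by the fraction of the kernel's energy that overlaps real
    data.  Unlike mirror padding (which turns edge cells into folded,
    half-rank functionals of duplicated samples) this keeps the power of
    stationary noise unbiased at the edges while every cell remains a
    full-rank estimate -- the short pre-onset baseline cannot afford to
    waste degrees of freedom.  Convolution runs through one shared rFFT.
    """
    n_trials, n_samp = data.shape
    sigma_t = cycles / (2 * np.pi * freqs)
    half = np.ceil(4 * sigma_t * fs).astype(int)
    nfft = next_fast_len(n_samp + 2 * int(half.max()) + 1)
    X = np.fft.rfft(data, nfft, axis=-1)
    ones = np.ones(n_samp)
    for j, (f, st, h) in enumerate(zip(freqs, sigma_t, half)):
        t = np.arange(-h, h + 1) / fs
        env = np.exp(-0.5 * (t / st) ** 2)
        kern = env * np.exp(2j * np.pi * f * t)
        kern /= env.sum()
        # full convolution: output index (s + h) corresponds to sample s
        cols = sel + h
        kr = np.fft.rfft(kern.real, nfft)
        ki = np.fft.rfft(kern.imag, nfft)
        wre = np.fft.irfft(X * kr, nfft, axis=-1)[:, cols]
        wim = np.fft.irfft(X * ki, nfft, axis=-1)[:, cols]
        # in-data kernel energy fraction at each selected sample
        frac = np.convolve(ones, env**2 / (env**2).sum(), mode="full")[cols]
        w = (wre + 1j * wim) / np.sqrt(np.maximum(frac, 1e-12))
        yield j, w


def _grid(trialset: TrialSet, hop: float):
    hop_n = max(1, int(round(hop * trialset.fs)))
    sel = np.arange(0, trialset.n_samples, hop_n)
    times = (sel - trialset.onset_index) / trialset.fs
    return sel, times


def _baseline_cells(times, baseline, guard):
    return (times >= baseline[0]) & (times <= baseline[1]) & (times <= -guard)


def _matched_baseline_power(
    data: np.ndarray,
    fs: float,
    onset: int,
    baseline_window: tuple[float, float],
    freqs: np.ndarray,
    sigma_t: np.ndarray,
) -> np.ndarray:
    """Expected wavelet power of the baseline, per frequency.

    The per-trial periodogram of the whole pre-onset segment is convolved
    with the wavelet's spectral power window exp(-4 pi^2 sigma_t^2 (xi-f)^2).
    This matches E|W|^2 for stationary noise exactly, but unlike averaging
    baseline wavelet cells it uses every pre-onset sample with full rank (no
    kernel truncation at the trial edge, no smearing across the onset), which
    matters because the baseline is short and sets the ERSP error budget.
    """
    b0 = onset + int(round(baseline_window[0] * fs))
    b1 = onset + int(round(baseline_window[1] * fs))
    if b0 < 0 or b1 <= b0:
        raise ValueError("baseline window outside the trials")
    seg = data[:, b0:b1]
    seg = seg - seg.mean(axis=-1, keepdims=True)
    m = seg.shape[1]
    nfft = 4 * m  # fine grid so the Gaussian window is integrated, not sampled
    # Two sine tapers: kills the boxcar's sinc^2 leakage of the strong 1/f
    # low end into every band (which biases a plain periodogram high by
    # ~0.1 dB) while, unlike a single Hann taper, keeping nearly the full
    # 2*B*T degrees of freedom of the short baseline.
    psd_mean = 0.0
    for k in (1, 2):
        taper = np.sqrt(2.0 / (m + 1)) * np.sin(np.pi * k * np.arange(1, m + 1) / (m + 1))
        spec = np.fft.rfft(seg * taper, nfft, axis=-1)
        psd = (np.abs(spec) ** 2) * (2.0 / (fs * np.sum(taper**2)))
        psd[:, 0] /= 2.0
        psd_mean = psd_mean + psd.mean(axis=0)
    psd_mean = psd_mean / 2.0
    xi = np.fft.rfftfreq(nfft, d=1.0 / fs)
    dxi = xi[1]
    out = np.empty(freqs.size)
    for j, (f, st) in enumerate(zip(freqs, sigma_t)):
        win = np.exp(-4 * np.pi**2 * st**2 * (xi - f) ** 2) + np.exp(
            -4 * np.pi**2 * st**2 * (xi + f) ** 2
        )
        out[j] = 0.5 * np.sum(psd_mean * win) * dxi
    return out


def ersp(
    trialset: TrialSet,
    freqs: np.ndarray | None = None,
    n_cycles=None,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
    hop: float = 0.05,
    edge_guard: bool = True,
) -> TimeFreqMap:
    """Baseline-relative spectral power map in dB.

    Per cell: 10*log10(mean-over-trials post power / mean baseline power at
    that frequency).  With ``edge_guard`` (default) baseline cells closer to
    onset than sqrt(2)*sigma_t(f) are excluded from the baseline mean, since
    the wavelet there already integrates post-onset samples.
    """
    if freqs is None:
        freqs = np.arange(1.0, 31.0)
    freqs = np.asarray(freqs, dtype=float)
    cycles = _cycles(freqs, n_cycles)
    sel, times = _grid(trialset, hop)
    # one onset guard for the whole map: the widest wavelet sets it
    sigma_t = cycles / (2 * np.pi * freqs)
    guard = float(np.sqrt(2) * sigma_t.max()) if edge_guard else 0.0
    # cells kept for the bootstrap also stay clear of the trial's left edge,
    # where truncated kernels pick up heavy spectral tails on 1/f noise
    left = baseline_window[0] + (float(sigma_t.max()) if edge_guard else 0.0)
    bcells = _baseline_cells(times, (left, baseline_window[1]), guard)
    if not np.any(bcells):
        raise ValueError("no usable baseline cells; trials need a pre-onset period")
    base_ref = _matched_baseline_power(
        trialset.data, trialset.fs, trialset.onset_index, baseline_window, freqs, sigma_t
    )
    power = np.empty((freqs.size, times.size))
    trial_base = np.empty((trialset.n_trials, freqs.size, int(bcells.sum())))
    trial_power = np.empty((trialset.n_trials, freqs.size, times.size), dtype=np.float32)
    for j, W in _wavelet_transform(trialset.data, trialset.fs, freqs, cycles, sel):
        p = np.abs(W) ** 2
        power[j] = p.mean(axis=0)
        trial_base[:, j, :] = p[:, bcells]
        trial_power[:, j, :] = p
    values = 10.0 * np.log10(power / base_ref[:, None])
    return TimeFreqMap(
        times=times,
        freqs=freqs,
        values=values,
        kind="ersp_db",
        baseline_window=baseline_window,
        meta={
            "n_cycles": cycles,
            "hop_s": hop,
            "edge_guard": edge_guard,
            "_power": power,
            "_trial_power": trial_power,
        },
        _trial_baseline=trial_base,
        _baseline_ref=base_ref,
    )


def itc_timecourse(
    trialset: TrialSet,
    freqs: np.ndarray | None = None,
    n_cycles=None,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
    hop: float = 0.05,
) -> TimeFreqMap:
    """Inter-trial coherency over time: per-cell resultant of wavelet phases."""
    if trialset.n_trials < 2:
        raise ValueError("ITC needs at least 2 trials")
    if freqs is None:
        freqs = np.arange(1.0, 31.0)
    freqs = np.asarray(freqs, dtype=float)
    cycles = _cycles(freqs, n_cycles)
    sel, times = _grid(trialset, hop)
    itc = np.empty((freqs.size, times.size))
    trial_base = None
    for j, W in _wavelet_transform(trialset.data, trialset.fs, freqs, cycles, sel):
        unit = W / np.maximum(np.abs(W), np.finfo(float).tiny)
        itc[j] = np.abs(unit.mean(axis=0))
        bcells = _baseline_cells(times, baseline_window, 0.0)
        if trial_base is None:
            trial_base = np.empty(
                (trialset.n_trials, freqs.size, int(bcells.sum())), dtype=complex
            )
        trial_base[:, j, :] = unit[:, bcells]
    return TimeFreqMap(
        times=times,
        freqs=freqs,
        values=itc,
        kind="itc",
        baseline_window=baseline_window,
        meta={"n_cycles": cycles, "hop_s": hop},
        _trial_baseline=trial_base,
    )


def significance_mask(
    tfmap: TimeFreqMap,
    B_perm: int = 200,
    alpha: float = 0.05,
    seed: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-cell bootstrap significance flags from resampled baseline latencies.

    ERSP maps use a paired trial bootstrap: the per-cell statistic is the
    trial mean of (cell power - that trial's own baseline mean), so the slow
    within-trial power fluctuations that dominate low frequencies cancel in
    the pairing; replicates resample trials with replacement and the cell is
    flagged when zero falls outside the recentred (alpha/2, 1-alpha/2)
    bootstrap interval.  ITC maps use resampled baseline latencies (with
    trial resampling) and flag cells above the 1-alpha null quantile.
    Per-cell and uncorrected, as is conventional; baseline stationarity is
    the null hypothesis.
    """
    if B_perm < 100:
        raise ValueError("B_perm must be >= 100")
    if tfmap._trial_baseline is None:
        raise ValueError("map carries no baseline samples; recompute with the library")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_trials, n_freqs, n_base = tfmap._trial_baseline.shape
    if tfmap.kind == "ersp_db":
        trial_power = tfmap.meta["_trial_power"]  # (n, F, T)
        base_mean = tfmap._trial_baseline.mean(axis=2)  # (n, F)
        # multinomial weights give the bootstrap trial means as one matmul
        counts = rng.multinomial(n_trials, np.full(n_trials, 1.0 / n_trials), size=B_perm)
        weights = counts / n_trials  # (B, n)
        mask = np.empty_like(tfmap.values, dtype=bool)
        for j in range(n_freqs):
            d = trial_power[:, j, :].astype(float) - base_mean[:, j][:, None]
            observed = d.mean(axis=0)
            boot = weights @ d  # (B, T)
            null = boot - observed[None, :]
            lo = np.quantile(null, alpha / 2, axis=0)
            hi = np.quantile(null, 1 - alpha / 2, axis=0)
            mask[j] = (observed < lo) | (observed > hi)
    elif tfmap.kind == "itc":
        trial_draws = rng.integers(0, n_trials, size=(B_perm, n_trials))
        cell_draws = rng.integers(0, n_base, size=(B_perm, n_trials))
        picked = tfmap._trial_baseline[trial_draws, :, cell_draws]  # (B, n, F)
        null = np.abs(picked.mean(axis=1))
        hi = np.quantile(null, 1 - alpha, axis=0)
        mask = tfmap.values > hi[:, None]
    else:
        raise ValueError(f"unknown map kind {tfmap.kind!r}")
    tfmap.mask = mask
    tfmap.meta["mask"] = {"B_perm": B_perm, "alpha": alpha, "correction": "none"}
    return mask


def band_summary(
    tfmap: TimeFreqMap,
    bands: dict[str, tuple[float, float]] | None = None,
    post_window: tuple[float, float] | None = None,
    interior_only: bool = True,
) -> list[BandSummary]:
    """Mean post-onset change per frequency band.

    With ``interior_only`` (default) cells within half a spectral FWHM of a
    band edge are excluded, so leakage from outside the band does not dilute
    the band mean; likewise the post window starts after the onset-smearing
    guard.  For an ERSP map the band change is the ratio of *pooled* in-band
    power (interior rows summed, post window vs baseline), which uses the
    short baseline's degrees of freedom jointly instead of averaging noisy
    per-row dB values; for other maps it is the plain cell mean.  The
    ``significant`` flag (when a mask is present) reports whether the
    majority of the included cells are flagged.
    """
    bands = bands or DEFAULT_BANDS
    sigma_f = tfmap.sigma_f()
    guard_t = float(np.max(np.sqrt(2) * tfmap.sigma_t()))
    if post_window is None:
        post_window = (guard_t, float(tfmap.times.max()))
    tcells = (tfmap.times >= post_window[0]) & (tfmap.times <= post_window[1])
    linear_power = tfmap.kind == "ersp_db" and "_power" in tfmap.meta
    out = []
    for name, (lo, hi) in bands.items():
        if hi > tfmap.freqs.max() + 1e-9 or lo < tfmap.freqs.min() - 1e-9:
            raise ValueError(f"band {name} outside the map's frequency range")
        edge = 1.1774 * sigma_f if interior_only else np.zeros_like(sigma_f)  # FWHM/2
        fcells = (tfmap.freqs >= lo + edge) & (tfmap.freqs <= hi - edge)
        if not np.any(fcells):
            fcells = (tfmap.freqs >= lo) & (tfmap.freqs <= hi)
        if linear_power:
            post_band = tfmap.meta["_power"][np.ix_(fcells, tcells)].mean(axis=1).sum()
            base_band = tfmap._baseline_ref[fcells].sum()
            mean = float(10.0 * np.log10(post_band / base_band))
        else:
            cells = tfmap.values[np.ix_(fcells, tcells)]
            mean = float(cells.mean()) if cells.size else None
        sig = None
        if tfmap.mask is not None:
            sig = bool(tfmap.mask[np.ix_(fcells, tcells)].mean() > 0.5)
        out.append(
            BandSummary(
                name=name,
                band=(lo, hi),
                mean_delta_db=mean,
                significant=sig,
                n_cells=int(np.count_nonzero(fcells) * np.count_nonzero(tcells)),
            )
        )
    return out


def resolution_comparison(
    trialset: TrialSet,
    f0: float,
    harmonic: int = 2,
    fine_window: float = 5.0,
    coarse_window: float = 1.0,
) -> pd.DataFrame:
    """Coherency and power at a driven harmonic at two frequency resolutions.

    The fine path uses the full analysis window (0.2 Hz bins for 5 s); the
    coarse path uses a short window (1 Hz bins for 1 s), emulating the broad
    resolution of common time-frequency plots.  A precisely tuned harmonic
    loses peak height at the coarse resolution (scalloping), which is why a
    map can miss harmonics the coherency spectrum detects.
    """
    target = harmonic * f0
    rows = []
    for label, win in (("fine", fine_window), ("coarse", coarse_window)):
        df = 1.0 / win
        f_used = round(target / df) * df
        x = trialset.post_window(win)
        coef = bin_coefficient(x, trialset.fs, f_used)
        rows.append(
            {
                "resolution": label,
                "bin_width_hz": df,
                "freq_used_hz": f_used,
                "coherency": float(resultant_length(np.angle(coef))),
                "power": float(np.mean(np.abs(coef) ** 2)),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["power_ratio_fine_over_coarse"] = float(
        out.loc[0, "power"] / max(out.loc[1, "power"], np.finfo(float).tiny)
    )
    return out
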