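# Methods

This note records the models, estimators, defaults and numerical choices
behind `phasetag`, and what the synthetic testbed does and does not
establish about real recordings.

## 1. Signal model

Each trial is a single EEG channel sampled at `fs` (default 1000 Hz): a
zero-disparity pre-period of 1–1.5 s (uniform), then 5–6 s (uniform) of a
depth plane alternating at f₀ = 2.1 Hz as a 50% duty-cycle square wave with
±0.05° disparity. Within a dataset the trials are trimmed to the common
window around onset, so all analysis sees a rectangular array with a single
onset index.

The phase-locked neural response is parameterised directly per harmonic:

    r(t) = Σₖ Aₖ cos(2π k f₀ (t − ℓ) + φₖ + ηⱼ),  t ≥ 0,

with amplitudes Aₖ (µV), onset-locked phases φₖ, a participant-level
propagation latency ℓ (so the phase penalty of pooling grows with harmonic
frequency), and a per-trial jitter ηⱼ ~ N(0, σ²) common to all harmonics.
The generator does not model the rectification chain that produces the
harmonics; parameterising the harmonics directly lets tests place energy at
exactly the harmonics each condition should express (even harmonics for the
correlated-like condition, the first harmonic for the anticorrelated-like
one).

With jitter alone, the asymptotic coherency at a driven harmonic is
exp(−σ²/2). The condition presets are calibrated to the coherency scale
reported for human recordings of this paradigm: σ = 1.5 rad
(`correlated_like_response`, C∞ ≈ 0.32, matching reported 0.29–0.34 second-
harmonic values) and σ = 1.8 rad (`anticorrelated_like_response`, C∞ ≈ 0.2,
matching reported 0.155–0.2 first-harmonic values). This is a *forward*
calibration of the study conditions, not a fit performed per run.

Noise is white (σ_w) + 1/f^γ (σ_p, γ = 1, flattened below 0.1 Hz) + mains
(50 Hz sinusoid, random phase per trial, so it contributes amplitude but no
coherency). The 1/f component is synthesised by spectral shaping of complex
Gaussian coefficients with an analytic variance normalisation, so identical
seeds give identical trials and the aggregate noise power is exact.

### Signal-to-noise conventions

`NoiseModel.target_time_snr` fixes the ratio of mean response power to mean
noise power over the 5 s analysis window (`snr_reference="broadband"`,
realised exactly in aggregate by construction; the tests check 5% over 100+
trials). A second convention, `snr_reference="bin"`, fixes the ratio of
response power to noise power *within the 0.2 Hz analysis bin* at the
dominant harmonic. The distinction matters: a 5 s coherent integration
concentrates a sinusoid into one of ~350 occupied bins, so broadband SNR 0.5
corresponds to per-bin SNR of order 100 and detection saturates within a few
trials. Trial-budget questions are only non-trivial on the bin scale, which
is where `planning` operates (see §5).

### Band perturbations

A `BandPerturbation` rescales the trial's own [f_lo, f_hi] Hz noise
component by 10^(ΔdB/20) from onset onward — the post-onset in-band power
changes by exactly Δ dB pointwise while the phase stays uniform across
trials, emulating an induced (non-phase-locked) oscillation. The tests
assert this identity exactly and confirm that coherency at the band
frequencies stays at the noise level.

## 2. Preprocessing

Band-pass 0.1–70 Hz plus 48–52 Hz notch, as cascaded Butterworth responses
(high-pass order 2, low-pass order 10, band-stop order 4). The cascade is
applied as |H(f)|² in the frequency domain on reflect-padded epochs —
exactly zero-phase, equivalent in magnitude to a forward–backward IIR pass.
A time-domain `filtfilt` of the 0.1 Hz high-pass is ill-conditioned on
few-second epochs (its impulse response outlasts the epoch; the padding
transient swamps the data), and the entire downstream analysis lives in
phase space, so a strictly zero phase shift is the binding requirement. The
realised contract is measured in the tests: ≥ 20 dB down at 80 Hz, 50 Hz
attenuated to < 10% RMS, pass-band amplitude within 5% and phase shift < 1°
at 4.2 Hz, and coherency of a noiseless phase-locked set preserved to 1e−3.

Artifact rejection replaces multi-channel/eye-channel criteria (not
available on a single channel) with two per-trial rules: peak-to-peak
amplitude > 200 µV, or robust log-variance z-score (median/MAD) > 5. At
default settings ≥ 9 of 10 injected 300 µV blink-like transients are
caught on clean background.

## 3. Coherency and the noise threshold

Phases come from the FFT of exactly 5 s from stimulus onset (surplus
samples discarded), giving a 0.2 Hz grid; the analysis range is 1–15 Hz
(71 bins). The default estimator is the resultant length; `ci_fraction`
(one minus the phase-angle confidence interval as a fraction of the circle)
is provided as a secondary estimator since an alternative formulation of
the statistic exists, but the resultant length is what reproduces the
reported threshold values through the Rayleigh null.

The null threshold draws B datasets of n i.i.d. uniform phases per
frequency (default B = 10,000, 95th percentile) — justified, and separately
*tested*, against full white-noise time-series simulation pushed through the
same FFT path (the definition of the statistic implies the two are equivalent;
the suite checks agreement within Monte-Carlo error, and against the
closed form sqrt(ln 20 / n) for n ∈ {50, 134, 534}). Null samples are
retained so detections carry exceedance p-values, p = (1 + #{null ≥
obs})/(B + 1), per harmonic and uncorrected (family size 6 is reported).

Harmonics of 2.1 Hz fall half-way between 0.2 Hz bins for odd k; the
default evaluates the nearest bin (ties resolve to the lower bin, offset
reported) and `mode="exact"` evaluates the DFT at k·f₀ exactly. Scalloping
at a half-bin offset costs amplitude, not phase consistency, so coherency
detection is hardly affected for strong responses.

Pooling concatenates trials across participants with weight 1 and recomputes
the threshold at the pooled n. Amplitude invariance (any positive per-trial
rescaling leaves the spectrum unchanged) is asserted to machine precision.

## 4. Time–frequency maps

Complex Morlet wavelets, default grid 1–30 Hz at 1 Hz with n_cycles =
1.5·f/f_min, i.e. a constant spectral bandwidth σ_f = 2/3 Hz and temporal
width σ_t ≈ 0.24 s; coefficients are sampled every 50 ms. This bandwidth
was chosen from an explicit error budget: interior cells of a 4 Hz band see
> 98% of a band-limited power change (leakage bias < 0.02 dB), while the
1 s baseline retains enough temporal degrees of freedom per frequency for
the ±1 dB band effects to be estimable (a 3-cycles-at-f_min scaling,
σ_t ≈ 0.48 s, leaves under one independent baseline sample per trial and
~0.3 dB per-row baseline noise even at 540 trials). Trials are zero-padded
with per-cell renormalisation by the kernel's in-data energy
(cone-of-influence correction); mirror padding was rejected because it
turns edge cells into folded, half-rank functionals of duplicated samples,
exactly where the short baseline can least afford it.

ERSP values are 10·log₁₀ of trial-mean wavelet power over the baseline
reference B(f). B(f) is *not* the mean of baseline wavelet cells: it is the
full pre-onset segment's PSD — estimated with K = 2 sine tapers on a 4×
zero-padded grid — integrated against the wavelet's spectral power window
exp(−4π²σ_t²(ξ∓f)²), which equals the expected wavelet power of stationary
noise while using every baseline sample at full rank with no onset
leakage. The two sine tapers suppress the boxcar's sinc² sidelobes (which
would leak the strong 1/f low end into every band, ~+0.1 dB) at almost no
cost in degrees of freedom, unlike a single Hann taper. Benchmarked against
a long-run truth on noise-only data, this estimator is unbiased to ~0.01 dB
with a standard deviation at the 2·B·T information floor of the 1 s
baseline (~0.09 dB for the alpha band at 540 trials).

`band_summary` reports the band change as the ratio of pooled in-band power
(interior rows — those at least half a spectral FWHM inside the band edges —
summed over a post window that starts √2·σ_t after onset) to the pooled
baseline reference. At the emulated study scale (540 trials) the recovered
alpha change for a true +1 dB injection is distributed ≈ N(0.95, 0.12) dB
and the beta change ≈ N(0.99, 0.06) dB; the 0.12 dB spread is the baseline
information floor, so single-dataset recoveries occasionally miss a ±0.2 dB
window — a property of the study conditions (1 s baseline), not of the
estimator.

ITC maps are per-cell resultant lengths of the wavelet unit phasors.

Significance masking is per-cell and uncorrected, as in the common EEG
toolboxes. For ERSP the statistic is *paired*: the trial mean of (cell
power − that trial's own baseline mean), bootstrap-resampled over trials;
pairing cancels the slow within-trial power fluctuations that dominate the
lowest frequencies, and trial resampling is essential because baseline
latencies alone are near-duplicates when σ_t exceeds the hop (latency-only
resampling collapses the null to less than half the true sampling spread).
Measured false-positive rate on stationary noise is 3–6% at α = 0.05, with
0.85 power for a +1 dB alpha injection at 250 trials. ITC masks resample
both trials and baseline latencies and flag cells above the 1−α null
quantile.

`resolution_comparison` quantifies why a 1 Hz-resolution map can miss
harmonics the 0.2 Hz coherency spectrum detects: the 1 s-window path loses
peak height to scalloping for a precisely tuned component, while broadband
changes agree across resolutions.

## 5. Trial-budget planning

The estimand is operational: the smallest n whose detection rate over
replicate experiments reaches `target_power` (default 0.8, a standard
choice the source bracket does not pin down) at α = 0.05. The default
simulator works on the per-trial bin coefficient Z = √s·e^{iφ} + CN(0, 1) —
`s` is the bin-referenced SNR (see §1) — and is validated in the tests
against full time-series simulation through the generator and FFT path.
Detection methods: `coherency` (resultant length against the Rayleigh
threshold) and `spectral` (mean per-trial bin *amplitude* against the 95th
percentile of matched noise-only simulations — incoherent averaging, the
amplitude analogue of the published comparison). Binary search doubles then
bisects n; power is monotone in both n and s (tested with binomial
tolerance). At s = 0.5 the coherency method needs ~16 trials and the
spectral method ~35; at s = 0.1, ~60 vs ~700 — the phase statistic
dominates, increasingly so at low SNR, which is the central methodological
ordering the suite asserts. The inverse map (`estimate_snr_from_trials`)
bisects on log-SNR with common random numbers; the round trip at s = 0.5
recovers the SNR within 25%.

The reported trial brackets (60–80 at "SNR 0.5", 120–150 at "SNR 0.1")
are treated as calibration corridors only: they depend on an external
formula whose SNR reference bandwidth is not stated, and no stationary
broadband noise model can make a broadband SNR of 0.5 require tens of
trials (§1). Our bin-referenced counts land in the right regime and order.

## 6. Pipeline and reproducibility

`run_pipeline` drives simulate → filter/reject → coherency (pooled, with
threshold and detections) → ERSP/ITC with masks → summary, from one
declarative `AnalysisConfig` (YAML-serialisable). Every output TSV embeds
the SHA-256 config hash; identical config + seed reproduces byte-identical
deterministic outputs. All stochastic operations accept explicit seeds or
`numpy.random.Generator`s; dataset generation derives per-trial-set streams
from the master seed via generator spawning.

## 7. Limitations

- Single channel only; no topography, re-referencing or spatial statistics.
- The generator's noise is stationary and Gaussian; real EEG has bursts,
  drifts and non-Gaussian artifacts beyond the two injected artifact kinds,
  so passing tests demonstrate estimator correctness under the stated
  model, not robustness to every recording pathology.
- The harmonic response model is additive and phase-locked with a single
  common jitter; it does not model amplitude variability across trials
  (which the phase-only statistic would ignore anyway) or frequency drift.
- Per-cell significance masks are uncorrected for multiple comparisons, by
  design parity with the conventional tooling.
- The `ci_fraction` estimator is a documented approximation of a
  confidence-interval-based coherency; the resultant length is the primary
  statistic throughout.
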