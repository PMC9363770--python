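"""Small shared signal-processing helpers."""

from __future__ import annotations

import numpy as np


def bin_coefficient(x: np.ndarray, fs: float, freq: float) -> np.ndarray:
    """Complex Fourier coefficient of ``x`` at an arbitrary frequency.

    Evaluates the single-bin DFT ``(2/N) * sum_t x_t exp(-2i pi f t / fs)``
    along the last axis, so a pure ``A*cos(2 pi f t + phi)`` whose frequency
    sits on the implied grid returns ``A * exp(i phi)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    t = np.arange(n) / fs
    kernel = np.exp(-2j * np.pi * freq * t)
    return (2.0 / n) * (x @ kernel)


def pink_spectrum_shape(n_samples: int, fs: float, exponent: float, f_floor: float = 0.1) -> np.ndarray:
    """Amplitude shaping of the one-sided spectrum for 1/f^gamma noise.

    The shape is ``f**(-gamma/2)`` flattened below ``f_floor`` (EEG amplifiers
    are AC-coupled around 0.1 Hz, and an unbounded 1/f pole would put all the
    power at DC).  DC and Nyquist are zeroed.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_floor) ** (-exponent / 2.0)
    shape[0] = 0.0
    if n_samples % 2 == 0:
        shape[-1] = 0.0
    return shape


def shaped_noise(
    rng: np.random.Generator,
    n_trials: int,
    n_samples: int,
    shape: np.ndarray,
    sd: float,
) -> np.ndarray:
    """Gaussian noise with the given one-sided spectral amplitude shape.

    Normalised analytically so each trace has expected standard deviation
    ``sd`` regardless of the shape.
    """
    if sd == 0:
        return np.zeros((n_trials, n_samples))
    spec = shape * (
        rng.standard_normal((n_trials, shape.size))
        + 1j * rng.standard_normal((n_trials, shape.size))
    )
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    # E[var(x)] = (4 / T^2) * sum_k shape_k^2 for zeroed DC/Nyquist bins.
    expected_var = 4.0 * np.sum(shape**2) / n_samples**2
    return x * (sd / np.sqrt(expected_var))


def band_mask(n_samples: int, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    return (freqs >= f_lo) & (freqs <= f_hi)


def band_component(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    """The [f_lo, f_hi] Hz band-limited part of each row of ``x``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    spec = np.fft.rfft(x, axis=-1)
    spec[:, ~band_mask(x.shape[-1], fs, f_lo, f_hi)] = 0.0
    return np.fft.irfft(spec, n=x.shape[-1], axis=-1)
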