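"""Figure helpers: coherency spectra with threshold/detection marks, and
time-frequency maps with significance shading."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coherency import CoherencySpectrum, HarmonicDetection, NullThreshold
from .timefreq import TimeFreqMap


def plot_coherency(
    spectrum: CoherencySpectrum,
    null: NullThreshold | None = None,
    detection: HarmonicDetection | None = None,
    path: str | Path | None = None,
    ax=None,
):
    """Coherency curve, noise-threshold line, and stars on detected harmonics."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(spectrum.freqs, spectrum.values, lw=1.2, label="coherency")
    if null is not None:
        ax.plot(null.freqs, null.thresholds, "k--", lw=1.0, label="noise threshold")
    if detection is not None:
        hit = detection.table[detection.table["detected"]]
        ax.plot(hit["bin_hz"], hit["coherency"] + 0.02, "k*", ms=9, ls="none")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("inter-trial coherency")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_map(tfmap: TimeFreqMap, path: str | Path | None = None, ax=None):
    """ERSP/ITC grid; insignificant cells are dimmed when a mask is present."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    values = tfmap.values
    if tfmap.mask is not None:
        values = np.where(tfmap.mask, values, np.nan)
        ax.pcolormesh(
            tfmap.times, tfmap.freqs, tfmap.values, cmap="Greys", alpha=0.35,
            shading="nearest",
        )
    vmax = np.nanmax(np.abs(tfmap.values))
    mesh = ax.pcolormesh(
        tfmap.times, tfmap.freqs, values, shading="nearest",
        cmap="RdBu_r" if tfmap.kind == "ersp_db" else "viridis",
        vmin=-vmax if tfmap.kind == "ersp_db" else 0,
        vmax=vmax if tfmap.kind == "ersp_db" else 1,
    )
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("time from onset (s)")
    ax.set_ylabel("frequency (Hz)")
    label = "ERSP (dB)" if tfmap.kind == "ersp_db" else "ITC"
    ax.figure.colorbar(mesh, ax=ax, label=label)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
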