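"""Display helpers (smoothing here is for visualization only)."""

from __future__ import annotations

import numpy as np


def moving_average(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Moving-average smoothing of a binned time course (display only)."""
    x = np.asarray(x, dtype=float)
    kernel = np.ones(n_bins) / n_bins
    return np.convolve(x, kernel, mode="same")


def plot_rate_timecourse(z_series, ax=None, smooth_bins: int = 4,
                         bin_s: float = 30.0):
    """Mean +/- SEM normalized firing-rate time course across units."""
    import matplotlib.pyplot as plt

    z = np.asarray(z_series, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    mean = moving_average(z.mean(axis=0), smooth_bins)
    sem = moving_average(z.std(axis=0) / np.sqrt(z.shape[0]), smooth_bins)
    t = np.arange(z.shape[1]) * bin_s / 60.0
    ax.plot(t, mean, color="k")
    ax.fill_between(t, mean - sem, mean + sem, alpha=0.3, color="k")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("normalized firing rate (z)")
    return ax


def plot_coherency_profile(freqs, profile, band=None, ax=None):
    """Grand-average coherency vs frequency with the extracted band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(freqs, profile, color="C0")
    if band is not None:
        ax.axvspan(band.low_hz, band.high_hz, alpha=0.2, color="C1")
        ax.axvline(band.peak_hz, color="C1", ls="--")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("imaginary coherency")
    return ax


def plot_cluster_slice(z_diff, cluster_labels, z_index, ax=None):
    """Axial slice of a difference map with retained clusters outlined."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(z_diff[:, :, z_index].T, cmap="coolwarm", origin="lower")
    ax.contour((cluster_labels[:, :, z_index] > 0).T, levels=[0.5],
               colors="k", linewidths=0.8)
    ax.set_title(f"z = {z_index}")
    return ax
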