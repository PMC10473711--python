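"""Basic result plots (requires the optional matplotlib dependency)."""

from __future__ import annotations

import numpy as np


def plot_lag_profile(profile, ax=None):
    """Plot single-lag AV and (A+V) accuracies and their MSI difference.

    ``profile`` is the tidy frame from :func:`avmsi.msi.single_lag_sweep`
    (columns ``lag_ms, r_av, r_sum, msi``). Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(profile.lag_ms, profile.r_av, label="AV", color="tab:red")
    if np.isfinite(profile.r_sum).any():
        ax.plot(profile.lag_ms, profile.r_sum, label="A+V", color="tab:blue")
    ax.axvline(0.0, color="0.6", lw=0.8, ls="--")
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("time lag (ms)")
    ax.set_ylabel("reconstruction accuracy (r)")
    ax.legend(frameon=False)
    return ax


def plot_decoder_weights(decoder, ax=None, cmap="RdBu_r"):
    """Heat map of decoder weights over channels x lags."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    w = decoder.weights_
    lags = decoder.lag_grid_.lag_times_ms
    vmax = np.abs(w).max() or 1.0
    im = ax.imshow(
        w, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax,
        extent=[lags[0], lags[-1], w.shape[0] - 0.5, -0.5],
    )
    ax.set_xlabel("time lag (ms)")
    ax.set_ylabel("channel")
    plt.colorbar(im, ax=ax, label="weight")
    return ax
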