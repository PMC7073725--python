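"""Diagnostic plots: detection curves with Feller predictions, vector fits.

These are thin matplotlib hooks; everything scientific happens in the
analysis modules.  Each function accepts an existing ``Axes`` so figures
can be composed into panels.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_detection_curves", "plot_vector_fit"]


def plot_detection_curves(observed_data, observed_fit, prediction=None, ax=None):
    """Chance-corrected detection points, fitted curve and Feller prediction.

    Marks the observed threshold (and the predicted one when a prediction
    is given) at the P = 0.5 line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    from .psychophysics import correct_for_chance

    x = observed_data.x
    P_hat = correct_for_chance(observed_data.proportion_correct(), observed_data.m)
    grid = np.linspace(x.min() - 0.3, x.max() + 0.3, 200)
    ax.plot(x, P_hat, "o", color="k", label="observed (chance-corrected)")
    ax.plot(grid, observed_fit.detection_probability(grid), "-", color="k", label="observed fit")
    ax.axvline(observed_fit.c, color="k", ls=":", lw=0.8)
    if prediction is not None:
        ax.plot(grid, prediction.detection_probability(grid), "--", color="tab:blue",
                label="Feller prediction")
        ax.axvline(prediction.threshold, color="tab:blue", ls=":", lw=0.8)
    ax.axhline(0.5, color="grey", lw=0.5)
    ax.set_xlabel("log10 concentration (µg/L)")
    ax.set_ylabel("detection probability")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_vector_fit(points, fit, ax=None):
    """Mixture intensity against unmixed intensity sum with the origin-line fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    grid = np.linspace(0, x.max() * 1.05, 50)
    ax.plot(x, y, "o", color="k")
    ax.plot(grid, fit.predict(grid), "-", color="tab:red",
            label=f"cos(α/2) = {fit.cos_half_alpha:.4f} (R² = {fit.r_squared:.3f})")
    ax.set_xlabel("OIa + OIb (unmixed sum)")
    ax.set_ylabel("OIab (mixture intensity)")
    ax.legend(frameon=False, fontsize=8)
    return ax
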