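"""Scatter and Bland-Altman plots for estimated vs measured EE."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers save to file
import matplotlib.pyplot as plt  # noqa: E402

from .validation import AgreementStats  # noqa: E402

__all__ = ["scatter_plot", "bland_altman_plot"]


def scatter_plot(pairs: pd.DataFrame, title: str = "", ax: plt.Axes | None = None) -> plt.Axes:
    """Estimated vs measured EE with the identity line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(pairs["measured_met"], pairs["estimated_met"], s=8, alpha=0.5)
    lims = [0, max(pairs["measured_met"].max(), pairs["estimated_met"].max()) * 1.05]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("Measured EE (METs)")
    ax.set_ylabel("Estimated EE (METs)")
    ax.set_title(title)
    return ax


def bland_altman_plot(
    pairs: pd.DataFrame,
    stats: AgreementStats | None = None,
    title: str = "",
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Difference vs mean plot with bias and +/- 2 SD limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    est = pairs["estimated_met"].to_numpy()
    meas = pairs["measured_met"].to_numpy()
    diff = est - meas
    mean = (est + meas) / 2
    ax.scatter(mean, diff, s=8, alpha=0.5)
    if stats is None:
        bias = float(diff.mean())
        sd = float(diff.std(ddof=1))
        lo, hi = bias - 2 * sd, bias + 2 * sd
    else:
        bias, lo, hi = stats.mean_bias, stats.loa_low, stats.loa_high
    ax.axhline(bias, ls="--", color="k", lw=1)
    ax.axhline(lo, ls=":", color="k", lw=1)
    ax.axhline(hi, ls=":", color="k", lw=1)
    ax.set_xlabel("Mean of estimated and measured EE (METs)")
    ax.set_ylabel("Estimated - measured (METs)")
    ax.set_title(title)
    return ax
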