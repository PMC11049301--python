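"""Diagnostic plots: method-comparison scatter with prediction band,
and stability trend with shelf-life band."""

from __future__ import annotations

import numpy as np

from .commutability import DemingFit, prediction_band
from .datatypes import MaterialPoint, PairedSampleSet, StabilitySeries
from .stability import TrendFit, prediction_band_point

__all__ = ["plot_commutability", "plot_stability"]


def plot_commutability(pairs: PairedSampleSet, fit: DemingFit,
                       materials=(), level: float = 0.95, ax=None):
    """Scatter of native pairs, Deming line, prediction band and
    candidate-material points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x, y = pairs.x, pairs.y
    grid = np.linspace(x.min() * 0.9, x.max() * 1.05, 200)
    lo, hi = zip(*(prediction_band(fit, g, level) for g in grid))
    ax.plot(grid, fit.intercept + fit.slope * grid, "k--", lw=1,
            label="Deming fit")
    ax.plot(grid, lo, "k-", lw=0.8)
    ax.plot(grid, hi, "k-", lw=0.8,
            label=f"{level:.0%} prediction band")
    ax.plot(x, y, "o", ms=4, color="0.4", label="native samples")
    for m in materials:
        marker = "s" if _is_commutable(fit, m, level) else "^"
        ax.plot(m.x_mean, m.y_mean, marker, ms=8, mfc="none", mec="C3",
                label=m.material_id)
    ax.set_xlabel(f"{pairs.x_method} glucose (mg/dL)")
    ax.set_ylabel(f"{pairs.y_method} glucose (mg/dL)")
    ax.legend(fontsize=8)
    return ax


def _is_commutable(fit: DemingFit, m: MaterialPoint, level: float) -> bool:
    lo, hi = prediction_band(fit, m.x_mean, level)
    return lo <= m.y_mean <= hi


def plot_stability(series: StabilitySeries, fit: TrendFit,
                   limits: tuple[float, float] | None = None,
                   level: float = 0.95, horizon: float | None = None,
                   ax=None):
    """Measurements, fitted trend and prediction band over storage time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = np.array([d for d, _, _ in series.records])
    y = np.array([v for _, _, v in series.records])
    end = horizon if horizon is not None else t.max() * 1.3
    grid = np.linspace(0, end, 300)
    lo, hi = zip(*(prediction_band_point(fit, g, level) for g in grid))
    ax.plot(t, y, "o", ms=4, color="0.4")
    ax.plot(grid, fit.b0 + fit.b1 * grid, "k-", lw=1.2, label="trend")
    ax.plot(grid, lo, "k--", lw=0.8)
    ax.plot(grid, hi, "k--", lw=0.8, label=f"{level:.0%} prediction band")
    if limits is not None:
        ax.axhline(limits[0], color="C0", lw=1.2)
        ax.axhline(limits[1], color="C0", lw=1.2,
                   label="acceptance limits")
    ax.set_xlabel("storage day")
    ax.set_ylabel("glucose (mg/dL)")
    ax.legend(fontsize=8)
    return ax
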