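"""Standard plots: percent-area series and time–scale coherence maps."""

from __future__ import annotations

import numpy as np

from .drought import AreaSeries
from .teleconnection import CoherenceResult


def plot_percent_area(series: AreaSeries, ax=None):
    """Weekly percent-area-affected curve with its OLS trend line."""
    import matplotlib.pyplot as plt

    from .trends import linear_trend

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t = np.arange(series.percent_area.size) / 52.0 + series.year[0]
    ax.plot(t, series.percent_area, lw=0.8)
    ok = np.isfinite(series.percent_area)
    if ok.sum() >= 3:
        b, a = linear_trend(t[ok], series.percent_area[ok])
        ax.plot(t, a + b * t, "r--", lw=1.2, label=f"{b:+.3f} %/yr")
        ax.legend(frameon=False)
    ax.set_xlabel("year")
    ax.set_ylabel("% area")
    ax.set_title(series.label)
    return ax


def plot_coherence(result: CoherenceResult, ax=None,
                   coherence_threshold: float = 0.5,
                   arrow_stride: tuple[int, int] = (6, 26)):
    """Time–scale coherence map with COI shading, significance contour
    and phase arrows (drawn only where coherence exceeds the threshold)."""
    import matplotlib.pyplot as plt

    if result.coherence is None:
        raise ValueError("result carries no coherence (use wtc)")
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    t = result.times
    per = result.periods
    pcm = ax.pcolormesh(t, per, result.coherence, vmin=0, vmax=1,
                        shading="auto", cmap="viridis")
    plt.colorbar(pcm, ax=ax, label="coherence $R^2$")
    if result.significance is not None and result.significance.any():
        ax.contour(t, per, result.significance.astype(float), levels=[0.5],
                   colors="k", linewidths=1.5)
    coi_period = result.coi_scale * per[0] / result.scales[0]
    ax.fill_between(t, coi_period, per.max(), color="w", alpha=0.4,
                    hatch="x", edgecolor="gray", linewidth=0)
    js, ts = arrow_stride
    sel = np.zeros_like(result.coherence, dtype=bool)
    sel[::js, ::ts] = True
    sel &= result.coherence > coherence_threshold
    sel &= result.in_coi()
    jj, tt = np.nonzero(sel)
    if jj.size:
        ax.quiver(t[tt], per[jj], np.cos(result.phase[sel]),
                  np.sin(result.phase[sel]), pivot="mid", scale=30,
                  width=0.003)
    ax.set_yscale("log", base=2)
    ax.set_ylim(per.max(), per.min())
    ax.set_xlabel("time")
    ax.set_ylabel("period")
    return ax
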