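"""Smoothed fields (SMN/SMT) and the normalized indices VCI, TCI, VHI.

The vegetation condition index rescales smoothed NDVI between its
multi-year extremes, the temperature condition index does the same for
brightness temperature with reversed orientation (hot ⇒ stressed ⇒ low),
and the vegetation health index is their convex combination::

    VCI = 100 (SMN − SMN_min) / (SMN_max − SMN_min)
    TCI = 100 (SMT_max − SMT) / (SMT_max − SMT_min)
    VHI = a VCI + (1 − a) TCI,    a ∈ [0, 1], default 0.5

Extrema are keyed per calendar week by default (the seasonal-anomaly
reading of "multi-year absolute maximum and minimum"); a whole-record
alternative is available via ``per_week=False``.

The operational product's empirical noise removal is proprietary; the
smoother here is a documented stand-in: median-of-3 despiking followed by
a centred triangular-weight moving average (default window 5 weeks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cube import WEEKS_PER_YEAR, WeeklyCube

log = logging.getLogger(__name__)

_SMOOTH_TAG = {"NDVI": "SMN", "BT": "SMT", "SMN": "SMN", "SMT": "SMT"}


@dataclass
class VhiWeights:
    """Share `a` of VCI in the VHI; 1 − a goes to TCI."""

    a: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("weight a must be in [0, 1]")


@dataclass
class ClimatologyExtrema:
    """Per-pixel, per-calendar-week multi-year extrema of SMN or SMT.

    Arrays have shape (52, n_lat, n_lon); ``degenerate`` flags pixels
    whose envelope collapses (max == min) and must stay masked.
    """

    vmax: np.ndarray
    vmin: np.ndarray
    tag: str
    per_week: bool = True

    def __post_init__(self) -> None:
        self.degenerate = ~(self.vmax > self.vmin)

    @property
    def span(self) -> np.ndarray:
        return self.vmax - self.vmin


def smooth_series(raw: WeeklyCube, window_weeks: int = 5) -> WeeklyCube:
    """Temporal noise removal: median-of-3 despike + triangular moving mean.

    The triangular kernel (window 5: weights 1,2,3,2,1 / 9) is symmetric,
    so linear segments pass through unchanged away from the edges; the
    median-of-3 step removes isolated one-week spikes entirely. Missing
    values are excluded and the kernel renormalized; the validity mask is
    propagated. Pixels with no valid data stay fully masked (logged).
    """
    if window_weeks < 3 or window_weeks % 2 == 0:
        raise ValueError("window_weeks must be odd and >= 3")
    nt = raw.n_time
    if nt < window_weeks:
        raise ValueError("cube shorter than the smoothing window")
    v = raw.masked_values()

    # median-of-3 despiking (endpoints untouched)
    desp = v.copy()
    with np.errstate(invalid="ignore"):
        stack = np.stack([v[:-2], v[1:-1], v[2:]], axis=0)
        all_nan = np.all(np.isnan(stack), axis=0)
        med = np.full(stack.shape[1:], np.nan)
        med[~all_nan] = np.nanmedian(stack[:, ~all_nan], axis=0)
    desp[1:-1] = med

    h = window_weeks // 2
    weights = (h + 1.0) - np.abs(np.arange(-h, h + 1, dtype=float))
    valid = np.isfinite(desp)
    filled = np.where(valid, desp, 0.0)
    num = np.zeros_like(filled)
    den = np.zeros_like(filled)
    for k, w in zip(range(-h, h + 1), weights):
        src = slice(max(0, -k), nt - max(0, k))
        dst = slice(max(0, k), nt - max(0, -k))
        num[dst] += w * filled[src]
        den[dst] += w * valid[src]
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / den, np.nan)

    out_mask = raw.mask & np.isfinite(sm)
    dead = ~np.any(out_mask, axis=0)
    if np.any(dead):
        log.warning("%d pixels have no valid data after smoothing",
                    int(dead.sum()))
    out = raw.with_values(np.where(out_mask, sm, np.nan),
                          tag=_SMOOTH_TAG.get(raw.tag, raw.tag),
                          mask=out_mask)
    out.attrs["smoother"] = f"median3+triangular{window_weeks}"
    return out


def climatology_extrema(smoothed: WeeklyCube,
                        per_week: bool = True) -> ClimatologyExtrema:
    """Multi-year max/min of a smoothed cube, per pixel.

    With ``per_week=True`` (default) extrema are taken separately for each
    calendar week across years; with ``per_week=False`` a single
    whole-record envelope is used for every week.
    """
    if smoothed.years.size < 3:
        raise ValueError("climatology needs at least 3 distinct years")
    ny, nx = smoothed.grid_shape
    v = smoothed.masked_values()
    vmax = np.full((WEEKS_PER_YEAR, ny, nx), np.nan)
    vmin = np.full((WEEKS_PER_YEAR, ny, nx), np.nan)
    with np.errstate(invalid="ignore"):
        if per_week:
            for w in range(1, WEEKS_PER_YEAR + 1):
                sel = smoothed.week == w
                if not np.any(sel):
                    continue
                block = v[sel].reshape(sel.sum(), -1)
                any_valid = np.any(np.isfinite(block), axis=0)
                vmax[w - 1].flat[any_valid] = np.nanmax(
                    block[:, any_valid], axis=0)
                vmin[w - 1].flat[any_valid] = np.nanmin(
                    block[:, any_valid], axis=0)
        else:
            flat = v.reshape(smoothed.n_time, -1)
            any_valid = np.any(np.isfinite(flat), axis=0)
            gmax = np.full(ny * nx, np.nan)
            gmin = np.full(ny * nx, np.nan)
            gmax[any_valid] = np.nanmax(flat[:, any_valid], axis=0)
            gmin[any_valid] = np.nanmin(flat[:, any_valid], axis=0)
            vmax[:] = gmax.reshape(ny, nx)[None]
            vmin[:] = gmin.reshape(ny, nx)[None]
    return ClimatologyExtrema(vmax, vmin, tag=smoothed.tag, per_week=per_week)


def _rescale(cube: WeeklyCube, extrema: ClimatologyExtrema, reverse: bool,
             tag: str) -> WeeklyCube:
    wk = cube.week - 1
    vmax, vmin = extrema.vmax[wk], extrema.vmin[wk]
    span = vmax - vmin
    degen = extrema.degenerate[wk]
    v = cube.masked_values()
    # divide before scaling so envelope endpoints land on 0/100 exactly
    with np.errstate(invalid="ignore", divide="ignore"):
        if reverse:
            idx = ((vmax - v) / span) * 100.0
        else:
            idx = ((v - vmin) / span) * 100.0
    idx[degen] = np.nan
    n_clipped = int(np.count_nonzero((idx < 0.0) | (idx > 100.0)))
    if n_clipped:
        log.info("%s: %d out-of-envelope values clipped to [0, 100]",
                 tag, n_clipped)
    idx = np.clip(idx, 0.0, 100.0)
    out_mask = cube.mask & np.isfinite(idx)
    out = cube.with_values(np.where(out_mask, idx, np.nan), tag=tag,
                           mask=out_mask)
    out.attrs["n_clipped"] = n_clipped
    return out


def compute_vci(smn: WeeklyCube, extrema: ClimatologyExtrema) -> WeeklyCube:
    """VCI = 100 (SMN − SMN_min)/(SMN_max − SMN_min), in [0, 100].

    Degenerate pixels (flat envelope) are masked; values outside the
    climatology envelope are clipped to [0, 100] and counted in
    ``attrs['n_clipped']``.
    """
    return _rescale(smn, extrema, reverse=False, tag="VCI")


def compute_tci(smt: WeeklyCube, extrema: ClimatologyExtrema) -> WeeklyCube:
    """TCI = 100 (SMT_max − SMT)/(SMT_max − SMT_min); hot ⇒ low TCI."""
    return _rescale(smt, extrema, reverse=True, tag="TCI")


def compute_vhi(vci: WeeklyCube, tci: WeeklyCube,
                weights: VhiWeights | float = 0.5) -> WeeklyCube:
    """VHI = a·VCI + (1 − a)·TCI on aligned cubes; masked where either is."""
    if isinstance(weights, (int, float)):
        weights = VhiWeights(float(weights))
    if not vci.aligned_with(tci):
        raise ValueError("VCI and TCI cubes are not aligned")
    a = weights.a
    mask = vci.mask & tci.mask
    vhi = a * vci.masked_values() + (1.0 - a) * tci.masked_values()
    out = vci.with_values(np.where(mask, vhi, np.nan), tag="VHI", mask=mask)
    out.attrs["vhi_weight_a"] = a
    return out
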