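"""Linear and wavelet teleconnection analysis against a climate index.

Two routes to the same question — does ENSO variability project onto the
vegetation-health fields?

* linear: per-pixel Pearson correlation between the index and a VHI cube
  restricted to the growing season, summarized by the fraction of grids
  with positive/negative coefficients;
* nonlinear: continuous Morlet wavelet transform (ω₀ = 6), the cross
  wavelet transform W^XY = W^X · W^Y* (common power and relative phase),
  and squared wavelet coherence

      R²_n(s) = |S(s⁻¹ W^XY_n(s))|² / [ S(s⁻¹|W^X_n(s)|²) · S(s⁻¹|W^Y_n(s)|²) ]

  where S smooths in time with a Gaussian of width s and across scale
  with a boxcar of 0.6 octaves (the Morlet decorrelation length). The
  5% significance level is estimated by Monte-Carlo against red noise:
  AR(1) surrogate pairs matching each series' lag-1 autocorrelation,
  a point being significant when its observed coherence exceeds the 95th
  percentile of the null there. The cone of influence (COI) marks where
  edge effects matter (e-folding convention, √2·s); headline statistics
  are reported for in-COI points only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import signal

from .cube import ClimateIndexSeries, WeeklyCube
from .phenology import GrowingSeason

log = logging.getLogger(__name__)

OMEGA0 = 6.0
#: Fourier period per unit scale for the ω₀ = 6 Morlet
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0 ** 2))
#: scale decorrelation length of the Morlet wavelet, in octaves
SCALE_DECORRELATION = 0.6


# ---------------------------------------------------------------------------
# linear route
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMap:
    """Per-pixel Pearson r against the index, with sign summary (%)."""

    r: np.ndarray
    fraction_positive: float
    fraction_negative: float
    n_pairs: int


def pearson_map(vhi_cube: WeeklyCube, index: ClimateIndexSeries,
                season: GrowingSeason | tuple[int, int] | None = None,
                ) -> CorrelationMap:
    """Per-pixel Pearson correlation between a cube and an index series.

    `index` must share the cube's weekly axis. With `season` given
    (calendar-week or month-free (start, end) pair from
    :func:`~veghealth.phenology.detect_growing_season` applied to weeks),
    only time steps whose calendar week falls inside it are used,
    concatenated across years. Pixels with fewer than 3 valid pairs are
    masked; sign fractions are percentages of valid nonzero-r pixels and
    sum to 100.
    """
    if len(index) != vhi_cube.n_time:
        raise ValueError("index series and cube time axes differ")
    sel = np.ones(vhi_cube.n_time, dtype=bool)
    if season is not None:
        if isinstance(season, GrowingSeason):
            lo, hi = season.start, season.end
        else:
            lo, hi = season
        sel = (vhi_cube.week >= lo) & (vhi_cube.week <= hi)
    v = vhi_cube.masked_values()[sel].reshape(sel.sum(), -1)
    ix = np.asarray(index.values, dtype=float)[sel][:, None]

    valid = np.isfinite(v)
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vm = np.where(valid, v, 0.0)
        xm = np.where(valid, ix, 0.0)
        mv = vm.sum(axis=0) / n
        mx = xm.sum(axis=0) / n
        dv = np.where(valid, v - mv, 0.0)
        dx = np.where(valid, ix - mx, 0.0)
        num = (dv * dx).sum(axis=0)
        den = np.sqrt((dv ** 2).sum(axis=0) * (dx ** 2).sum(axis=0))
        r = num / den
    r[n < 3] = np.nan
    r = r.reshape(vhi_cube.grid_shape)

    finite = np.isfinite(r) & (r != 0)
    total = int(finite.sum())
    fpos = 100.0 * np.count_nonzero(r[finite] > 0) / total if total else np.nan
    fneg = 100.0 * np.count_nonzero(r[finite] < 0) / total if total else np.nan
    return CorrelationMap(r, fpos, fneg, int(sel.sum()))


# ---------------------------------------------------------------------------
# wavelet route
# ---------------------------------------------------------------------------

@dataclass
class WaveletSpectrum:
    """Morlet CWT coefficients W_n(s) on dyadic scales, with COI."""

    coefficients: np.ndarray  # (n_scales, n_time) complex
    scales: np.ndarray        # in time units
    times: np.ndarray
    coi_scale: np.ndarray     # per-time maximum trustworthy scale
    dt: float
    dj: float
    omega0: float
    series: np.ndarray        # the analyzed (detrended/standardized) series

    @property
    def periods(self) -> np.ndarray:
        """Equivalent Fourier periods of the scales."""
        return FOURIER_FACTOR * self.scales

    def in_coi(self) -> np.ndarray:
        """Boolean (scale, time) matrix of edge-trustworthy points."""
        return self.scales[:, None] <= self.coi_scale[None, :]


@dataclass
class CoherenceResult:
    """Cross power / coherence / phase on the (scale, time) plane."""

    scales: np.ndarray
    times: np.ndarray
    coi_scale: np.ndarray
    cross_power: np.ndarray
    phase: np.ndarray
    coherence: np.ndarray | None = None
    significance: np.ndarray | None = None  # bool, 5% vs red noise
    dt: float = 1.0

    @property
    def periods(self) -> np.ndarray:
        return FOURIER_FACTOR * self.scales

    def in_coi(self) -> np.ndarray:
        return self.scales[:, None] <= self.coi_scale[None, :]

    def to_dataset(self) -> xr.Dataset:
        coords = {"scale": self.scales, "time": self.times}
        data = {
            "cross_power": (("scale", "time"), self.cross_power),
            "phase": (("scale", "time"), self.phase),
            "coi_scale": (("time",), self.coi_scale),
        }
        if self.coherence is not None:
            data["coherence"] = (("scale", "time"), self.coherence)
        if self.significance is not None:
            data["significant"] = (("scale", "time"),
                                   self.significance.astype("int8"))
        return xr.Dataset(data, coords=coords,
                          attrs={"period_per_scale": FOURIER_FACTOR})


def dyadic_scales(n: int, dt: float, dj: float = 1.0 / 12.0,
                  s0: float | None = None,
                  max_scale: float | None = None) -> np.ndarray:
    """Dyadic scale ladder s0·2^(j·dj) spanning up to n·dt/3 by default."""
    if s0 is None:
        s0 = 2.0 * dt
    if max_scale is None:
        max_scale = n * dt / 3.0
    j_max = int(np.floor(np.log2(max_scale / s0) / dj))
    return s0 * 2.0 ** (dj * np.arange(j_max + 1))


def _prepare(x: np.ndarray, detrend: bool, standardize: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains NaN/inf; mask or interpolate first")
    if detrend:
        x = signal.detrend(x)
    else:
        x = x - x.mean()
    if standardize:
        sd = x.std()
        if sd > 0:
            x = x / sd
    return x


class _MorletEngine:
    """Precomputed FFT filters for repeated CWT/coherence on one geometry."""

    def __init__(self, n: int, dt: float, scales: np.ndarray,
                 omega0: float = OMEGA0, dj: float = 1.0 / 12.0):
        self.n, self.dt, self.dj, self.omega0 = n, dt, dj, omega0
        self.scales = np.asarray(scales, dtype=float)
        self.nfft = int(2 ** np.ceil(np.log2(n)))
        k = np.fft.fftfreq(self.nfft, d=dt) * 2.0 * np.pi
        pos = k > 0
        norm = np.sqrt(2.0 * np.pi * self.scales[:, None] / dt) * np.pi ** -0.25
        arg = self.scales[:, None] * k[None, :] - omega0
        self.wavelet_hat = np.where(pos[None, :],
                                    norm * np.exp(-0.5 * arg ** 2), 0.0)
        # time-smoothing Gaussian filters (width s), frequency domain
        self.nsm = int(2 ** np.ceil(np.log2(2 * n)))
        ks = np.fft.fftfreq(self.nsm, d=dt) * 2.0 * np.pi
        self.smooth_hat = np.exp(-0.5 * (self.scales[:, None]
                                         * ks[None, :]) ** 2)
        # scale-smoothing boxcar: 0.6 octaves -> 0.6/dj scale bins
        width = max(1, int(round(SCALE_DECORRELATION / dj)))
        if width % 2 == 0:
            width += 1
        self.scale_kernel = np.ones(width) / width
        self.coi_scale = (dt * np.minimum(np.arange(n), n - 1 - np.arange(n))
                          / np.sqrt(2.0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        """CWT coefficients, shape (n_scales, n)."""
        xh = np.fft.fft(x, n=self.nfft)
        return np.fft.ifft(xh[None, :] * self.wavelet_hat, axis=1)[:, :self.n]

    def _smooth_time(self, field: np.ndarray) -> np.ndarray:
        fh = np.fft.fft(field, n=self.nsm, axis=1)
        sm = np.fft.ifft(fh * self.smooth_hat, axis=1)[:, :self.n]
        return sm if np.iscomplexobj(field) else sm.real

    def _smooth_scale(self, field: np.ndarray) -> np.ndarray:
        k = self.scale_kernel
        h = k.size // 2
        padded = np.pad(field, ((h, h), (0, 0)), mode="edge")
        out = np.zeros_like(field)
        for i, w in enumerate(k):
            out += w * padded[i:i + field.shape[0]]
        return out

    def smooth(self, field: np.ndarray) -> np.ndarray:
        """S = S_scale(S_time(·)): Gaussian in time, boxcar over scale."""
        return self._smooth_scale(self._smooth_time(field))

    def coherence(self, wx: np.ndarray, wy: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
        """(R², smoothed cross spectrum) from two coefficient matrices."""
        sinv = 1.0 / self.scales[:, None]
        sxx = self.smooth(sinv * np.abs(wx) ** 2)
        syy = self.smooth(sinv * np.abs(wy) ** 2)
        sxy = self.smooth(sinv * (wx * np.conj(wy)))
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.abs(sxy) ** 2 / (sxx * syy)
        return r2, sxy


def cwt(x: np.ndarray, dt: float = 1.0, dj: float = 1.0 / 12.0,
        s0: float | None = None, max_scale: float | None = None,
        omega0: float = OMEGA0, detrend: bool = True,
        standardize: bool = True) -> WaveletSpectrum:
    """Continuous Morlet wavelet transform on dyadic scales.

    The series is linearly detrended and standardized by default, then
    zero-padded to the next power of two; the COI follows the e-folding
    convention (trustworthy scales ≤ distance-to-edge/√2).
    """
    x = _prepare(x, detrend, standardize)
    n = x.size
    if n < 32:
        raise ValueError("need at least 32 samples for a useful transform")
    scales = dyadic_scales(n, dt, dj, s0, max_scale)
    eng = _MorletEngine(n, dt, scales, omega0, dj)
    return WaveletSpectrum(eng.transform(x), scales,
                           np.arange(n) * dt, eng.coi_scale,
                           dt, dj, omega0, x)


def xwt(x_spec: WaveletSpectrum, y_spec: WaveletSpectrum,
        n_surrogates: int = 0, rng_seed: int = 0,
        sig_level: float = 0.95) -> CoherenceResult:
    """Cross wavelet transform W^XY = W^X · W^Y*.

    Cross power is |W^XY| and phase its argument. With
    ``n_surrogates > 0`` a Monte-Carlo red-noise test marks points whose
    cross power exceeds the null's `sig_level` quantile.
    """
    if (x_spec.scales.shape != y_spec.scales.shape
            or not np.allclose(x_spec.scales, y_spec.scales)
            or x_spec.coefficients.shape != y_spec.coefficients.shape):
        raise ValueError("spectra have mismatching scale/time axes")
    wxy = x_spec.coefficients * np.conj(y_spec.coefficients)
    result = CoherenceResult(
        scales=x_spec.scales.copy(), times=x_spec.times.copy(),
        coi_scale=x_spec.coi_scale.copy(),
        cross_power=np.abs(wxy), phase=np.angle(wxy), dt=x_spec.dt)
    if n_surrogates > 0:
        eng = _MorletEngine(x_spec.series.size, x_spec.dt, x_spec.scales,
                            x_spec.omega0, x_spec.dj)
        rng = np.random.default_rng(rng_seed)
        ax = estimate_ar1(x_spec.series)
        ay = estimate_ar1(y_spec.series)
        exceed = np.zeros_like(result.cross_power, dtype=np.int32)
        for _ in range(n_surrogates):
            sx = _ar1_surrogate(rng, eng.n, ax)
            sy = _ar1_surrogate(rng, eng.n, ay)
            null = np.abs(eng.transform(sx) * np.conj(eng.transform(sy)))
            exceed += null >= result.cross_power
        result.significance = exceed < (1.0 - sig_level) * n_surrogates
    return result


def estimate_ar1(x: np.ndarray) -> float:
    """Lag-1 autocorrelation; non-stationary estimates clamp to 0.99."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = np.dot(x, x)
    if denom == 0:
        return 0.0
    r = float(np.dot(x[:-1], x[1:]) / denom)
    if r >= 1.0:
        log.warning("lag-1 autocorrelation >= 1; clamping to 0.99")
        return 0.99
    return r


def _ar1_surrogate(rng: np.random.Generator, n: int, a: float) -> np.ndarray:
    eps = rng.standard_normal(n)
    if a == 0.0:
        return eps
    x = signal.lfilter([1.0], [1.0, -a], eps)
    sd = x.std()
    return x / sd if sd > 0 else x


def wtc(x: np.ndarray, y: np.ndarray, dt: float = 1.0,
        dj: float = 1.0 / 12.0, s0: float | None = None,
        max_scale: float | None = None, omega0: float = OMEGA0,
        n_surrogates: int = 300, rng_seed: int = 0,
        sig_level: float = 0.95, detrend: bool = True) -> CoherenceResult:
    """Squared wavelet coherence with Monte-Carlo red-noise significance.

    Coherence is the smoothed-cross-spectrum ratio R²_n(s) ∈ [0, 1];
    phase comes from the smoothed cross spectrum. Significance: AR(1)
    surrogate pairs matching each input's lag-1 autocorrelation are run
    through the identical estimator and a point is flagged when fewer
    than (1 − sig_level) of the null values reach its observed coherence
    (equivalently, observed R² above the null's `sig_level` quantile).
    """
    xs = _prepare(x, detrend, True)
    ys = _prepare(y, detrend, True)
    if xs.size != ys.size:
        raise ValueError("series lengths differ")
    n = xs.size
    if n < 32:
        raise ValueError("need at least 32 samples")
    scales = dyadic_scales(n, dt, dj, s0, max_scale)
    eng = _MorletEngine(n, dt, scales, omega0, dj)
    wx, wy = eng.transform(xs), eng.transform(ys)
    r2, sxy = eng.coherence(wx, wy)
    result = CoherenceResult(
        scales=scales, times=np.arange(n) * dt, coi_scale=eng.coi_scale,
        cross_power=np.abs(wx * np.conj(wy)), phase=np.angle(sxy),
        coherence=r2, dt=dt)
    if n_surrogates > 0:
        rng = np.random.default_rng(rng_seed)
        ax, ay = estimate_ar1(xs), estimate_ar1(ys)
        exceed = np.zeros_like(r2, dtype=np.int32)
        for _ in range(n_surrogates):
            swx = eng.transform(_ar1_surrogate(rng, n, ax))
            swy = eng.transform(_ar1_surrogate(rng, n, ay))
            null_r2, _ = eng.coherence(swx, swy)
            exceed += null_r2 >= r2
        result.significance = exceed < (1.0 - sig_level) * n_surrogates
    return result


def dominant_phase(result: CoherenceResult,
                   coherence_threshold: float = 0.5) -> float:
    """Circular-mean phase over in-COI points with coherence above threshold.

    Phase arrows are conventionally drawn only where coherence exceeds
    0.5; this returns their mean direction in (−π, π] (NaN when no point
    qualifies). In-phase ⇒ ≈0, anti-phase ⇒ ≈±π.
    """
    if result.coherence is None:
        raise ValueError("result carries no coherence (use wtc)")
    sel = result.in_coi() & (result.coherence > coherence_threshold)
    if not sel.any():
        return float("nan")
    z = np.exp(1j * result.phase[sel]).mean()
    return float(np.angle(z))
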