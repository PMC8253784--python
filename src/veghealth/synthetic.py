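"""Synthetic weekly NDVI/BT cubes and an ENSO-like index.

The generator emulates the statistical structure of a blended AVHRR/VIIRS
weekly vegetation-health product over a mid-latitude agricultural region:
a single-harmonic seasonal cycle (NDVI winter ≈0.11, early-August peak
≈0.40; BT mean ≈12 °C), per-pixel AR(1) interannual noise, optional linear
trends, embedded multi-week drought episodes (NDVI depressed, BT elevated),
a missing-data mask, and an ENSO-like index whose interannual variability
can be coupled into the temperature field. It is the ground truth every
downstream stage is tested against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cube import WEEKS_PER_YEAR, ClimateIndexSeries, WeeklyCube, weekly_axis

log = logging.getLogger(__name__)

#: calendar week (1..52) of the NDVI seasonal maximum (early August)
NDVI_PEAK_WEEK = 32
#: calendar week of the BT seasonal maximum (mid-summer)
BT_PEAK_WEEK = 28


@dataclass
class SyntheticConfig:
    """Conditions of the emulated 1982–2016, 16-km weekly product.

    Grid and record length default to the Jing-Jin-Ji window
    (36.02–42.62 °N, 113.06–119.88 °E at 16 km ≈ 46×38 pixels, 35 years).
    Seasonal NDVI defaults reproduce a winter floor of ≈0.11 and an
    August peak of ≈0.40. Noise and autocorrelation magnitudes are not
    observable from the published record; the defaults are one fixed,
    field-plausible choice (see docs/methods.md).
    """

    n_years: int = 35
    n_lat: int = 46
    n_lon: int = 38
    start_year: int = 1982
    lat_bounds: tuple[float, float] = (36.02, 42.62)
    lon_bounds: tuple[float, float] = (113.06, 119.88)
    seasonal_ndvi_baseline: float = 0.255
    seasonal_ndvi_amplitude: float = 0.145
    seasonal_bt_mean: float = 12.0
    seasonal_bt_amplitude: float = 16.5
    noise_ar1_coeff: float = 0.6
    noise_sd_ndvi: float = 0.02
    noise_sd_bt: float = 1.0
    trend_ndvi_per_year: float = 0.0
    trend_bt_per_year: float = 0.0
    enso_coupling_bt: float = 0.0
    enso_ar1: float = 0.95
    enso_period_years: float = 4.0
    enso_amplitude: float = 1.0
    enso_noise_sd: float = 0.1
    missing_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3 (climatology needs "
                             "multiple years)")
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must contain at least one pixel")
        if not (0.0 <= self.noise_ar1_coeff < 1.0):
            raise ValueError("noise_ar1_coeff must be in [0, 1)")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")

    @property
    def n_weeks(self) -> int:
        return self.n_years * WEEKS_PER_YEAR


@dataclass
class DroughtEpisodeSpec:
    """A multi-week drought anomaly embedded into the synthetic fields.

    ``start_week_index``/``end_week_index`` are 0-based global week
    indices (inclusive). ``spatial_extent`` is the fraction of pixels
    affected; the affected set is drawn reproducibly from the run seed.
    """

    start_week_index: int
    end_week_index: int
    ndvi_depression: float = 0.15
    bt_elevation: float = 3.0
    spatial_extent: float = 1.0

    def __post_init__(self) -> None:
        if self.start_week_index > self.end_week_index:
            raise ValueError("episode start must not exceed end")
        if self.ndvi_depression < 0 or self.bt_elevation < 0:
            raise ValueError("depression/elevation must be >= 0")
        if not (0.0 <= self.spatial_extent <= 1.0):
            raise ValueError("spatial_extent must be in [0, 1]")

    @property
    def duration_weeks(self) -> int:
        return self.end_week_index - self.start_week_index + 1


def seasonal_cycle(weeks: np.ndarray, baseline: float, amplitude: float,
                   peak_week: int) -> np.ndarray:
    """Single annual harmonic peaking at `peak_week`."""
    return baseline + amplitude * np.cos(
        2.0 * np.pi * (weeks - peak_week) / WEEKS_PER_YEAR)


def _ar1_noise(rng: np.random.Generator, shape: tuple, ar1: float,
               sd: float) -> np.ndarray:
    """AR(1) noise along axis 0 with stationary standard deviation `sd`."""
    if sd == 0.0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - ar1 ** 2)
    eps = rng.normal(0.0, innov_sd, size=shape)
    out = np.empty(shape)
    out[0] = rng.normal(0.0, sd, size=shape[1:])
    for t in range(1, shape[0]):
        out[t] = ar1 * out[t - 1] + eps[t]
    return out


def generate_enso_like(n_weeks: int, ar1: float = 0.95,
                       periodic_component: tuple[float, float] = (4.0, 1.0),
                       noise_sd: float = 0.1,
                       rng_seed: int | np.random.Generator = 0,
                       ) -> ClimateIndexSeries:
    """Zero-mean ENSO-like weekly index: AR(1) noise + interannual sinusoid.

    Parameters
    ----------
    periodic_component : (period_years, amplitude)
        Deterministic sinusoid placing power in the 2–7-year ENSO band.
    """
    if n_weeks < 2 * WEEKS_PER_YEAR:
        raise ValueError("need at least two years (104 weeks) of index")
    if ar1 >= 1.0:
        raise ValueError("ar1 must be < 1 (stationarity)")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    period_years, amplitude = periodic_component
    t = np.arange(n_weeks)
    series = np.zeros(n_weeks)
    if amplitude != 0.0:
        series += amplitude * np.sin(
            2.0 * np.pi * t / (period_years * WEEKS_PER_YEAR))
    if noise_sd > 0.0:
        sd = noise_sd / np.sqrt(1.0 - ar1 ** 2) if ar1 > 0 else noise_sd
        series += _ar1_noise(rng, (n_weeks, 1), ar1, sd)[:, 0]
    return ClimateIndexSeries(values=series - series.mean())


def generate_fields(config: SyntheticConfig,
                    episodes: list[DroughtEpisodeSpec] | None = None,
                    ) -> tuple[WeeklyCube, WeeklyCube, ClimateIndexSeries]:
    """Generate (NDVI cube, BT cube, ENSO-like index) under `config`.

    Per-pixel series are seasonal harmonic + linear trend + AR(1) noise
    + episode anomalies (+ ENSO coupling for BT); NDVI is clipped to
    [−1, 1] (clip count recorded in ``attrs['n_clipped']``). Identical
    config and seed give bit-identical output; episodes and the missing
    mask draw from independent seed streams, so adding an episode does
    not perturb the noise realisation.
    """
    episodes = list(episodes or [])
    nt, ny, nx = config.n_weeks, config.n_lat, config.n_lon
    for ep in episodes:
        if ep.start_week_index < 0 or ep.end_week_index >= nt:
            raise ValueError(
                f"episode weeks [{ep.start_week_index}, {ep.end_week_index}] "
                f"outside record of {nt} weeks")

    ss = np.random.SeedSequence(config.rng_seed)
    rng_ndvi, rng_bt, rng_enso, rng_episode, rng_mask = (
        np.random.default_rng(s) for s in ss.spawn(5))

    year, week = weekly_axis(config.start_year, config.n_years)
    t_years = np.arange(nt) / WEEKS_PER_YEAR

    enso = generate_enso_like(
        nt, ar1=config.enso_ar1,
        periodic_component=(config.enso_period_years, config.enso_amplitude),
        noise_sd=config.enso_noise_sd, rng_seed=rng_enso)
    enso.year, enso.week = year.copy(), week.copy()

    ndvi = seasonal_cycle(week.astype(float), config.seasonal_ndvi_baseline,
                          config.seasonal_ndvi_amplitude, NDVI_PEAK_WEEK)
    bt = seasonal_cycle(week.astype(float), config.seasonal_bt_mean,
                        config.seasonal_bt_amplitude, BT_PEAK_WEEK)
    ndvi = ndvi + config.trend_ndvi_per_year * t_years
    bt = bt + config.trend_bt_per_year * t_years
    ndvi = np.broadcast_to(ndvi[:, None, None], (nt, ny, nx)).copy()
    bt = np.broadcast_to(bt[:, None, None], (nt, ny, nx)).copy()

    ndvi += _ar1_noise(rng_ndvi, (nt, ny, nx), config.noise_ar1_coeff,
                       config.noise_sd_ndvi)
    bt += _ar1_noise(rng_bt, (nt, ny, nx), config.noise_ar1_coeff,
                     config.noise_sd_bt)
    if config.enso_coupling_bt != 0.0:
        bt += config.enso_coupling_bt * enso.values[:, None, None]

    for ep in episodes:
        n_aff = int(round(ep.spatial_extent * ny * nx))
        flat = rng_episode.permutation(ny * nx)[:n_aff]
        iy, ix = np.unravel_index(flat, (ny, nx))
        sl = slice(ep.start_week_index, ep.end_week_index + 1)
        ndvi[sl, iy, ix] -= ep.ndvi_depression
        bt[sl, iy, ix] += ep.bt_elevation

    n_clipped = int(np.count_nonzero((ndvi < -1.0) | (ndvi > 1.0)))
    if n_clipped:
        log.warning("NDVI clipped to [-1, 1] at %d cells", n_clipped)
    ndvi = np.clip(ndvi, -1.0, 1.0)

    mask = np.ones((nt, ny, nx), dtype=bool)
    n_missing = int(round(config.missing_fraction * mask.size))
    if n_missing:
        flat = rng_mask.choice(mask.size, size=n_missing, replace=False)
        mask.flat[flat] = False

    lat = np.linspace(config.lat_bounds[1], config.lat_bounds[0], ny)
    lon = np.linspace(config.lon_bounds[0], config.lon_bounds[1], nx)
    attrs = {"rng_seed": config.rng_seed, "n_clipped": n_clipped}
    ndvi_cube = WeeklyCube(ndvi, year, week, mask.copy(), tag="NDVI",
                           lat=lat, lon=lon, attrs=dict(attrs))
    bt_cube = WeeklyCube(bt, year, week, mask.copy(), tag="BT",
                         lat=lat, lon=lon, attrs={"rng_seed": config.rng_seed})
    return ndvi_cube, bt_cube, enso


def episode_pixels(config: SyntheticConfig, episode_index: int,
                   episodes: list[DroughtEpisodeSpec]) -> np.ndarray:
    """Boolean (lat, lon) map of pixels hit by episode `episode_index`.

    Replays the episode seed stream, so it matches ``generate_fields``
    for the same config and episode list.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    rng_episode = np.random.default_rng(ss.spawn(5)[3])
    ny, nx = config.n_lat, config.n_lon
    hit = np.zeros((ny, nx), dtype=bool)
    for i, ep in enumerate(episodes):
        n_aff = int(round(ep.spatial_extent * ny * nx))
        flat = rng_episode.permutation(ny * nx)[:n_aff]
        if i == episode_index:
            hit.flat[flat] = True
            break
    return hit
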