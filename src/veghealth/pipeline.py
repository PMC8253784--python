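"""End-to-end pipeline: simulate → indices → drought → trends → teleconnection.

``run_pipeline`` executes every stage on a synthetic record, writes all
products (NetCDF cubes, CSV series, JSON summaries) into an output
directory, and records a JSON run manifest (package version, seed, full
config, clip counters, warnings, product list) so any run is
reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, drought, indices, phenology, synthetic, teleconnection, trends
from .io import write_cube, write_extrema

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration for a full synthetic-data run."""

    synthetic: synthetic.SyntheticConfig = dataclasses.field(
        default_factory=synthetic.SyntheticConfig)
    episodes: list[synthetic.DroughtEpisodeSpec] = dataclasses.field(
        default_factory=list)
    vhi_weight_a: float = 0.5
    smoother_window: int = 5
    climatology_per_week: bool = True
    event_threshold: float = 40.0
    wavelet_surrogates: int = 300
    wavelet_seed: int = 0
    out_dir: str = "veghealth_out"

    def __post_init__(self) -> None:
        indices.VhiWeights(self.vhi_weight_a)  # range check
        if self.smoother_window < 3 or self.smoother_window % 2 == 0:
            raise ValueError("smoother_window must be odd and >= 3")
        if self.wavelet_surrogates < 0:
            raise ValueError("wavelet_surrogates must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = synthetic.SyntheticConfig(**raw.pop("synthetic", {}))
        eps = [synthetic.DroughtEpisodeSpec(**e)
               for e in raw.pop("episodes", [])]
        return cls(synthetic=syn, episodes=eps, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: PipelineConfig,
                 seed: int | None = None) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    if seed is not None:
        config = dataclasses.replace(
            config,
            synthetic=dataclasses.replace(config.synthetic, rng_seed=seed),
            wavelet_seed=seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    products: list[str] = []
    warnings: list[str] = []

    def _save(name: str, writer) -> None:
        writer(out / name)
        products.append(name)

    log.info("stage: synthetic data")
    ndvi, bt, enso = synthetic.generate_fields(config.synthetic,
                                               config.episodes)
    if ndvi.attrs.get("n_clipped"):
        warnings.append(f"NDVI clipped at {ndvi.attrs['n_clipped']} cells")
    _save("ndvi.nc", lambda p: write_cube(ndvi, p))
    _save("bt.nc", lambda p: write_cube(bt, p))
    _save("enso_index.csv", enso.to_csv)

    log.info("stage: indices")
    smn = indices.smooth_series(ndvi, config.smoother_window)
    smt = indices.smooth_series(bt, config.smoother_window)
    extrema_n = indices.climatology_extrema(smn, config.climatology_per_week)
    extrema_t = indices.climatology_extrema(smt, config.climatology_per_week)
    vci = indices.compute_vci(smn, extrema_n)
    tci = indices.compute_tci(smt, extrema_t)
    vhi = indices.compute_vhi(vci, tci, config.vhi_weight_a)
    _save("extrema_smn.nc", lambda p: write_extrema(extrema_n, p))
    _save("vci.nc", lambda p: write_cube(vci, p))
    _save("tci.nc", lambda p: write_cube(tci, p))
    _save("vhi.nc", lambda p: write_cube(vhi, p))

    log.info("stage: phenology")
    clim = np.full(52, np.nan)
    smn_reg = smn.regional_mean()
    for w in range(1, 53):
        clim[w - 1] = np.nanmean(smn_reg[smn.week == w])
    season = phenology.detect_growing_season(clim)
    season_dict = (None if season is None else
                   {"start_week": season.start, "end_week": season.end,
                    "duration_weeks": season.duration})
    _save("growing_season.json", lambda p: p.write_text(
        json.dumps(season_dict, indent=2)))

    log.info("stage: drought statistics")
    area = {lbl: drought.percent_area(vhi, lbl).percent_area
            for lbl in drought.CATEGORIES}
    df = pd.DataFrame({"year": vhi.year, "week": vhi.week, **area})
    _save("percent_area.csv", lambda p: df.to_csv(p, index=False))
    vhi_reg = vhi.regional_mean()
    events = drought.detect_events(vhi_reg, config.event_threshold,
                                   week_labels=vhi.global_week + 1)
    ev_df = pd.DataFrame([{"onset_week": e.onset_week, "end_week": e.end_week,
                           "duration_weeks": e.duration_weeks}
                          for e in events])
    _save("drought_events.csv", lambda p: ev_df.to_csv(p, index=False))
    stats_rows = []
    for lbl in drought.CATEGORIES:
        st = drought.category_stats(vhi, lbl)
        stats_rows.append({"category": lbl,
                           "mean_vhi_in_band": st.mean_vhi_in_band,
                           "regional_mean_duration_weeks":
                               st.total_weeks_in_band})
    _save("category_stats.csv", lambda p: pd.DataFrame(stats_rows)
          .to_csv(p, index=False))

    log.info("stage: trends")
    t_years = vhi.time_years
    trend_rows = []
    for lbl in drought.CATEGORIES:
        series = area[lbl]
        ok = np.isfinite(series)
        if ok.sum() >= 8:
            res = trends.trend_result(t_years[ok], series[ok])
            trend_rows.append({"category": lbl, **dataclasses.asdict(res)})
    _save("area_trends.csv", lambda p: pd.DataFrame(trend_rows)
          .to_csv(p, index=False))

    log.info("stage: teleconnection")
    season_weeks = ((season.start, season.end) if season is not None
                    else None)
    tci_map = teleconnection.pearson_map(tci, enso, season=season_weeks)
    corr = {"tci_fraction_positive": tci_map.fraction_positive,
            "tci_fraction_negative": tci_map.fraction_negative,
            "n_pairs": tci_map.n_pairs}
    _save("correlation_summary.json", lambda p: p.write_text(
        json.dumps(corr, indent=2)))
    tci_reg = tci.regional_mean()
    gap = ~np.isfinite(tci_reg)
    if gap.any() and (~gap).sum() >= 2:
        # weeks with no valid pixel: bridge by linear interpolation so the
        # transform sees a gapless series
        warnings.append(f"interpolated {int(gap.sum())} all-masked weeks "
                        "in regional TCI before wavelet analysis")
        idx = np.arange(tci_reg.size)
        tci_reg[gap] = np.interp(idx[gap], idx[~gap], tci_reg[~gap])
    if np.all(np.isfinite(tci_reg)) and tci_reg.size >= 32:
        coh = teleconnection.wtc(tci_reg, enso.values,
                                 dt=1.0 / 52.0,
                                 n_surrogates=config.wavelet_surrogates,
                                 rng_seed=config.wavelet_seed)
        _save("wtc_tci_enso.nc", lambda p: coh.to_dataset()
              .to_netcdf(p, engine="scipy"))
    else:
        warnings.append("regional TCI unusable for wavelet analysis; "
                        "coherence stage skipped")

    manifest = {
        "package": "veghealth",
        "version": __version__,
        "seed": config.synthetic.rng_seed,
        "config": config.to_dict(),
        "n_clipped_ndvi": int(ndvi.attrs.get("n_clipped", 0)),
        "n_clipped_vci": int(vci.attrs.get("n_clipped", 0)),
        "n_clipped_tci": int(tci.attrs.get("n_clipped", 0)),
        "warnings": warnings,
        "products": products,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
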