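"""Drought classification, percent-area statistics and event detection.

Vegetation/drought condition bands on the VHI (or VCI/TCI) scale:

===========  ============  =======================================
label        VHI interval  meaning
===========  ============  =======================================
D4           [0, 5)        exceptional drought
D3-D4        [0, 15)       extreme-to-exceptional
D2-D4        [0, 25)       severe-to-exceptional
D1-D4        [0, 35)       moderate-to-exceptional
stress       [0, 40)       vegetation stress
normal       [40, 60]      normal condition
favorable    (60, 100]     favorable condition
===========  ============  =======================================

The drought classes are cumulative (nested) intervals, so their
percent-area series satisfy D4 ≤ D3-D4 ≤ D2-D4 ≤ D1-D4 ≤ stress at every
week, and stress/normal/favorable partition [0, 100]. Values of exactly
40 and 60 are conventionally assigned to "normal" (the published bands
leave them open); the closure is configurable by building custom
:class:`ConditionCategory` objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import WeeklyCube

DEFAULT_EVENT_THRESHOLD = 40.0


@dataclass(frozen=True)
class ConditionCategory:
    """A half-open/closed VHI interval with a label."""

    label: str
    vhi_low: float
    vhi_high: float
    low_inclusive: bool = True
    high_inclusive: bool = False

    def contains(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        lo = v >= self.vhi_low if self.low_inclusive else v > self.vhi_low
        hi = v <= self.vhi_high if self.high_inclusive else v < self.vhi_high
        return lo & hi


CATEGORIES: dict[str, ConditionCategory] = {
    "D4": ConditionCategory("D4", 0.0, 5.0),
    "D3-D4": ConditionCategory("D3-D4", 0.0, 15.0),
    "D2-D4": ConditionCategory("D2-D4", 0.0, 25.0),
    "D1-D4": ConditionCategory("D1-D4", 0.0, 35.0),
    "stress": ConditionCategory("stress", 0.0, 40.0),
    "normal": ConditionCategory("normal", 40.0, 60.0, True, True),
    "favorable": ConditionCategory("favorable", 60.0, 100.0, False, True),
}

#: drought classes ordered from most to least intense
DROUGHT_LABELS = ("D4", "D3-D4", "D2-D4", "D1-D4")
#: top-level bands that partition [0, 100]
PARTITION_LABELS = ("stress", "normal", "favorable")


@dataclass
class AreaSeries:
    """Percent of valid pixels inside a band, per week."""

    label: str
    year: np.ndarray
    week: np.ndarray
    percent_area: np.ndarray  # NaN where a week has no valid pixel


@dataclass
class DroughtEvent:
    """A maximal run of weeks with regional VHI below threshold."""

    onset_week: int
    end_week: int

    @property
    def duration_weeks(self) -> int:
        return self.end_week - self.onset_week + 1


@dataclass
class CategoryStats:
    """Mean index value inside a band and the number of weeks spent there."""

    label: str
    mean_vhi_in_band: float  # NaN when the band is never occupied
    total_weeks_in_band: int
    duration_map: np.ndarray | None = None  # per-pixel weeks in band
    mean_map: np.ndarray | None = None      # per-pixel mean in band


def classify(vhi_value: float) -> set[str]:
    """All condition bands containing a VHI value (drought classes nest)."""
    v = float(vhi_value)
    if not (0.0 <= v <= 100.0):
        raise ValueError("VHI value must lie in [0, 100]")
    return {c.label for c in CATEGORIES.values() if c.contains(v)}


def percent_area(vhi: WeeklyCube, band: ConditionCategory | str) -> AreaSeries:
    """Percent of valid pixels in `band` each week.

    The denominator is the number of valid (unmasked) pixels that week;
    weeks with no valid pixel yield NaN.
    """
    if isinstance(band, str):
        band = CATEGORIES[band]
    v = vhi.masked_values().reshape(vhi.n_time, -1)
    valid = np.isfinite(v)
    n_valid = valid.sum(axis=1).astype(float)
    in_band = band.contains(v) & valid
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * in_band.sum(axis=1) / np.where(n_valid > 0, n_valid,
                                                     np.nan)
    return AreaSeries(band.label, vhi.year.copy(), vhi.week.copy(), pct)


def detect_events(regional_vhi: np.ndarray,
                  threshold: float = DEFAULT_EVENT_THRESHOLD,
                  week_labels: np.ndarray | None = None,
                  ) -> list[DroughtEvent]:
    """Maximal runs of consecutive weeks with regional VHI < threshold.

    `week_labels` gives the label reported for each position (defaults to
    1-based week numbers); durations are inclusive, so a drought entered
    in week 23 and last seen in week 32 lasts 10 weeks.
    """
    v = np.asarray(regional_vhi, dtype=float)
    if week_labels is None:
        week_labels = np.arange(1, v.size + 1)
    below = np.isfinite(v) & (v < threshold)
    events: list[DroughtEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8),
                                                   [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        events.append(DroughtEvent(int(week_labels[start]),
                                   int(week_labels[stop - 1])))
    return events


def category_stats(vhi: WeeklyCube | np.ndarray,
                   band: ConditionCategory | str) -> CategoryStats:
    """Mean value and dwell time inside a band.

    For a 1-D regional series: mean of the in-band values and their
    count. For a cube: regional mean over all valid in-band cell-weeks,
    the regional-average per-pixel dwell time, plus per-pixel duration
    and mean maps.
    """
    if isinstance(band, str):
        band = CATEGORIES[band]
    if isinstance(vhi, WeeklyCube):
        v = vhi.masked_values()
        sel = band.contains(v) & np.isfinite(v)
        dur_map = sel.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sums = np.where(sel, v, 0.0).sum(axis=0)
            mean_map = np.where(dur_map > 0, sums / dur_map, np.nan)
        total = int(round(float(dur_map.mean())))
        mean = float(np.where(sel, v, np.nan)[sel].mean()) if sel.any() else float("nan")
        return CategoryStats(band.label, mean, total, dur_map, mean_map)
    v = np.asarray(vhi, dtype=float)
    sel = band.contains(v) & np.isfinite(v)
    mean = float(v[sel].mean()) if sel.any() else float("nan")
    return CategoryStats(band.label, mean, int(sel.sum()))


def early_warning(tci_regional: np.ndarray, vhi_regional: np.ndarray,
                  decline_weeks: int = 4,
                  vhi_threshold: float = DEFAULT_EVENT_THRESHOLD,
                  ) -> list[int]:
    """Pre-drought warning weeks: sustained TCI decline before VHI drops.

    A week is flagged when TCI has declined strictly monotonically over
    the preceding `decline_weeks` steps while regional VHI is still at or
    above `vhi_threshold` (i.e. no drought under way yet). Returned weeks
    are 1-based. Falling canopy-temperature condition several weeks ahead
    of the VHI crossing is the early-warning signal.
    """
    tci = np.asarray(tci_regional, dtype=float)
    vhi = np.asarray(vhi_regional, dtype=float)
    if tci.shape != vhi.shape:
        raise ValueError("TCI and VHI series must be aligned")
    warnings: list[int] = []
    for i in range(decline_weeks, tci.size):
        window = tci[i - decline_weeks:i + 1]
        if np.all(np.diff(window) < 0) and vhi[i] >= vhi_threshold:
            warnings.append(i + 1)
    return warnings
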