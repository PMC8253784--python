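"""Growing-season detection from regional smoothed NDVI.

Fixed-threshold rule: the season begins when regional SMN rises to the
onset threshold (0.20) and stays there for at least two consecutive
steps, and ends at the last step after the seasonal peak with SMN at or
above the senescence threshold (0.25). On a monthly mid-latitude cycle
this yields the familiar April–October, roughly seven-month season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

START_THRESHOLD = 0.20
END_THRESHOLD = 0.25


@dataclass
class GrowingSeason:
    """1-based start/end step (week or month) and inclusive duration."""

    start: int
    end: int

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


def detect_growing_season(smn_regional: np.ndarray,
                          start_threshold: float = START_THRESHOLD,
                          end_threshold: float = END_THRESHOLD,
                          persistence: int = 2) -> GrowingSeason | None:
    """Detect one growing season in a single seasonal cycle of regional SMN.

    Parameters
    ----------
    smn_regional : 1-D array
        One year of regional-mean SMN, weekly (52) or monthly (12).
    persistence : int
        Number of consecutive steps that must sit at/above
        `start_threshold` for the onset to count (guards against a
        single-step false start).

    Returns
    -------
    GrowingSeason with 1-based inclusive indices, or None when the series
    never reaches `start_threshold` persistently (no growing season).
    """
    s = np.asarray(smn_regional, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("need a 1-D series of at least 2 steps")
    n = s.size
    above = s >= start_threshold

    start = None
    for i in range(n):
        run = above[i:i + persistence]
        if run.size == persistence and run.all():
            start = i
            break
    if start is None:
        return None

    peak = int(np.nanargmax(s))
    tail = np.nonzero(s[peak:] >= end_threshold)[0]
    if tail.size == 0:
        end = peak
    else:
        # last step at/above threshold after the peak; searching only
        # past the peak keeps a pre-season blip from ending the season
        end = peak + int(tail[-1])
    end = max(end, start)
    return GrowingSeason(start=start + 1, end=end + 1)
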