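"""Daily activity-onset detection, onset-delay statistics, actograms.

Onset is operationalised as the bin boundary maximising the step-template
contrast S(t) = mean(counts in [t, t+W)) - mean(counts in [t-W, t)) with a
6-h window W, i.e. the transition from a 6-h period of inactivity to a 6-h
period of high activity. The search for day d runs from that day's ZT4 to
the next day's ZT4 so that onsets delayed by a weekend jet-lag shift stay
attributed to their own day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import _circular as circ
from .errors import InvalidArgumentError
from .schedules import MIN_PER_DAY, LightSchedule
from .simulate import ActivityRecording


@dataclass
class OnsetSeries:
    """Per-day activity onsets (ZT hours, NaN = missing) and their signed
    circular delays relative to a baseline mean."""

    animal_id: str
    onsets: np.ndarray
    baseline_mean: float = float("nan")
    delays: Optional[np.ndarray] = None

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        ok = self.onsets[~np.isnan(self.onsets)]
        if np.any((ok < 0) | (ok >= 24)):
            raise InvalidArgumentError("onsets must lie in [0, 24) or be NaN")


@dataclass
class ActogramMatrix:
    """Double-plotted actogram: row d shows day d beside day d+1."""

    values: np.ndarray
    bin_minutes: int

    @property
    def n_days(self) -> int:
        return self.values.shape[0]


class OnsetDetector(BaseEstimator):
    """Step-template onset detector.

    Parameters
    ----------
    window_h : float
        Half-template width W in hours (inactive window before, active
        window after the candidate transition).
    search_start_zt : float
        ZT anchor of each day's search window; day d is searched over
        [ZT ``search_start_zt`` of day d, same time next day).
    min_coverage : float
        Minimum fraction of a day's bins that must be recorded (and not all
        zero) for an onset to be reported; otherwise NaN.
    """

    def __init__(self, window_h: float = 6.0, search_start_zt: float = 4.0,
                 min_coverage: float = 0.5):
        self.window_h = window_h
        self.search_start_zt = search_start_zt
        self.min_coverage = min_coverage

    def detect(self, rec: ActivityRecording, sched: LightSchedule) -> OnsetSeries:
        bin_min = rec.bin_minutes
        win_min = self.window_h * 60.0
        if win_min <= 0 or abs(win_min / bin_min - round(win_min / bin_min)) > 1e-9:
            raise InvalidArgumentError("bin width must divide the template window")
        w = int(round(win_min / bin_min))
        n = rec.n_bins
        if w > n:
            raise InvalidArgumentError("template window longer than recording")
        bpd = rec.bins_per_day
        counts = rec.counts.astype(float)
        csum = np.concatenate(([0.0], np.cumsum(counts)))

        # minutes between recording start and experiment time zero
        start_mod = rec.start.hour * 60 + rec.start.minute
        offset = (start_mod - sched.reference_lights_on) % MIN_PER_DAY

        n_days = min(sched.n_days, (offset + n * bin_min) // MIN_PER_DAY)
        anchor = int(round(self.search_start_zt * 60))
        onsets = np.full(int(n_days), np.nan)

        for d in range(1, int(n_days) + 1):
            day_lo = ((d - 1) * MIN_PER_DAY - offset) / bin_min
            day_hi = (d * MIN_PER_DAY - offset) / bin_min
            lo_bin = max(0, int(np.ceil(day_lo)))
            hi_bin = min(n, int(np.ceil(day_hi)))
            day_slice = counts[lo_bin:hi_bin]
            if day_slice.size < self.min_coverage * bpd or not np.any(day_slice):
                continue

            t0 = ((d - 1) * MIN_PER_DAY + anchor - offset) / bin_min
            best_s, best_t = -np.inf, None
            for t in range(max(1, int(np.ceil(t0))),
                           min(n, int(np.ceil(t0)) + bpd)):
                left_lo = max(0, t - w)
                right_hi = min(n, t + w)
                if t <= left_lo or right_hi <= t:
                    continue
                s = (csum[right_hi] - csum[t]) / (right_hi - t) - (
                    csum[t] - csum[left_lo]
                ) / (t - left_lo)
                if s > best_s:
                    best_s, best_t = s, t
            if best_t is not None:
                onsets[d - 1] = ((offset + best_t * bin_min) % MIN_PER_DAY) / 60.0

        return OnsetSeries(animal_id=rec.animal_id, onsets=onsets)

    def fit(self, rec: ActivityRecording, sched: LightSchedule):
        self.onsets_ = self.detect(rec, sched)
        return self


def detect_onsets(rec: ActivityRecording, sched: LightSchedule,
                  window_h: float = 6.0) -> OnsetSeries:
    """Detect one activity onset per experimental day (see OnsetDetector)."""
    return OnsetDetector(window_h=window_h).detect(rec, sched)


def onset_delays(series: OnsetSeries, baseline_days: Iterable[int]) -> OnsetSeries:
    """Fill the delay statistic: signed circular difference of each day's
    onset from the circular mean onset over ``baseline_days`` (1-based),
    mapped to (-12, +12]; positive = later than baseline."""
    days = [int(d) for d in baseline_days]
    if not days or min(days) < 1 or max(days) > series.onsets.size:
        raise InvalidArgumentError("baseline_days outside recorded days")
    base = series.onsets[[d - 1 for d in days]]
    base = base[~np.isnan(base)]
    if base.size == 0:
        raise InvalidArgumentError("no usable onsets in the baseline window")
    mean = circ.circ_mean(base)
    delays = circ.signed_diff(series.onsets, mean)
    return OnsetSeries(
        animal_id=series.animal_id,
        onsets=series.onsets,
        baseline_mean=mean,
        delays=np.asarray(delays, dtype=float),
    )


def double_plot(rec: ActivityRecording) -> ActogramMatrix:
    """Double-plotted actogram matrix: row d = day d beside day d+1, the
    last row padded with zeros."""
    bpd = rec.bins_per_day
    n_days = rec.n_days
    if n_days < 2:
        raise InvalidArgumentError("double plot needs at least 2 full days")
    values = np.zeros((n_days, 2 * bpd), dtype=rec.counts.dtype)
    for d in range(n_days):
        values[d, :bpd] = rec.counts[d * bpd:(d + 1) * bpd]
        nxt = rec.counts[(d + 1) * bpd:(d + 2) * bpd]
        values[d, bpd:bpd + nxt.size] = nxt
    return ActogramMatrix(values=values, bin_minutes=rec.bin_minutes)
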