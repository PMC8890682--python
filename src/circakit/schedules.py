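"""Light/dark schedules and zeitgeber-time conversion.

A :class:`LightSchedule` is an ordered list of experimental days, each with
absolute lights-on/lights-off times in minutes from the experiment start.
Time zero is day 1's *reference* lights-on (08:00 by convention), which
defines zeitgeber time: ZT0 = lights on, ZT12 = lights off under the normal
12:12 cycle. ZT is always computed against this reference, never against a
shifted light interval, so phase delays on jet-lag days show up as onsets
later than ZT12.

Protocols provided:

* normal LD — lights 08:00-20:00 every day;
* SJL (social jet lag) — baseline LD, then the whole cycle translated
  later by ``delay_h`` (default 6 h) on two consecutive "weekend" days,
  then back to normal LD;
* 6-h advance — from the shift day onward the entire cycle runs
  ``advance_h`` earlier, so the dark period starts earlier while every lit
  day keeps a 12-h photoperiod;
* DD — constant darkness (days with no light interval at all).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .errors import InvalidArgumentError, OutOfRangeError

MIN_PER_DAY = 1440
DEFAULT_LIGHTS_ON = "08:00"
PHOTOPERIOD_MIN = 720  # 12-h light phase


def _parse_clock(clock: Union[str, int, float]) -> int:
    """Parse 'HH:MM' (or a minute count) into minutes past midnight."""
    if isinstance(clock, (int, float)):
        m = int(clock)
    else:
        try:
            hh, mm = clock.split(":")
            m = int(hh) * 60 + int(mm)
        except (ValueError, AttributeError) as exc:
            raise InvalidArgumentError(f"cannot parse clock time {clock!r}") from exc
    if not 0 <= m < MIN_PER_DAY:
        raise InvalidArgumentError(f"clock time {clock!r} outside a day")
    return m


@dataclass(frozen=True)
class DayRecord:
    """One experimental day: light interval in absolute minutes, or DD."""

    day_index: int
    lights_on: Optional[int]  # minutes from experiment start; None on DD days
    lights_off: Optional[int]

    @property
    def is_dd(self) -> bool:
        return self.lights_on is None and self.lights_off is None

    def dark_onset_zt(self) -> Optional[float]:
        """ZT (hours) at which the dark period starts, None for DD days."""
        if self.is_dd:
            return None
        return (self.lights_off % MIN_PER_DAY) / 60.0


@dataclass(frozen=True)
class LightSchedule:
    days: tuple
    reference_lights_on: int = 480  # clock minutes past midnight defining ZT0

    def __post_init__(self):
        if not self.days:
            raise InvalidArgumentError("schedule needs at least one day")
        for i, day in enumerate(self.days):
            if day.day_index != i + 1:
                raise InvalidArgumentError(
                    "day_index must increase from 1 without gaps"
                )
            if day.is_dd:
                continue
            if day.lights_on is None or day.lights_off is None:
                raise InvalidArgumentError(
                    "lit day must set both lights_on and lights_off"
                )
            dur = day.lights_off - day.lights_on
            if not 0 < dur < MIN_PER_DAY:
                raise InvalidArgumentError(
                    f"day {day.day_index}: light interval must have positive "
                    f"duration below 24 h, got {dur} min"
                )

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def span_minutes(self) -> int:
        return self.n_days * MIN_PER_DAY

    def day(self, day_index: int) -> DayRecord:
        if not 1 <= day_index <= self.n_days:
            raise OutOfRangeError(f"day {day_index} outside schedule")
        return self.days[day_index - 1]

    def clock_minutes(self, t_minutes: int) -> int:
        """Wall-clock minute-of-day of an absolute experiment time."""
        return (t_minutes + self.reference_lights_on) % MIN_PER_DAY

    def light_intervals(self):
        """Absolute (start_min, stop_min) light intervals, DD days skipped."""
        return [
            (d.lights_on, d.lights_off) for d in self.days if not d.is_dd
        ]


def make_ld(n_days: int, lights_on_clock: Union[str, int] = DEFAULT_LIGHTS_ON) -> LightSchedule:
    """Normal 12:12 LD schedule, lights on 08:00-20:00 each day."""
    if n_days < 1:
        raise InvalidArgumentError("n_days must be >= 1")
    ref = _parse_clock(lights_on_clock)
    days = tuple(
        DayRecord(d, (d - 1) * MIN_PER_DAY, (d - 1) * MIN_PER_DAY + PHOTOPERIOD_MIN)
        for d in range(1, n_days + 1)
    )
    return LightSchedule(days, reference_lights_on=ref)


def make_sjl(
    n_baseline_days: int = 7,
    delay_h: float = 6.0,
    n_recovery_days: int = 5,
    lights_on_clock: Union[str, int] = DEFAULT_LIGHTS_ON,
) -> LightSchedule:
    """Social-jet-lag schedule: the whole LD cycle is translated later by
    ``delay_h`` on the two days following baseline, then returns to normal.

    With defaults the shifted weekend runs lights 14:00-02:00, i.e. dark
    onset 6 h later than the normal 20:00.
    """
    if not 0 < delay_h <= 12:
        raise InvalidArgumentError("delay_h must be in (0, 12]")
    if n_baseline_days < 1 or n_recovery_days < 0:
        raise InvalidArgumentError("need >= 1 baseline day and >= 0 recovery days")
    ref = _parse_clock(lights_on_clock)
    shift = int(round(delay_h * 60))
    days = []
    total = n_baseline_days + 2 + n_recovery_days
    for d in range(1, total + 1):
        base = (d - 1) * MIN_PER_DAY
        if n_baseline_days < d <= n_baseline_days + 2:
            days.append(DayRecord(d, base + shift, base + shift + PHOTOPERIOD_MIN))
        else:
            days.append(DayRecord(d, base, base + PHOTOPERIOD_MIN))
    return LightSchedule(tuple(days), reference_lights_on=ref)


def make_advance(
    n_baseline_days: int = 7,
    advance_h: float = 6.0,
    n_post_days: int = 7,
    lights_on_clock: Union[str, int] = DEFAULT_LIGHTS_ON,
) -> LightSchedule:
    """Phase-advance schedule: from the shift day onward the whole cycle
    runs ``advance_h`` earlier (dark onset at 14:00 for the 6-h default),
    keeping a 12-h photoperiod on every lit day; the transition night's
    dark period is correspondingly shortened.
    """
    if not 0 < advance_h <= 12:
        raise InvalidArgumentError("advance_h must be in (0, 12]")
    if n_baseline_days < 1 or n_post_days < 1:
        raise InvalidArgumentError("need >= 1 baseline and >= 1 post day")
    ref = _parse_clock(lights_on_clock)
    shift = int(round(advance_h * 60))
    days = []
    total = n_baseline_days + n_post_days
    for d in range(1, total + 1):
        base = (d - 1) * MIN_PER_DAY
        if d <= n_baseline_days:
            days.append(DayRecord(d, base, base + PHOTOPERIOD_MIN))
        else:
            days.append(DayRecord(d, base - shift, base - shift + PHOTOPERIOD_MIN))
    return LightSchedule(tuple(days), reference_lights_on=ref)


def make_dd(n_days: int, lights_on_clock: Union[str, int] = DEFAULT_LIGHTS_ON) -> LightSchedule:
    """Constant-darkness schedule; the reference lights-on still defines ZT0
    (projected zeitgeber time of the preceding entrained cycle)."""
    if n_days < 1:
        raise InvalidArgumentError("n_days must be >= 1")
    ref = _parse_clock(lights_on_clock)
    days = tuple(DayRecord(d, None, None) for d in range(1, n_days + 1))
    return LightSchedule(days, reference_lights_on=ref)


def to_zt(t_minutes: float, sched: LightSchedule) -> float:
    """Convert absolute experiment time (minutes from start, i.e. from day 1's
    reference lights-on) to zeitgeber time in hours.

    Always uses the reference lights-on, never a shifted interval.
    """
    if not 0 <= t_minutes <= sched.span_minutes:
        raise OutOfRangeError(
            f"t={t_minutes} min outside schedule span [0, {sched.span_minutes}]"
        )
    return (t_minutes / 60.0) % 24.0


def from_zt(zt_hours: float, sched: LightSchedule, day_index: int = 1) -> float:
    """Absolute experiment minutes of phase ``zt_hours`` on a given day."""
    sched.day(day_index)  # bounds check
    return (day_index - 1) * MIN_PER_DAY + (zt_hours % 24.0) * 60.0


def clock_to_zt(clock: Union[str, int], sched: LightSchedule) -> float:
    """ZT (hours) of a wall-clock time under the schedule's reference.

    E.g. 17:00 with lights-on 08:00 is ZT9.
    """
    m = _parse_clock(clock)
    return ((m - sched.reference_lights_on) % MIN_PER_DAY) / 60.0


_PROTOCOLS = {"LD", "SJL", "ADVANCE", "DD"}


def load_schedule(source: Union[str, Path, dict]) -> LightSchedule:
    """Build a schedule from a YAML/JSON config file or an equivalent dict.

    Keys: ``protocol`` in {LD, SJL, ADVANCE, DD}, ``baseline_days``,
    ``shift_hours``, ``post_days``, ``lights_on_clock`` (default "08:00").
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        cfg = json.loads(text) if str(source).endswith(".json") else yaml.safe_load(text)
    else:
        cfg = dict(source)
    protocol = str(cfg.get("protocol", "LD")).upper()
    if protocol not in _PROTOCOLS:
        raise InvalidArgumentError(f"unknown protocol {protocol!r}")
    baseline = int(cfg.get("baseline_days", 7))
    shift = float(cfg.get("shift_hours", 6.0))
    post = int(cfg.get("post_days", 5))
    clock = cfg.get("lights_on_clock", DEFAULT_LIGHTS_ON)
    if protocol == "LD":
        return make_ld(baseline, clock)
    if protocol == "SJL":
        return make_sjl(baseline, shift, post, clock)
    if protocol == "ADVANCE":
        return make_advance(baseline, shift, max(post, 1), clock)
    return make_dd(baseline, clock)
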