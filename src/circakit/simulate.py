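"""Synthetic cohort generator: entrainment dynamics and bioluminescence.

The behavioural model is a one-dimensional discrete-time phase map. The
state is the activity-onset phase psi_d (in ZT hours) on experimental day
d. Each day the phase drifts by the intrinsic period error (tau - 24) and
is pulled toward that day's dark onset:

    psi_{d+1} = psi_d + (tau - 24) + Delta,
    Delta     = sign(gap) * min(delta_max_dir, r * |gap|),

where gap is the signed circular difference (dark-onset ZT - psi_d) on the
shorter arc, r is the fractional correction per day, and delta_max_dir is
the direction-specific daily shift limit (delays are easier than advances,
as in rodent re-entrainment). On DD days Delta = 0 and the phase free-runs.

Activity is then emitted as Poisson counts per bin: mean ``lambda_active``
inside the active phase [psi_d + jitter, psi_d + alpha) and ``lambda_rest``
elsewhere. Optional negative masking forces bins that fall in light down to
the rest rate.

The bioluminescence emulator produces the six-point PER2-reporter sampling
design (every 4 h for 24 h starting 17:00): a cosine around an arbitrary
mesor whose acrophase is the organ's baseline phase plus a coupled fraction
of the behavioural phase shift, with multiplicative lognormal noise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _circular as circ
from .errors import InvalidArgumentError
from .schedules import MIN_PER_DAY, DayRecord, LightSchedule, clock_to_zt

START_EPOCH = datetime(2021, 1, 1, 8, 0)  # day 1 lights-on, for CSV timestamps

# Six consecutive samples at 4-h intervals starting 17:00.
BIOLUM_SAMPLE_CLOCKS = ("17:00", "21:00", "01:00", "05:00", "09:00", "13:00")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the entrainment simulator.

    tau               intrinsic free-running period, hours (20-28)
    delta_delay_max   max phase delay per day from light, h/day
    delta_advance_max max phase advance per day from light, h/day
    response_frac     fraction of the remaining phase gap corrected per day
    alpha             active-phase duration, hours
    lambda_active     mean counts per bin during the active phase
    lambda_rest       mean counts per bin at rest
    onset_jitter_sd   SD of Gaussian day-to-day onset jitter, hours
    masking           if True, light forces active bins to the rest rate
    peripheral_delay_h  constant phase delay added to organ acrophases
                        (models diet-induced peripheral delay)
    """

    tau: float = 24.0
    delta_delay_max: float = 3.75
    delta_advance_max: float = 0.7
    response_frac: float = 0.625
    alpha: float = 12.0
    lambda_active: float = 10.0
    lambda_rest: float = 0.5
    onset_jitter_sd: float = 0.25
    masking: bool = False
    peripheral_delay_h: float = 0.0
    mesor_photons: float = 1.0e6
    modality: str = "area_sensor"
    bin_minutes: int = 6
    seed: Optional[int] = None

    def __post_init__(self):
        if not 20.0 <= self.tau <= 28.0:
            raise InvalidArgumentError("tau must lie in [20, 28] h")
        if self.delta_delay_max < 0 or self.delta_advance_max < 0:
            raise InvalidArgumentError("shift limits must be >= 0")
        if not 0.0 < self.alpha < 24.0:
            raise InvalidArgumentError("alpha must lie in (0, 24) h")
        if not self.lambda_active > self.lambda_rest >= 0:
            raise InvalidArgumentError("need lambda_active > lambda_rest >= 0")
        if self.response_frac < 0:
            raise InvalidArgumentError("response_frac must be >= 0")
        if self.modality not in ("area_sensor", "wheel"):
            raise InvalidArgumentError(f"unknown modality {self.modality!r}")


# Calibration notes: the delay limit 3.75 h/day with response fraction
# 0.625 reproduces a first-shift-day (Saturday) onset delay of ~3.75 h and a
# cumulative Sunday delay of ~5.2 h after a 6-h schedule delay; the advance
# limits give non-recovery by the fifth weekday without a wheel (0.7 h/day)
# and recovery on the fifth day with one (1.2 h/day, aided by tau = 23.5).
_PRESETS = {
    "ND_NoWheel": SimConfig(tau=24.0, delta_advance_max=0.7, lambda_active=10.0),
    "ND_Wheel": SimConfig(
        tau=23.5, delta_advance_max=1.2, lambda_active=40.0, modality="wheel"
    ),
    "HFD_NoWheel": SimConfig(
        tau=24.0, delta_advance_max=0.7, lambda_active=10.0, peripheral_delay_h=2.0
    ),
    "HFD_Wheel": SimConfig(
        tau=23.5,
        delta_advance_max=1.2,
        lambda_active=40.0,
        modality="wheel",
        peripheral_delay_h=2.0,
    ),
}


def preset(name: str, **overrides) -> SimConfig:
    """Named parameter set (diet x wheel). Unknown names raise."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


@dataclass
class ActivityRecording:
    """Evenly binned locomotor counts (area sensor or running wheel)."""

    start: datetime
    bin_minutes: int
    counts: np.ndarray
    modality: str = "area_sensor"
    animal_id: str = "animal"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise InvalidArgumentError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bins_per_day(self) -> int:
        return MIN_PER_DAY // self.bin_minutes

    @property
    def n_days(self) -> int:
        return self.n_bins // self.bins_per_day


@dataclass(frozen=True)
class OrganProfile:
    """Peripheral-organ bioluminescence parameters.

    ``coupling`` is the fraction of the behavioural phase shift transmitted
    to the organ clock; 1 means the organ tracks behaviour fully.
    """

    organ: str
    baseline_acrophase: float
    coupling: float = 1.0
    amplitude_pct: float = 20.0
    noise_cv: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.baseline_acrophase < 24.0:
            raise InvalidArgumentError("baseline_acrophase must lie in [0, 24)")
        if not 0.0 <= self.coupling <= 1.0:
            raise InvalidArgumentError("coupling must lie in [0, 1]")
        if self.amplitude_pct < 0 or self.noise_cv < 0:
            raise InvalidArgumentError("amplitude_pct and noise_cv must be >= 0")


# Group-mean acrophases observed under normal LD, by (organ, wheel access).
ORGAN_ACROPHASES = {
    ("kidney", True): 18.8,
    ("kidney", False): 17.5,
    ("liver", True): 19.2,
    ("liver", False): 19.0,
    ("submandibular_gland", True): 19.5,
    ("submandibular_gland", False): 18.9,
}

ORGANS = ("kidney", "liver", "submandibular_gland")


def organ_profile(organ: str, wheel: bool = True, **overrides) -> OrganProfile:
    """Standard profile for one of the three imaged organs."""
    key = (organ, bool(wheel))
    if key not in ORGAN_ACROPHASES:
        raise InvalidArgumentError(f"unknown organ {organ!r}")
    kwargs = dict(organ=organ, baseline_acrophase=ORGAN_ACROPHASES[key])
    kwargs.update(overrides)
    return OrganProfile(**kwargs)


@dataclass
class BioluminescenceSeries:
    """Six-point in vivo photon-rate series for one animal/organ."""

    animal_id: str
    organ: str
    sample_clock_times: Sequence[str]
    photon_rates: np.ndarray
    normalized_pct: Optional[np.ndarray] = None

    def __post_init__(self):
        self.photon_rates = np.asarray(self.photon_rates, dtype=float)
        if len(self.sample_clock_times) != 6 or self.photon_rates.size != 6:
            raise InvalidArgumentError("a series has exactly six samples")
        if self.normalized_pct is not None:
            self.normalized_pct = np.asarray(self.normalized_pct, dtype=float)


def evolve_phase(psi_d: float, sched_day: DayRecord, cfg: SimConfig) -> float:
    """One day of the phase map: intrinsic drift plus bounded light correction.

    The correction pulls the onset phase toward the day's dark onset along
    the shorter circular arc, at ``response_frac`` of the gap per day, capped
    at ``delta_delay_max`` (later) / ``delta_advance_max`` (earlier). DD days
    have no correction.
    """
    psi = circ.wrap(psi_d)
    drift = cfg.tau - 24.0
    target = sched_day.dark_onset_zt()
    if target is None:
        return float(circ.wrap(psi + drift))
    gap = float(circ.signed_diff(target, psi))
    if gap >= 0:
        delta = min(cfg.delta_delay_max, cfg.response_frac * gap)
    else:
        delta = -min(cfg.delta_advance_max, cfg.response_frac * (-gap))
    return float(circ.wrap(psi + drift + delta))


def phase_trajectory(
    sched: LightSchedule, cfg: SimConfig, psi_start: float = 12.0
) -> np.ndarray:
    """Onset phases psi_d for every day of the schedule.

    The animal enters the experiment entrained to the normal cycle
    (psi = ZT12 on the eve of day 1).
    """
    psis = np.empty(sched.n_days)
    psi = psi_start
    for d in range(1, sched.n_days + 1):
        psi = evolve_phase(psi, sched.day(d), cfg)
        psis[d - 1] = psi
    return psis


def simulate_activity(
    sched: LightSchedule,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    animal_id: str = "animal",
) -> ActivityRecording:
    """Generate one animal's binned activity under a light schedule."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    psis = phase_trajectory(sched, cfg)
    jitter = (
        rng.normal(0.0, cfg.onset_jitter_sd, size=sched.n_days)
        if cfg.onset_jitter_sd > 0
        else np.zeros(sched.n_days)
    )
    bins_per_day = MIN_PER_DAY // cfg.bin_minutes
    n_bins = sched.n_days * bins_per_day
    mid_h = (np.arange(n_bins) + 0.5) * cfg.bin_minutes / 60.0  # absolute hours

    lam = np.full(n_bins, cfg.lambda_rest, dtype=float)
    for d in range(sched.n_days):
        onset = d * 24.0 + psis[d] + jitter[d]
        active = (mid_h >= onset) & (mid_h < onset + cfg.alpha)
        lam[active] = cfg.lambda_active

    if cfg.masking:
        lit = np.zeros(n_bins, dtype=bool)
        for on, off in sched.light_intervals():
            lit |= (mid_h >= on / 60.0) & (mid_h < off / 60.0)
        lam[lit] = np.minimum(lam[lit], cfg.lambda_rest)

    counts = rng.poisson(lam)
    return ActivityRecording(
        start=START_EPOCH,
        bin_minutes=cfg.bin_minutes,
        counts=counts,
        modality=cfg.modality,
        animal_id=animal_id,
    )


def simulate_bioluminescence(
    behavior_phase_shift: float,
    profile: OrganProfile,
    cfg: SimConfig,
    sched: LightSchedule,
    rng: Optional[np.random.Generator] = None,
    animal_id: str = "animal",
) -> BioluminescenceSeries:
    """Six-point PER2-reporter series whose true acrophase is the organ
    baseline plus the coupled behavioural shift (plus any diet delay)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    acro = circ.wrap(
        profile.baseline_acrophase
        + profile.coupling * behavior_phase_shift
        + cfg.peripheral_delay_h
    )
    zts = np.array([clock_to_zt(c, sched) for c in BIOLUM_SAMPLE_CLOCKS])
    clean = cfg.mesor_photons * (
        1.0 + profile.amplitude_pct / 100.0 * np.cos(2 * np.pi * (zts - acro) / 24.0)
    )
    if profile.noise_cv > 0:
        sigma = np.sqrt(np.log1p(profile.noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=6)
    else:
        noise = np.ones(6)
    rates = clean * noise
    return BioluminescenceSeries(
        animal_id=animal_id,
        organ=profile.organ,
        sample_clock_times=BIOLUM_SAMPLE_CLOCKS,
        photon_rates=rates,
    )


# ---------------------------------------------------------------------------
# Plain-text I/O


def write_activity_csv(rec: ActivityRecording, path) -> None:
    """CSV with ISO-8601 timestamps and header comment lines recording the
    bin width, modality and animal id."""
    path = Path(path)
    ts = [
        (rec.start + timedelta(minutes=i * rec.bin_minutes)).isoformat()
        for i in range(rec.n_bins)
    ]
    buf = io.StringIO()
    buf.write(f"# bin_minutes={rec.bin_minutes}\n")
    buf.write(f"# modality={rec.modality}\n")
    buf.write(f"# animal_id={rec.animal_id}\n")
    pd.DataFrame({"timestamp": ts, "count": rec.counts}).to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_activity_csv(path) -> ActivityRecording:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#", parse_dates=["timestamp"])
    if df.empty:
        raise InvalidArgumentError(f"{path} holds no samples")
    return ActivityRecording(
        start=df["timestamp"].iloc[0].to_pydatetime(),
        bin_minutes=int(meta.get("bin_minutes", 6)),
        counts=df["count"].to_numpy(),
        modality=meta.get("modality", "area_sensor"),
        animal_id=meta.get("animal_id", path.stem),
    )


def write_awd(rec: ActivityRecording, path) -> None:
    """Actiwatch AWD text: 7 header lines then one count per line."""
    path = Path(path)
    lines = [
        rec.animal_id,
        rec.start.strftime("%d-%b-%Y"),
        rec.start.strftime("%H:%M"),
        str(rec.bin_minutes),
        "0",  # age, unused
        "X0",  # watch serial placeholder
        "M",  # sex placeholder
    ]
    lines += [str(int(c)) for c in rec.counts]
    path.write_text("\n".join(lines) + "\n")


def write_bioluminescence_csv(series_list: Sequence[BioluminescenceSeries], path) -> None:
    rows = []
    for s in series_list:
        for clock, rate in zip(s.sample_clock_times, s.photon_rates):
            rows.append(
                {
                    "animal_id": s.animal_id,
                    "organ": s.organ,
                    "clock_time": clock,
                    "photons_per_min": rate,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bioluminescence_csv(path):
    """Read back one series per (animal_id, organ) group."""
    df = pd.read_csv(path)
    out = []
    for (animal, organ), grp in df.groupby(["animal_id", "organ"], sort=True):
        out.append(
            BioluminescenceSeries(
                animal_id=str(animal),
                organ=str(organ),
                sample_clock_times=list(grp["clock_time"]),
                photon_rates=grp["photons_per_min"].to_numpy(),
            )
        )
    return out
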