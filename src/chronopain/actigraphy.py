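"""Home-cage actigraphy from passive-infrared (PIR) activity streams.

Single-housed animals are sampled every 10 s; an epoch with zero detected
activity is "inactive". Immobility-defined sleep is any maximal run of
inactive epochs lasting at least 40 s (a rule previously validated against
EEG); all remaining time forms activity segments, so short pauses under the
rule's duration do not break an activity bout. From the bout partition we
derive zeitgeber-time (ZT) hourly profiles, light/dark phase summaries,
the fraction of the dark phase spent in long (>10 min) activity bouts, and
the nonparametric circadian statistics interdaily stability (IS),
intradaily variability (IV) and the Lomb-Scargle periodogram.

Conventions: ZT0 = lights on, ZT12 = lights off; the dark phase is
ZT12-24. Epochs are 0-based half-open intervals. Profiles, IS and IV are
computed on whole ZT days (partial days at the stream ends are trimmed so
hour-of-day means are unbiased).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "ActivityStream",
    "Bout",
    "BoutList",
    "HourlyProfile",
    "CircadianSummary",
    "score_immobility",
    "long_bout_fraction",
    "phase_and_hourly_profile",
    "interdaily_stability",
    "intradaily_variability",
    "lomb_scargle_power",
    "circadian_summary",
    "DEFAULT_PERIOD_GRID_H",
]

#: Default periodogram grid: 16-32 h in 0.1 h steps.
DEFAULT_PERIOD_GRID_H = np.round(np.arange(16.0, 32.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class ActivityStream:
    """Per-animal PIR stream: one activity count per fixed-length epoch."""

    animal_id: str
    counts: np.ndarray
    epoch_s: int = 10
    #: stream index of an epoch falling exactly on ZT0 (lights on).
    lights_on_epoch: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("counts must be a nonempty 1-D array")
        if np.any(c < 0):
            raise ValueError("activity counts must be nonnegative")
        if self.epoch_s <= 0 or 3600 % self.epoch_s != 0:
            raise ValueError("epoch_s must divide 3600")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def epochs_per_hour(self) -> int:
        return 3600 // self.epoch_s

    @property
    def epochs_per_day(self) -> int:
        return 24 * self.epochs_per_hour

    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    def zt_hours(self) -> np.ndarray:
        """ZT hour in [0, 24) of each epoch's start."""
        idx = np.arange(self.n_epochs)
        return ((idx - self.lights_on_epoch) % self.epochs_per_day) / self.epochs_per_hour


@dataclass(frozen=True)
class Bout:
    start: int  # epoch index, inclusive
    end: int    # epoch index, exclusive
    kind: Literal["immobility_sleep", "activity"]

    @property
    def n_epochs(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BoutList:
    bouts: tuple[Bout, ...]
    n_epochs: int
    epoch_s: int
    lights_on_epoch: int
    min_immobility_s: int

    def immobile_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_epochs, dtype=bool)
        for b in self.bouts:
            if b.kind == "immobility_sleep":
                mask[b.start:b.end] = True
        return mask

    @property
    def epochs_per_hour(self) -> int:
        return 3600 // self.epoch_s

    @property
    def epochs_per_day(self) -> int:
        return 24 * self.epochs_per_hour

    def zt_hours(self) -> np.ndarray:
        idx = np.arange(self.n_epochs)
        return ((idx - self.lights_on_epoch) % self.epochs_per_day) / self.epochs_per_hour


@dataclass(frozen=True)
class HourlyProfile:
    """Per-ZT-hour immobility/activity fractions averaged across days."""

    immobility_frac: np.ndarray  # length 24
    activity_frac: np.ndarray    # length 24
    n_days: int


@dataclass(frozen=True)
class CircadianSummary:
    animal_id: str
    long_bout_dark_frac: float
    dark_immobility_frac: float
    light_immobility_frac: float
    IS: float
    IV: float
    ls_power_24h: float
    ls_peak_period_h: float
    ls_peak_power: float
    ls_p_value: float


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length segments of a boolean array as (start, end, value)."""
    if mask.size == 0:
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [mask.size]))
    return [(int(s), int(e), bool(mask[s])) for s, e in zip(starts, ends)]


def score_immobility(
    stream: ActivityStream,
    min_immobility_s: int = 40,
    activity_threshold: int = 0,
) -> BoutList:
    """Partition a stream into immobility-defined sleep and activity bouts.

    An epoch is inactive iff its count is <= ``activity_threshold`` (default
    0, i.e. no detected movement). Maximal inactive runs of at least
    ``min_immobility_s`` become immobility bouts; everything else is merged
    into maximal activity bouts, so the partition covers the stream exactly.
    """
    if min_immobility_s % stream.epoch_s != 0:
        raise ValueError(
            f"min_immobility_s={min_immobility_s} is not a multiple of the "
            f"epoch length ({stream.epoch_s} s)"
        )
    min_epochs = min_immobility_s // stream.epoch_s
    inactive = stream.counts <= activity_threshold
    immobile = np.zeros_like(inactive)
    for s, e, val in _runs(inactive):
        if val and (e - s) >= min_epochs:
            immobile[s:e] = True
    bouts = tuple(
        Bout(s, e, "immobility_sleep" if val else "activity")
        for s, e, val in _runs(immobile)
    )
    return BoutList(
        bouts=bouts,
        n_epochs=stream.n_epochs,
        epoch_s=stream.epoch_s,
        lights_on_epoch=stream.lights_on_epoch,
        min_immobility_s=min_immobility_s,
    )


def _phase_mask(bouts: BoutList, phase: Literal["dark", "light"]) -> np.ndarray:
    zt = bouts.zt_hours()
    return (zt >= 12.0) if phase == "dark" else (zt < 12.0)


def long_bout_fraction(
    bouts: BoutList,
    phase: Literal["dark", "light"] = "dark",
    min_activity_bout_min: float = 10.0,
) -> float:
    """Fraction of a light phase spent inside long (>10 min, strict)
    activity bouts."""
    if phase not in ("dark", "light"):
        raise ValueError("phase must be 'dark' or 'light'")
    if bouts.n_epochs * bouts.epoch_s < 12 * 3600:
        raise ValueError("stream shorter than one 12-h phase")
    in_phase = _phase_mask(bouts, phase)
    phase_epochs = int(in_phase.sum())
    if phase_epochs == 0:
        raise ValueError(f"stream contains no {phase}-phase epochs")
    min_s = min_activity_bout_min * 60.0
    long_mask = np.zeros(bouts.n_epochs, dtype=bool)
    for b in bouts.bouts:
        if b.kind == "activity" and b.n_epochs * bouts.epoch_s > min_s:
            long_mask[b.start:b.end] = True
    return float((long_mask & in_phase).sum() / phase_epochs)


def _trim_whole_days(bouts: BoutList) -> tuple[np.ndarray, int]:
    """Immobile mask trimmed to whole ZT days starting at the first ZT0."""
    epd = bouts.epochs_per_day
    first_zt0 = (bouts.lights_on_epoch % epd)
    if first_zt0 >= bouts.n_epochs:
        raise ValueError("stream does not reach ZT0")
    n_days = (bouts.n_epochs - first_zt0) // epd
    if n_days < 1:
        raise ValueError("need at least one full ZT day")
    mask = bouts.immobile_mask()[first_zt0:first_zt0 + n_days * epd]
    return mask, n_days


def phase_and_hourly_profile(
    bouts: BoutList,
) -> tuple[HourlyProfile, float, float]:
    """Per-ZT-hour immobility profile plus dark/light immobility fractions.

    Returns ``(profile, dark_immobility_frac, light_immobility_frac)``,
    all computed on whole ZT days.
    """
    mask, n_days = _trim_whole_days(bouts)
    eph = bouts.epochs_per_hour
    by_hour = mask.reshape(n_days, 24, eph)
    imm = by_hour.mean(axis=(0, 2))
    profile = HourlyProfile(
        immobility_frac=imm, activity_frac=1.0 - imm, n_days=n_days
    )
    dark = float(by_hour[:, 12:, :].mean())
    light = float(by_hour[:, :12, :].mean())
    return profile, dark, light


def interdaily_stability(
    hourly_series: Sequence[float], bins_per_day: int = 24
) -> float:
    """Interdaily stability (IS) of a binned series spanning >= 2 days.

    IS = (n * sum_h (xbar_h - xbar)^2) / (p * sum_i (x_i - xbar)^2) with
    p = bins_per_day and xbar_h the hour-of-day means; 1 for a perfectly
    repeated daily profile, ~1/d for noise over d days.
    """
    x = np.asarray(hourly_series, dtype=float)
    n = x.size
    if n % bins_per_day != 0 or n // bins_per_day < 2:
        raise ValueError("series must span an integer number (>= 2) of days")
    denom_var = np.sum((x - x.mean()) ** 2)
    if denom_var == 0:
        raise ValueError("IS undefined (zero variance)")
    hour_means = x.reshape(-1, bins_per_day).mean(axis=0)
    num = n * np.sum((hour_means - x.mean()) ** 2)
    return float(num / (bins_per_day * denom_var))


def intradaily_variability(hourly_series: Sequence[float]) -> float:
    """Intradaily variability (IV): normalized first-difference variance.

    IV = (n * sum_{i>=2} (x_i - x_{i-1})^2) / ((n-1) * sum_i (x_i - xbar)^2);
    ~2 for white noise, 4 for a strictly alternating series, small for a
    smooth ramp.
    """
    x = np.asarray(hourly_series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 bins")
    denom_var = np.sum((x - x.mean()) ** 2)
    if denom_var == 0:
        raise ValueError("IV undefined (zero variance)")
    num = n * np.sum(np.diff(x) ** 2)
    return float(num / ((n - 1) * denom_var))


def lomb_scargle_power(
    times_h: Sequence[float],
    values: Sequence[float],
    period_grid_h: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Normalized Lomb-Scargle periodogram over a period grid.

    Returns ``(peak_period_h, power_at_24h, p_value)`` where power is in the
    classical normalization (periodogram / series variance) and the p-value
    for the peak is the approximate classical level
    ``1 - (1 - exp(-P_peak))**M`` with M the grid size (conservative for an
    oversampled grid).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be equal-length 1-D")
    if t.size < 3:
        raise ValueError("too few samples")
    if t.max() - t.min() < 48.0:
        raise ValueError("need at least 2 days of data")
    grid = np.asarray(
        DEFAULT_PERIOD_GRID_H if period_grid_h is None else period_grid_h,
        dtype=float,
    )
    if grid.min() > 24.0 or grid.max() < 24.0:
        raise ValueError("period grid must cover 24 h")
    yc = y - y.mean()
    var = yc.var()
    if var == 0:
        warnings.warn("constant series: periodogram power is 0")
        return float("nan"), 0.0, 1.0
    omega = 2.0 * np.pi / grid
    power = signal.lombscargle(t, yc, omega) / var
    i_peak = int(np.argmax(power))
    i_24 = int(np.argmin(np.abs(grid - 24.0)))
    p_peak = float(power[i_peak])
    m = grid.size
    p_value = float(1.0 - (1.0 - np.exp(-p_peak)) ** m)
    return float(grid[i_peak]), float(power[i_24]), p_value


def hourly_fraction_series(
    bouts: BoutList, which: Literal["immobility", "activity"] = "immobility"
) -> tuple[np.ndarray, np.ndarray]:
    """Hour-binned fraction series over whole ZT days.

    Returns ``(times_h, fractions)`` with times at bin centers, suitable for
    IS/IV and the periodogram.
    """
    mask, n_days = _trim_whole_days(bouts)
    eph = bouts.epochs_per_hour
    frac = mask.reshape(n_days * 24, eph).mean(axis=1)
    if which == "activity":
        frac = 1.0 - frac
    times = np.arange(n_days * 24) + 0.5
    return times, frac


def circadian_summary(
    stream: ActivityStream,
    min_immobility_s: int = 40,
    min_activity_bout_min: float = 10.0,
    period_grid_h: Sequence[float] | None = None,
    rhythm_on: Literal["immobility", "activity"] = "immobility",
) -> CircadianSummary:
    """All per-animal circadian summary statistics in one pass.

    IS and IV are computed on the hourly fraction series selected by
    ``rhythm_on`` (immobility by default); the periodogram is computed on
    the hourly activity fraction (strength of the 24-h activity cycle).
    """
    bouts = score_immobility(stream, min_immobility_s=min_immobility_s)
    _, dark_imm, light_imm = phase_and_hourly_profile(bouts)
    lb = long_bout_fraction(bouts, "dark", min_activity_bout_min)
    _, frac_rhythm = hourly_fraction_series(bouts, rhythm_on)
    t_act, frac_act = hourly_fraction_series(bouts, "activity")
    is_val = interdaily_stability(frac_rhythm)
    iv_val = intradaily_variability(frac_rhythm)
    peak_period, power_24, p_val = lomb_scargle_power(
        t_act, frac_act, period_grid_h
    )
    grid = np.asarray(
        DEFAULT_PERIOD_GRID_H if period_grid_h is None else period_grid_h,
        dtype=float,
    )
    yc = frac_act - frac_act.mean()
    peak_power = float(
        np.max(signal.lombscargle(t_act, yc, 2 * np.pi / grid) / yc.var())
    ) if yc.var() > 0 else 0.0
    return CircadianSummary(
        animal_id=stream.animal_id,
        long_bout_dark_frac=lb,
        dark_immobility_frac=dark_imm,
        light_immobility_frac=light_imm,
        IS=is_val,
        IV=iv_val,
        ls_power_24h=power_24,
        ls_peak_period_h=peak_period,
        ls_peak_power=peak_power,
        ls_p_value=p_val,
    )
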