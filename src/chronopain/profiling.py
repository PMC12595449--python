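"""Individual profiling, correlation matrices and early-to-late prediction.

Profiling follows the one-standard-deviation rule: an animal is "affected"
on an assay if its value lies one control-group sample SD or more beyond
the control mean, in the direction of impairment for that assay; otherwise
it is resilient. Cross-sectional structure is summarized with Pearson
correlations between outcomes measured in the same animals, and the
early-burden hypothesis is tested by correlating an early time-weighted
average of a sensory assay against a late outcome.

Mechanical thresholds are analyzed on the log10 scale throughout (the
conventional transform that normalizes von Frey data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vonfrey import weighted_time_average

__all__ = [
    "OutcomeTable",
    "AffectedClassification",
    "CorrelationResult",
    "classify_affected",
    "correlation_matrix",
    "predict_late_from_early",
    "DEFAULT_DIRECTIONALITY",
    "LOG_SCALE_ASSAYS",
]

Direction = Literal["lower_is_affected", "higher_is_affected"]

#: Direction of impairment for the standard assays.
DEFAULT_DIRECTIONALITY: dict[str, Direction] = {
    "vf_threshold_g": "lower_is_affected",
    "wb_pct": "lower_is_affected",
    "spt_pct": "lower_is_affected",
    "oft_center_s": "lower_is_affected",
    "affective_s": "higher_is_affected",
    "guarding_index": "higher_is_affected",
}

#: Assays analyzed on the log10 scale in correlation/prediction stages.
LOG_SCALE_ASSAYS = frozenset({"vf_threshold_g"})

REQUIRED_COLUMNS = ("animal_id", "sex", "group", "day", "assay", "value")


@dataclass
class OutcomeTable:
    """Long-format behavioral outcomes: one row per animal x day x assay."""

    records: pd.DataFrame
    directionality: Mapping[str, Direction] = field(
        default_factory=lambda: dict(DEFAULT_DIRECTIONALITY)
    )

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        dup = df.duplicated(subset=["animal_id", "day", "assay"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                "duplicate animal x day x assay record: "
                f"{row['animal_id']} day {row['day']} {row['assay']}"
            )
        self.records = df.reset_index(drop=True)

    def values_at(
        self,
        assay: str,
        day: float,
        groups: Sequence[str] | None = None,
        sex: str | None = None,
    ) -> pd.Series:
        """Per-animal values of one assay at one day (index: animal_id)."""
        df = self.records
        m = (df["assay"] == assay) & (df["day"] == day) & df["value"].notna()
        if groups is not None:
            m &= df["group"].isin(groups)
        if sex is not None:
            m &= df["sex"] == sex
        sub = df[m]
        return pd.Series(sub["value"].values, index=sub["animal_id"].values)

    def animals(self) -> pd.DataFrame:
        return (
            self.records[["animal_id", "sex", "group"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )


@dataclass(frozen=True)
class AffectedClassification:
    affected: pd.Series          # bool per animal_id
    cutoff_value: float
    control_mean: float
    control_sd: float
    direction: Direction

    @property
    def affected_fraction(self) -> float:
        return float(self.affected.mean())


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    label_a: str
    label_b: str
    undefined: bool = False


def classify_affected(
    values: pd.Series | Mapping[str, float],
    controls: Sequence[float],
    direction: Direction,
) -> AffectedClassification:
    """Flag animals one control SD or more beyond the control mean.

    The boundary is inclusive ("one SD or more"); the SD is the sample
    (n-1) standard deviation of the control group.
    """
    v = pd.Series(dict(values)) if not isinstance(values, pd.Series) else values
    c = np.asarray(controls, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 control animals")
    mean = float(c.mean())
    sd = float(c.std(ddof=1))
    if sd == 0:
        raise ValueError("control SD is zero: cutoff undefined")
    if direction == "lower_is_affected":
        cutoff = mean - sd
        flags = v <= cutoff
    elif direction == "higher_is_affected":
        cutoff = mean + sd
        flags = v >= cutoff
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return AffectedClassification(
        affected=flags, cutoff_value=cutoff, control_mean=mean,
        control_sd=sd, direction=direction,
    )


def _maybe_log(assay: str, s: pd.Series) -> pd.Series:
    return np.log10(s) if assay in LOG_SCALE_ASSAYS else s


def _pearson(x: np.ndarray, y: np.ndarray, la: str, lb: str) -> CorrelationResult:
    n = x.size
    if n < 3:
        raise ValueError(f"fewer than 3 shared animals for {la} vs {lb}")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(math.nan, math.nan, n, la, lb, undefined=True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, la, lb)


def correlation_matrix(
    table: OutcomeTable,
    pairs: Sequence[tuple[tuple[str, float], tuple[str, float]]],
    groups: Sequence[str] | None = None,
) -> list[CorrelationResult]:
    """Pearson r/p for each ((assayA, dayA), (assayB, dayB)) pair.

    Computed across animals that carry both values; constant vectors yield
    an explicit undefined flag rather than a silent drop. Threshold assays
    enter on the log10 scale.
    """
    out: list[CorrelationResult] = []
    for (assay_a, day_a), (assay_b, day_b) in pairs:
        va = table.values_at(assay_a, day_a, groups)
        vb = table.values_at(assay_b, day_b, groups)
        shared = va.index.intersection(vb.index)
        x = _maybe_log(assay_a, va.loc[shared]).to_numpy(dtype=float)
        y = _maybe_log(assay_b, vb.loc[shared]).to_numpy(dtype=float)
        out.append(
            _pearson(x, y, f"{assay_a}@{day_a:g}", f"{assay_b}@{day_b:g}")
        )
    return out


def early_burden(
    table: OutcomeTable,
    assay: str,
    window_days: tuple[float, float] = (0.0, 14.0),
    groups: Sequence[str] | None = None,
) -> pd.Series:
    """Per-animal time-weighted average of an assay inside an early window."""
    lo, hi = window_days
    if hi <= lo:
        raise ValueError("empty early window")
    df = table.records
    m = (
        (df["assay"] == assay)
        & (df["day"] >= lo)
        & (df["day"] <= hi)
        & df["value"].notna()
    )
    if groups is not None:
        m &= df["group"].isin(groups)
    sub = df[m].sort_values("day")
    out: dict[str, float] = {}
    for animal, grp in sub.groupby("animal_id", sort=True):
        vals = _maybe_log(assay, grp["value"]).to_numpy(dtype=float)
        out[animal] = weighted_time_average(vals, grp["day"].to_numpy(dtype=float))
    return pd.Series(out)


def predict_late_from_early(
    table: OutcomeTable,
    early_assay: str = "vf_threshold_g",
    late_assay: str = "spt_pct",
    late_day: float = 180.0,
    early_window_days: tuple[float, float] = (0.0, 14.0),
    groups: Sequence[str] | None = None,
) -> CorrelationResult:
    """Correlate early pain burden with a late outcome.

    The predictor is the time-weighted average of ``early_assay`` within
    the early window (default days 0-14, the first two weeks); the response
    is the late value of ``late_assay``. Returns a Pearson result over
    animals carrying both.
    """
    early = early_burden(table, early_assay, early_window_days, groups)
    late = table.values_at(late_assay, late_day, groups)
    shared = early.index.intersection(late.index)
    x = early.loc[shared].to_numpy(dtype=float)
    y = _maybe_log(late_assay, late.loc[shared]).to_numpy(dtype=float)
    la = f"{early_assay}@[{early_window_days[0]:g},{early_window_days[1]:g}]"
    return _pearson(x, y, la, f"{late_assay}@{late_day:g}")
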