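"""Up-down (Dixon) estimation of 50% mechanical withdrawal thresholds.

The up-down staircase presents calibrated von Frey monofilaments, stepping
one filament down after each withdrawal and one up after each non-withdrawal.
Testing ends a fixed number of presentations after the first response change
(default 4) or when the staircase runs off either end of the filament series.
The 50% withdrawal threshold is then

    threshold (g) = 10 ** (log10(last filament force) + 0.3 * k)

where ``k`` is a tabulated constant determined by the terminal response
pattern. The constants here are derived, not transcribed: for each pattern we
compute the maximum-likelihood estimate of the mean of a normal tolerance
distribution whose standard deviation equals one staircase step, given the
dose walk the pattern implies, and take ``k`` as the (signed) distance in
steps from the last dose to that estimate. This is the same construction that
underlies the classical published tables; the packaged table can be audited
or overridden (see :func:`build_k_table`, :func:`load_k_table`).

Downstream statistics on thresholds are conventionally done on log10 grams;
:func:`weighted_time_average` implements the time-weighted ("weighted
average") summary used for irregularly sampled longitudinal series.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DEFAULT_FILAMENTS_G",
    "FilamentSeries",
    "UpDownSequence",
    "ThresholdEstimate",
    "WITHDRAW",
    "NO_WITHDRAW",
    "dixon_k",
    "build_k_table",
    "load_k_table",
    "estimate_threshold",
    "simulate_updown",
    "weighted_time_average",
]

WITHDRAW = "withdraw"
NO_WITHDRAW = "no_withdraw"

#: A common mouse hind-paw filament set (grams); includes the 0.04/0.16/1.0 g
#: filaments used for affective scoring. Roughly log-spaced.
DEFAULT_FILAMENTS_G: tuple[float, ...] = (
    0.02, 0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0,
)

#: log10-gram step assumed by the threshold formula.
LOG_STEP = 0.3


@dataclass(frozen=True)
class FilamentSeries:
    """Ordered series of filament forces in grams, weakest first."""

    forces_g: tuple[float, ...] = DEFAULT_FILAMENTS_G

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.forces_g)
        if len(f) < 3:
            raise ValueError("filament series needs at least 3 filaments")
        if any(x <= 0 for x in f):
            raise ValueError("filament forces must be positive")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("filament forces must be strictly increasing")
        object.__setattr__(self, "forces_g", f)

    def __len__(self) -> int:
        return len(self.forces_g)

    @property
    def log10_forces(self) -> np.ndarray:
        return np.log10(np.asarray(self.forces_g))


@dataclass(frozen=True)
class UpDownSequence:
    """Ordered filament presentations with binary responses.

    ``presentations`` is a sequence of ``(filament_index, response)`` where
    response is ``"withdraw"`` or ``"no_withdraw"``. Strict up-down stepping
    is enforced: the index decreases by one after a withdrawal and increases
    by one after a non-withdrawal. The staircase may terminate at any point
    (including when a step off the series would be required).
    """

    presentations: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        pres = tuple((int(i), str(r)) for i, r in self.presentations)
        if not pres:
            raise ValueError("empty up-down sequence")
        for i, r in pres:
            if r not in (WITHDRAW, NO_WITHDRAW):
                raise ValueError(f"invalid response {r!r}")
            if i < 0:
                raise ValueError("negative filament index")
        for (i0, r0), (i1, _) in zip(pres, pres[1:]):
            expected = i0 - 1 if r0 == WITHDRAW else i0 + 1
            if i1 != expected:
                raise ValueError(
                    f"malformed sequence: index {i1} follows ({i0}, {r0}); "
                    f"expected {expected}"
                )
        object.__setattr__(self, "presentations", pres)

    @property
    def responses(self) -> str:
        """Response string over {X, O}: X = withdraw, O = no withdrawal."""
        return "".join("X" if r == WITHDRAW else "O" for _, r in self.presentations)

    def terminal_pattern(self) -> str | None:
        """Pattern keying the k table: responses from just before the first
        response change through the end. ``None`` if no change occurred."""
        s = self.responses
        for c in range(1, len(s)):
            if s[c] != s[0]:
                return s[c - 1:]
        return None


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold_g: float
    last_filament_g: float
    k: float
    censored: Literal["none", "floor", "ceiling"] = "none"


def _pattern_doses(pattern: str) -> np.ndarray:
    """Relative dose (in steps) at each presentation of a terminal pattern."""
    doses = [0.0]
    for ch in pattern[:-1]:
        doses.append(doses[-1] - 1.0 if ch == "X" else doses[-1] + 1.0)
    return np.asarray(doses)


def dixon_k(pattern: str) -> float:
    """ML-derived k constant for a terminal response pattern.

    Assumes P(withdraw at dose x) = Phi(x - mu) with doses in units of one
    staircase step; returns ``mu_hat - x_last`` so that the threshold formula
    ``last * 10**(0.3*k)`` lands on the estimated mean.
    """
    if len(pattern) < 2 or set(pattern) - {"X", "O"}:
        raise ValueError(f"invalid pattern {pattern!r}")
    if pattern[1] == pattern[0]:
        raise ValueError(
            f"pattern {pattern!r} must start at the first response change"
        )
    doses = _pattern_doses(pattern)
    signs = np.array([1.0 if ch == "X" else -1.0 for ch in pattern])

    def nll(mu: float) -> float:
        return -np.sum(stats.norm.logcdf(signs * (doses - mu)))

    lo, hi = doses.min() - 8.0, doses.max() + 8.0
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x - doses[-1])


def build_k_table(max_len: int = 9) -> dict[str, float]:
    """Enumerate all terminal patterns up to ``max_len`` responses and
    compute their k constants."""
    table: dict[str, float] = {}
    for length in range(2, max_len + 1):
        for first in "XO":
            second = "O" if first == "X" else "X"
            for tail_bits in range(2 ** (length - 2)):
                tail = "".join(
                    "X" if (tail_bits >> j) & 1 else "O"
                    for j in range(length - 2)
                )
                pat = first + second + tail
                table[pat] = dixon_k(pat)
    return table


def load_k_table() -> dict[str, float]:
    """Load the packaged k-constant table (pattern -> k)."""
    with resources.files("chronopain").joinpath("data/updown_k_table.json").open() as fh:
        return {str(k): float(v) for k, v in json.load(fh).items()}


def estimate_threshold(
    seq: UpDownSequence,
    series: FilamentSeries | None = None,
    ktab: dict[str, float] | None = None,
) -> ThresholdEstimate:
    """50% withdrawal threshold from one up-down sequence.

    Boundary handling: a sequence with no response change is censored — all
    non-withdrawals at the strongest filament give a ceiling estimate at the
    maximum force, all withdrawals down to the weakest give a floor estimate
    at the minimum force. Otherwise the terminal pattern is looked up in the
    k table and the formula ``10**(log10(last) + 0.3*k)`` applied.
    """
    series = series or FilamentSeries()
    if ktab is None:
        ktab = load_k_table()
    n = len(series)
    for i, _ in seq.presentations:
        if i >= n:
            raise ValueError(f"filament index {i} outside series of {n}")
    pattern = seq.terminal_pattern()
    last_idx, last_resp = seq.presentations[-1]
    last_g = series.forces_g[last_idx]
    if pattern is None:
        if last_resp == NO_WITHDRAW:
            if last_idx != n - 1:
                raise ValueError(
                    "sequence ended without a response change before reaching "
                    "the strongest filament"
                )
            return ThresholdEstimate(series.forces_g[-1], last_g, math.nan, "ceiling")
        if last_idx != 0:
            raise ValueError(
                "sequence ended without a response change before reaching "
                "the weakest filament"
            )
        return ThresholdEstimate(series.forces_g[0], last_g, math.nan, "floor")
    if pattern not in ktab:
        raise KeyError(f"response pattern {pattern!r} not in k table")
    k = ktab[pattern]
    thr = 10.0 ** (math.log10(last_g) + LOG_STEP * k)
    return ThresholdEstimate(thr, last_g, k, "none")


def simulate_updown(
    true_threshold_g: float,
    slope: float,
    series: FilamentSeries | None = None,
    n_trials_after_change: int = 4,
    seed: int | np.random.Generator = 0,
    start_index: int | None = None,
) -> UpDownSequence:
    """Simulate one animal's up-down staircase.

    Withdrawal probability follows a logistic psychometric function of
    log10(force) centered on log10(true threshold) with the given slope
    (logit units per log10 gram). The staircase starts mid-series, steps
    strictly up-down, and stops ``n_trials_after_change`` presentations after
    the first response change, or earlier if it runs off the series.
    """
    if true_threshold_g <= 0:
        raise ValueError("true threshold must be positive")
    if slope <= 0:
        raise ValueError("psychometric slope must be positive")
    series = series or FilamentSeries()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    logf = series.log10_forces
    idx = len(series) // 2 if start_index is None else int(start_index)
    if not 0 <= idx < len(series):
        raise ValueError("start index outside series")
    center = math.log10(true_threshold_g)
    if n_trials_after_change < 1:
        raise ValueError("n_trials_after_change must be >= 1")
    pres: list[tuple[int, str]] = []
    change_seen = False
    remaining = int(n_trials_after_change)
    first_resp: str | None = None
    while True:
        x = slope * (logf[idx] - center)
        p = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))
        resp = WITHDRAW if rng.random() < p else NO_WITHDRAW
        pres.append((idx, resp))
        if change_seen:
            remaining -= 1
            if remaining == 0:
                break
        elif first_resp is None:
            first_resp = resp
        elif resp != first_resp:
            change_seen = True
        nxt = idx - 1 if resp == WITHDRAW else idx + 1
        if nxt < 0 or nxt >= len(series):
            break
        idx = nxt
    return UpDownSequence(tuple(pres))


def weighted_time_average(values: Sequence[float], days: Sequence[float]) -> float:
    """Time-weighted mean with trapezoidal interval weights.

    Interior points weigh (gap to previous + gap to next)/2; boundary points
    half their single adjacent gap. A single point returns its own value.
    Equally spaced days reduce to the arithmetic mean.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(days, dtype=float)
    if v.size == 0 or d.size == 0:
        raise ValueError("empty input")
    if v.shape != d.shape:
        raise ValueError("values and days must have equal length")
    if v.size == 1:
        return float(v[0])
    if np.any(np.diff(d) <= 0):
        raise ValueError("days must be strictly increasing")
    gaps = np.diff(d)
    w = np.empty_like(v)
    w[0] = gaps[0] / 2.0
    w[-1] = gaps[-1] / 2.0
    if v.size > 2:
        w[1:-1] = (gaps[:-1] + gaps[1:]) / 2.0
    return float(np.sum(w * v) / np.sum(w))
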