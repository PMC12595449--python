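"""Immobility scoring, circadian summary statistics and periodograms."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronopain.actigraphy import (
    ActivityStream,
    DEFAULT_PERIOD_GRID_H,
    hourly_fraction_series,
    interdaily_stability,
    intradaily_variability,
    lomb_scargle_power,
    long_bout_fraction,
    phase_and_hourly_profile,
    score_immobility,
)

EPD = 8640  # 10-s epochs per day


def stream(counts, lights_on=0):
    return ActivityStream("a1", np.asarray(counts), 10, lights_on)


def rle_oracle(inactive, min_epochs):
    """Independent run-length-encoding partition of a binary stream."""
    immobile = np.zeros(len(inactive), dtype=bool)
    pos = 0
    for val, grp in itertools.groupby(inactive):
        n = len(list(grp))
        if val and n >= min_epochs:
            immobile[pos:pos + n] = True
        pos += n
    return immobile


class TestImmobilityScoring:
    def test_all_active_single_activity_bout(self):
        b = score_immobility(stream([3] * 50))
        assert len(b.bouts) == 1
        assert b.bouts[0].kind == "activity"
        assert (b.bouts[0].start, b.bouts[0].end) == (0, 50)

    def test_single_60s_run(self):
        counts = [1] * 5 + [0] * 6 + [2] * 5
        b = score_immobility(stream(counts))
        imm = [x for x in b.bouts if x.kind == "immobility_sleep"]
        assert len(imm) == 1
        assert (imm[0].start, imm[0].end) == (5, 11)

    def test_40s_boundary_is_inclusive(self):
        # 3-epoch (30 s) run does not qualify; 4-epoch (40 s) run does
        counts = [1] + [0] * 3 + [1] + [0] * 4 + [1]
        b = score_immobility(stream(counts))
        imm = [x for x in b.bouts if x.kind == "immobility_sleep"]
        assert len(imm) == 1
        assert imm[0].n_epochs == 4

    def test_epoch_mismatch_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            score_immobility(stream([0] * 10), min_immobility_s=45)

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=1, max_size=400))
    def test_partition_matches_rle_oracle(self, counts):
        """The bout partition covers the stream exactly and agrees with an
        independent RLE computation, including the 4-epoch boundary."""
        b = score_immobility(stream(counts))
        covered = np.zeros(len(counts), dtype=int)
        for bout in b.bouts:
            covered[bout.start:bout.end] += 1
        assert (covered == 1).all()
        expected = rle_oracle(np.asarray(counts) == 0, 4)
        assert np.array_equal(b.immobile_mask(), expected)


class TestLongBouts:
    def test_continuous_dark_activity_is_one(self):
        counts = np.ones(EPD, dtype=int)
        b = score_immobility(stream(counts))
        assert long_bout_fraction(b, "dark") == 1.0

    def test_exactly_ten_minute_bouts_excluded(self):
        # dark phase filled with 60-epoch (= 10 min) activity bouts split
        # by 40-s immobility runs: strict > 10 min means fraction 0
        day = np.zeros(EPD, dtype=int)
        pos = EPD // 2
        while pos + 64 <= EPD:
            day[pos:pos + 60] = 1
            pos += 64
        b = score_immobility(stream(day))
        assert long_bout_fraction(b, "dark") == 0.0

    def test_thirty_minute_bout_fraction(self):
        day = np.zeros(EPD, dtype=int)
        start = EPD // 2 + 100
        day[start:start + 180] = 1  # 30 min in the 12-h dark phase
        b = score_immobility(stream(day))
        assert long_bout_fraction(b, "dark") == pytest.approx(180 / (EPD / 2))

    def test_short_stream_rejected(self):
        b = score_immobility(stream([1] * 100))
        with pytest.raises(ValueError, match="phase"):
            long_bout_fraction(b, "dark")


class TestProfiles:
    def test_fully_immobile(self):
        b = score_immobility(stream(np.zeros(EPD, dtype=int)))
        prof, dark, light = phase_and_hourly_profile(b)
        assert dark == 1.0 and light == 1.0
        assert np.allclose(prof.immobility_frac, 1.0)
        assert np.allclose(prof.activity_frac, 0.0)

    def test_immobile_light_only(self):
        day = np.ones(EPD, dtype=int)
        day[: EPD // 2] = 0  # ZT0-12 inactive
        b = score_immobility(stream(day))
        _, dark, light = phase_and_hourly_profile(b)
        assert (dark, light) == (0.0, 1.0)

    def test_two_day_profile_matches_brute_tally(self, rng):
        counts = rng.integers(0, 2, size=2 * EPD)
        b = score_immobility(stream(counts))
        prof, dark, light = phase_and_hourly_profile(b)
        mask = b.immobile_mask()
        tally = mask.reshape(2, 24, 360).mean(axis=(0, 2))
        assert np.allclose(prof.immobility_frac, tally)
        assert dark == pytest.approx(tally[12:].mean())
        assert light == pytest.approx(tally[:12].mean())

    def test_partial_days_trimmed(self, rng):
        counts = rng.integers(0, 2, size=2 * EPD)
        padded = np.concatenate([counts, rng.integers(0, 2, size=1000)])
        p1, _, _ = phase_and_hourly_profile(score_immobility(stream(counts)))
        p2, _, _ = phase_and_hourly_profile(score_immobility(stream(padded)))
        assert np.allclose(p1.immobility_frac, p2.immobility_frac)


class TestISIV:
    def test_is_one_for_identical_days(self):
        day = np.sin(np.arange(24)) + 2
        assert interdaily_stability(np.tile(day, 2)) == pytest.approx(1.0)

    def test_is_hand_case_two_bins(self):
        assert interdaily_stability([0, 1, 0, 1], bins_per_day=2) == pytest.approx(1.0)

    def test_is_noise_scales_as_one_over_days(self, rng):
        x = rng.normal(size=14 * 24)
        assert interdaily_stability(x) < 0.25

    def test_is_errors(self):
        with pytest.raises(ValueError):
            interdaily_stability([1.0] * 48)
        with pytest.raises(ValueError):
            interdaily_stability([1.0, 2.0, 3.0])  # not whole days

    def test_iv_ramp(self):
        assert intradaily_variability(np.arange(24.0)) == pytest.approx(
            24 / 1150, rel=1e-12
        )

    def test_iv_alternating_is_four(self):
        assert intradaily_variability([0.0, 1.0] * 12) == pytest.approx(4.0)

    def test_iv_noise_near_two(self, rng):
        x = rng.normal(size=336)
        assert 1.7 <= intradaily_variability(x) <= 2.3

    def test_prepending_identical_day_fixes_iv_profile_not_is(self, rng):
        """Periodic extension leaves the profile and IV unchanged; IS of a
        perfectly periodic stream stays at 1."""
        day = rng.normal(size=24)
        two = np.tile(day, 2)
        three = np.tile(day, 3)
        assert intradaily_variability(two) == pytest.approx(
            intradaily_variability(three), rel=0.2
        )
        assert interdaily_stability(two) == pytest.approx(1.0)
        assert interdaily_stability(three) == pytest.approx(1.0)


class TestLombScargle:
    def make_sin(self, period_h, days=14, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(days * 24) + 0.5
        y = np.sin(2 * np.pi * t / period_h) + noise * rng.normal(size=t.size)
        return t, y

    def test_24h_peak(self):
        t, y = self.make_sin(24.0, noise=0.01)
        peak, p24, pval = lomb_scargle_power(t, y)
        assert abs(peak - 24.0) <= 0.1
        assert pval < 0.01
        assert p24 > 0.8 * y.size / 2  # near the theoretical n/2 maximum

    def test_20h_peak_beats_24h(self):
        t, y = self.make_sin(20.0, noise=0.01)
        peak, p24, _ = lomb_scargle_power(t, y)
        assert abs(peak - 20.0) <= 0.1
        grid = DEFAULT_PERIOD_GRID_H
        from scipy.signal import lombscargle

        full = lombscargle(t, y - y.mean(), 2 * np.pi / grid) / y.var()
        assert p24 < full.max()

    def test_white_noise_rarely_significant(self):
        sig = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            t = np.arange(14 * 24) + 0.5
            y = rng.normal(size=t.size)
            _, _, pval = lomb_scargle_power(t, y)
            sig += pval < 0.05
        assert sig <= 4  # >= 90% below the 95% level

    def test_constant_series_warns_power_zero(self):
        t = np.arange(72) + 0.5
        with pytest.warns(UserWarning, match="constant"):
            peak, p24, pval = lomb_scargle_power(t, np.ones_like(t))
        assert p24 == 0.0

    def test_grid_must_cover_24h(self):
        t, y = self.make_sin(24.0)
        with pytest.raises(ValueError, match="24"):
            lomb_scargle_power(t, y, period_grid_h=np.arange(16, 20, 0.1))


def test_hourly_series_roundtrip(rng):
    counts = rng.integers(0, 3, size=3 * EPD)
    b = score_immobility(stream(counts))
    t, frac = hourly_fraction_series(b, "immobility")
    assert t.size == frac.size == 72
    t2, frac2 = hourly_fraction_series(b, "activity")
    assert np.allclose(frac + frac2, 1.0)
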