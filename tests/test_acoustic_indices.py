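"""Rate series, saturation statistics, band energy, window/lunar means."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from colonypulse.acoustic_indices import (
    MAX_DETECTIONS_PER_MIN,
    EnergyBand,
    RateSeries,
    band_energy_series,
    hourly_rates,
    lunar_mean,
    per_minute_rates,
    saturation_fraction,
    windowed_nightly_rate,
)
from colonypulse.acoustic_pipeline import Clip, clip_spectrogram, DEFAULT_SPECTRAL
from colonypulse.call_classifier import DetectionEvent
from colonypulse.night_schedule import RateWindow

T0 = datetime(2015, 7, 17, 6, 0, 0)


def _events(minute_counts, t0=T0, kind="aerial"):
    events = []
    for m, c in enumerate(minute_counts):
        for k in range(c):
            events.append(DetectionEvent(t0 + timedelta(minutes=m, seconds=2 * k),
                                         kind, 1.0, True))
    return events


class TestPerMinuteRates:
    def test_no_events_all_zero(self):
        span = (T0, T0 + timedelta(minutes=5))
        series = per_minute_rates([], span=span)
        assert len(series.counts) == 5
        assert np.all(series.counts == 0)

    def test_event_in_every_clip_hits_ceiling(self):
        series = per_minute_rates(_events([30, 30]))
        assert np.all(series.counts == MAX_DETECTIONS_PER_MIN)

    def test_random_placement_matches_bruteforce_recount(self, rng):
        counts = rng.integers(0, 31, size=20)
        events = _events(list(counts))
        series = per_minute_rates(events, span=(T0, T0 + timedelta(minutes=20)))
        # oracle: recount from the raw event list
        brute = np.zeros(20)
        for e in events:
            brute[int((e.clip_start - T0).total_seconds() // 60)] += 1
        assert np.array_equal(series.counts, brute)

    def test_qc_excluded_minutes_are_null_not_zero(self):
        events = _events([5, 5, 5])
        retained = {T0, T0 + timedelta(minutes=2)}
        series = per_minute_rates(events, retained_minutes=retained,
                                  span=(T0, T0 + timedelta(minutes=3)))
        assert series.counts[0] == 5
        assert np.isnan(series.counts[1])
        assert series.counts[2] == 5

    def test_unaccepted_events_ignored(self):
        events = [DetectionEvent(T0, "aerial", 0.3, False)]
        series = per_minute_rates(events, span=(T0, T0 + timedelta(minutes=1)))
        assert series.counts[0] == 0


class TestSaturation:
    def _series(self, hourly_values):
        minutes = pd.date_range(T0, periods=60 * len(hourly_values), freq="1min")
        counts = np.repeat(hourly_values, 60).astype(float)
        return RateSeries(minutes=minutes, counts=counts)

    def test_all_saturated(self):
        assert saturation_fraction(self._series([30, 30])).fraction_saturated == 1.0

    def test_none_saturated(self):
        assert saturation_fraction(self._series([0, 0])).fraction_saturated == 0.0

    def test_mixed_61_39(self):
        vals = [25] * 61 + [5] * 39
        stats = saturation_fraction(self._series(vals), cutoff=20)
        assert stats.fraction_saturated == pytest.approx(0.61)
        assert stats.n_hours == 100

    def test_no_retained_hours_undefined(self):
        s = self._series([10])
        s.counts[:] = np.nan
        with pytest.raises(ValueError):
            saturation_fraction(s)


class TestBandEnergy:
    def test_member_bins_are_three_centered_bins(self):
        bins = EnergyBand().member_bins(DEFAULT_SPECTRAL)
        centers = DEFAULT_SPECTRAL.bin_centers_hz()[bins]
        assert len(bins) == 3
        assert np.allclose(centers, [1376.3, 1419.4, 1462.4], atol=0.5)

    def test_silence_is_zero(self):
        spec = clip_spectrogram(Clip(T0, np.zeros(32000)))
        series = band_energy_series([spec])
        assert series.iloc[0] == 0.0

    def test_in_band_tone_beats_out_of_band_tone(self):
        t = np.arange(32000) / 16000
        s_in = clip_spectrogram(Clip(T0, 0.5 * np.sin(2 * np.pi * 1419 * t)))
        s_out = clip_spectrogram(Clip(T0, 0.5 * np.sin(2 * np.pi * 3000 * t)))
        series = band_energy_series([s_in, s_out])
        assert series.iloc[0] > 10 * series.iloc[1]

    def test_energy_grows_with_overlapping_calls_past_the_rate_ceiling(self):
        """Overlapped chatters keep raising band energy even though the
        clip-binary detection rate cannot exceed 30/min."""
        from colonypulse.synthetic_colony import synth_call

        freqs = [1380.0, 1419.0, 1450.0, 1400.0]
        energies = []
        for n_overlap in (1, 2, 4):
            x = np.zeros(32000)
            for k in range(n_overlap):
                w = 0.2 * synth_call("chatter", base_hz=freqs[k], seed=k)
                off = 2000 * k  # staggered onsets, still overlapping
                x[off : off + len(w)] += w[: 32000 - off]
            spec = clip_spectrogram(Clip(T0, np.clip(x, -1, 1)))
            energies.append(band_energy_series([spec]).iloc[0])
        assert energies[0] < energies[1] < energies[2]


class TestWindowedRate:
    def test_uniform_rate_recovered(self, schedule_july):
        s = schedule_july
        n_min = int(s.night_length.total_seconds() // 60)
        minutes = pd.date_range(s.sunset, periods=n_min, freq="1min")
        series = RateSeries(minutes=minutes, counts=np.full(n_min, 10.0))
        for w in (RateWindow("sunset", 120, 240), RateWindow("sunrise", -120, -60)):
            assert windowed_nightly_rate(series, s, w) == pytest.approx(10.0)

    def test_calls_outside_window_give_zero(self, schedule_july):
        s = schedule_july
        n_min = int(s.night_length.total_seconds() // 60)
        minutes = pd.date_range(s.sunset, periods=n_min, freq="1min")
        counts = np.zeros(n_min)
        counts[:60] = 30.0  # first hour only
        series = RateSeries(minutes=minutes, counts=counts)
        assert windowed_nightly_rate(series, s, RateWindow("sunset", 120, 240)) == 0.0

    def test_ramp_profile_matches_minute_enumeration(self, schedule_july):
        s = schedule_july
        n_min = int(s.night_length.total_seconds() // 60)
        minutes = pd.date_range(s.sunset, periods=n_min, freq="1min")
        counts = np.arange(n_min, dtype=float) % 31
        series = RateSeries(minutes=minutes, counts=counts)
        w = RateWindow("sunset", 120, 240)
        assert windowed_nightly_rate(series, s, w) == pytest.approx(counts[120:240].mean())

    def test_empty_window_returns_none(self, schedule_july):
        s = schedule_july
        n_min = int(s.night_length.total_seconds() // 60)
        minutes = pd.date_range(s.sunset, periods=n_min, freq="1min")
        series = RateSeries(minutes=minutes, counts=np.full(n_min, np.nan))
        assert windowed_nightly_rate(series, s, RateWindow("sunset", 120, 240)) is None


class TestLunarMean:
    def test_constant_value_recovered(self):
        nightly = {f"2015-07-{d:02d}": 3.5 for d in range(1, 31)}
        assert lunar_mean(nightly, "2015-07-16") == 3.5

    def test_window_spans_29_nights_inclusive(self):
        nightly = {f"2015-07-{d:02d}": float(d) for d in range(1, 32)}
        # center 16: includes July 2..30
        expected = np.mean([float(d) for d in range(2, 31)])
        assert lunar_mean(nightly, "2015-07-16") == pytest.approx(expected)

    def test_edge_window_uses_available_nights(self):
        nightly = {f"2015-07-{d:02d}": float(d) for d in range(1, 21)}
        expected = np.mean([float(d) for d in range(1, 21)])  # 20 nights only
        assert lunar_mean(nightly, "2015-07-15") == pytest.approx(expected)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            lunar_mean({"2015-07-01": 1.0}, "2015-09-01")

    def test_null_nights_skipped(self):
        nightly = {"2015-07-15": np.nan, "2015-07-16": 4.0}
        assert lunar_mean(nightly, "2015-07-16") == 4.0


def test_hourly_rates_use_only_retained_minutes():
    minutes = pd.date_range(T0, periods=120, freq="1min")
    counts = np.full(120, 10.0)
    counts[:30] = np.nan
    series = RateSeries(minutes=minutes, counts=counts)
    hourly = hourly_rates(series)
    assert hourly.iloc[0] == pytest.approx(10.0)  # mean over retained 30 only
    assert len(hourly) == 2
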