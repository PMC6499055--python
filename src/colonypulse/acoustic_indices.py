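"""Abundance indices from detections and spectra.

Detections are clip-binary, so a minute holds at most 30 accepted events —
rates saturate at the ceiling when every 2-s clip contains a call. Rates
are aggregated per minute, per hour (mean calls/min over QC-retained
minutes), over nightly anchor windows (e.g., 120-240 min after sunset),
and over the 29-night lunar window (center ± 14 nights) that removes
moon-phase bias from survey-date comparisons.

The band-limited energy index — mean relative spectral energy in the
1,376-1,462 Hz band where the aerial call concentrates — keeps increasing
with call overlap after the detection rate has hit its ceiling, which is
exactly why the two indices are kept side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .acoustic_pipeline import DEFAULT_SPECTRAL, ClipSpectrogram, SpectralConfig
from .call_classifier import DetectionEvent
from .night_schedule import NightSchedule, RateWindow, _naive_utc, resolve_window

__all__ = [
    "MAX_DETECTIONS_PER_MIN",
    "RateSeries",
    "SaturationStats",
    "EnergyBand",
    "per_minute_rates",
    "hourly_rates",
    "saturation_fraction",
    "band_energy_series",
    "windowed_nightly_rate",
    "lunar_mean",
]

MAX_DETECTIONS_PER_MIN = 30  # 2-s clip binarization ceiling


@dataclass
class RateSeries:
    """Accepted detections per minute; QC-excluded minutes are NaN, not 0."""

    minutes: pd.DatetimeIndex
    counts: np.ndarray = field(repr=False)  # float; NaN where QC-excluded

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.minutes)


@dataclass(frozen=True)
class SaturationStats:
    cutoff: float
    fraction_saturated: float
    n_hours: int


@dataclass(frozen=True)
class EnergyBand:
    low_hz: float = 1376.0
    high_hz: float = 1462.0

    def member_bins(self, cfg: SpectralConfig = DEFAULT_SPECTRAL) -> np.ndarray:
        centers = cfg.bin_centers_hz()
        sel = np.flatnonzero((centers >= self.low_hz - cfg.bin_width_hz / 2)
                             & (centers <= self.high_hz + cfg.bin_width_hz / 2))
        if len(sel) == 0:
            raise ValueError("energy band contains no spectrogram bins")
        return sel


def _floor_minute(t: datetime) -> datetime:
    return t.replace(second=0, microsecond=0)


def per_minute_rates(
    events: Sequence[DetectionEvent],
    retained_minutes: set[datetime] | None = None,
    span: tuple[datetime, datetime] | None = None,
) -> RateSeries:
    """Accepted detections per minute (events deduplicated per clip upstream).

    ``retained_minutes`` is the QC-kept set; minutes outside it are NaN.
    ``span`` fixes the minute axis; defaults to the event range.
    """
    accepted = [e for e in events if e.accepted and e.clip_start is not None]
    if span is None:
        if not accepted:
            raise ValueError("no accepted events and no span given")
        t0 = _floor_minute(min(_naive_utc(e.clip_start) for e in accepted))
        t1 = _floor_minute(max(_naive_utc(e.clip_start) for e in accepted))
    else:
        t0, t1 = _floor_minute(_naive_utc(span[0])), _naive_utc(span[1])
        t1 = _floor_minute(t1 - timedelta(microseconds=1))
    minutes = pd.date_range(t0, t1, freq="1min")
    counts = np.zeros(len(minutes), dtype=float)
    pos = {m: i for i, m in enumerate(minutes.to_pydatetime())}
    for e in accepted:
        m = _floor_minute(_naive_utc(e.clip_start))
        if m in pos:
            counts[pos[m]] += 1
    counts = np.minimum(counts, MAX_DETECTIONS_PER_MIN)
    if retained_minutes is not None:
        keep = np.array([m in retained_minutes for m in minutes.to_pydatetime()])
        counts[~keep] = np.nan
    return RateSeries(minutes=minutes, counts=counts)


def hourly_rates(series: RateSeries) -> pd.Series:
    """Mean calls/min per clock hour over QC-retained (non-NaN) minutes."""
    s = series.as_series()
    return s.groupby(s.index.floor("h")).mean()


def saturation_fraction(series: RateSeries, cutoff: float = 20.0) -> SaturationStats:
    """Fraction of hours whose mean rate is >= cutoff calls/min."""
    hourly = hourly_rates(series).dropna()
    if len(hourly) == 0:
        raise ValueError("no retained hours: saturation fraction undefined")
    frac = float((hourly >= cutoff).mean())
    return SaturationStats(cutoff=cutoff, fraction_saturated=frac, n_hours=len(hourly))


def band_energy_series(
    spectra: Iterable[ClipSpectrogram],
    band: EnergyBand = EnergyBand(),
    cfg: SpectralConfig = DEFAULT_SPECTRAL,
) -> pd.Series:
    """Per-clip mean relative energy over the band's member bins.

    Magnitudes are relative to full scale (1.0 = 16-bit full scale); each
    clip's value is the mean magnitude over member bins and frames. Hourly
    and nightly summaries are means of this per-clip series.
    """
    bins = band.member_bins(cfg)
    idx, vals = [], []
    for s in spectra:
        idx.append(s.clip_start)
        vals.append(float(s.frames[:, bins].mean()))
    return pd.Series(vals, index=pd.DatetimeIndex(idx))


def windowed_nightly_rate(
    series: RateSeries,
    schedule: NightSchedule,
    window: RateWindow,
) -> float | None:
    """Mean calls/min over QC-retained minutes inside the resolved window.

    Returns None when the window holds no retained minutes.
    """
    start, end = resolve_window(schedule, window)
    s = series.as_series()
    sel = s[(s.index >= _naive_utc(start)) & (s.index < _naive_utc(end))].dropna()
    if len(sel) == 0:
        return None
    return float(sel.mean())


def lunar_mean(nightly: dict | pd.Series, center) -> float:
    """Mean of non-null nightly values over the closed 29-night window
    centered on ``center`` (± 14 nights, one lunar cycle)."""
    s = pd.Series(nightly)
    s.index = pd.to_datetime(s.index)
    c = pd.Timestamp(center)
    sel = s[(s.index >= c - pd.Timedelta(days=14)) & (s.index <= c + pd.Timedelta(days=14))]
    sel = sel.dropna()
    if len(sel) == 0:
        raise ValueError("no non-null nights in the 29-night window")
    return float(sel.mean())
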