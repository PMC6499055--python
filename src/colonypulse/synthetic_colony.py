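"""Ground-truthed synthetic colony: attendance, soundscapes, cameras, radar.

Storm-petrels attend the colony only at night: activity is near zero in
the first hour after sunset, rises to a plateau roughly hours 2-6, and
falls back to near zero by sunrise; it is suppressed multiplicatively by
moonlight when the moon is up, modulated night-to-night by a 2-3 day
foraging-trip cycle, and scales with the number of occupied burrows. The
generator turns those assumptions into per-minute aerial (chatter) and
ground (purr) call intensities, renders labelled night audio at 16 kHz by
inhomogeneous Poisson placement of synthesized calls over wind/surf noise,
and draws matching camera burst counts and radar frame stacks — all
byte-reproducible under a fixed seed, with the truth record retained so
every downstream index can be validated against what was simulated.

Call acoustics follow the species: the chatter is an amplitude-modulated
pulse train with an accelerating pulse rate on a harmonic carrier with
base frequency 1-2 kHz; the purr is a staccato buzz at 800-1,000 Hz in
long bouts ending with a convex upward sweep from 750 toward 1,600 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date as _date
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, lfilter

from .acoustic_pipeline import CLIP_SECONDS, SAMPLE_RATE, write_wav
from .camera_counts import CATEGORIES, CameraDesign
from .night_schedule import NightSchedule, _naive_utc
from .surveys import PlotGeometry

__all__ = [
    "CallParams",
    "ColonyConfig",
    "NightTruth",
    "RadarFrameConfig",
    "simulate_attendance",
    "synth_call",
    "render_audio",
    "render_night_audio",
    "synth_camera_bursts",
    "synth_radar_night",
    "DEFAULT_CATEGORY_PROPS",
]

# pooled detection-category shares (clear / eye-shine / wing / blur),
# renormalized to sum to 1 (printed values sum to 100.1%)
_RAW_PROPS = np.array([0.747, 0.085, 0.060, 0.109])
DEFAULT_CATEGORY_PROPS = _RAW_PROPS / _RAW_PROPS.sum()


@dataclass(frozen=True)
class CallParams:
    """Species call parameters (all frequencies in Hz, durations in s)."""

    chatter_base_hz: tuple[float, float] = (1000.0, 2000.0)
    chatter_harmonics: int = 3
    chatter_duration_s: float = 1.5
    chatter_pulse_rate_hz: tuple[float, float] = (8.0, 16.0)  # accelerates
    purr_buzz_hz: tuple[float, float] = (800.0, 1000.0)
    purr_sweep_hz: tuple[float, float] = (750.0, 1600.0)
    purr_bout_s: float = 30.0
    purr_pulse_rate_hz: float = 25.0

    def __post_init__(self):
        nyq = SAMPLE_RATE / 2
        for lo, hi in (self.chatter_base_hz, self.purr_buzz_hz, self.purr_sweep_hz):
            if not (0 < lo < hi <= nyq):
                raise ValueError("call frequencies must lie in (0, Nyquist]")


@dataclass
class ColonyConfig:
    """Study conditions for one simulated plot-season."""

    plots: tuple[PlotGeometry, ...] = (PlotGeometry.rectangle(),)
    burrow_density: float = 5.0         # burrows / m^2
    occupancy_prob: float = 0.7         # fraction of burrows occupied
    flight_intensity_scale: float = 0.05  # aerial call events/min per occupied burrow
    ground_call_scale: float = 0.001    # purr bout starts/min per occupied burrow
    moon_aversion: float = 1.0          # multiplier exponent, >= 0
    trip_cycle_days: float = 2.5        # attendance oscillation period (2-3 d)
    cycle_amplitude: float = 0.3
    plateau_hours: tuple[float, float] = (2.0, 6.0)  # hours after sunset
    season: tuple[_date, _date] = (_date(2015, 5, 1), _date(2015, 8, 31))
    camera_gain: float = 0.02           # expected birds/frame per (aerial call/min)
    radar_gain: float = 0.2             # expected target blobs/frame per (aerial call/min)
    call_params: CallParams = field(default_factory=CallParams)
    rng_seed: int = 0

    def __post_init__(self):
        if self.burrow_density < 0 or not (0 <= self.occupancy_prob <= 1):
            raise ValueError("densities >= 0 and occupancy_prob in [0,1] required")
        if self.moon_aversion < 0:
            raise ValueError("moon_aversion must be >= 0")
        if self.plateau_hours[0] >= self.plateau_hours[1]:
            raise ValueError("plateau start must precede end")

    @property
    def total_area_m2(self) -> float:
        return sum(p.area_m2 for p in self.plots)

    @property
    def occupied_burrows(self) -> float:
        """Expected number of occupied burrows across the plots."""
        return self.occupancy_prob * self.burrow_density * self.total_area_m2

    @property
    def occupied_density(self) -> float:
        return self.occupancy_prob * self.burrow_density

    def to_yaml(self) -> str:
        def _clean(v):
            if isinstance(v, tuple):
                return [_clean(x) for x in v]
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, _date):
                return v.isoformat()
            return v

        return yaml.safe_dump(_clean(asdict(self)), sort_keys=False)


@dataclass
class NightTruth:
    """Simulation truth for one night: per-minute intensities and gains."""

    night_date: _date
    schedule: NightSchedule
    minute_starts: np.ndarray = field(repr=False)   # datetime64[s], sunset grid
    lam_aerial: np.ndarray = field(repr=False)      # expected chatter events/min
    lam_ground: np.ndarray = field(repr=False)      # expected purr bout starts/min
    camera_gain: float = 0.02
    radar_gain: float = 0.2
    call_params: CallParams = field(default_factory=CallParams)

    @property
    def n_minutes(self) -> int:
        return len(self.lam_aerial)

    def minute_index(self, t: datetime) -> int:
        rel = (_naive_utc(t) - _naive_utc(self.schedule.sunset)).total_seconds() / 60.0
        return min(max(int(rel), 0), self.n_minutes - 1)

    def camera_intensity(self, t: datetime) -> float:
        """Expected birds per frame for a burst near time t."""
        return self.camera_gain * float(self.lam_aerial[self.minute_index(t)])

    def radar_intensity(self, t: datetime) -> float:
        """Expected target blobs per radar frame near time t."""
        return self.radar_gain * float(self.lam_aerial[self.minute_index(t)])

    def expected_total_aerial(self) -> float:
        return float(self.lam_aerial.sum())

    def expected_total_ground(self) -> float:
        return float(self.lam_ground.sum())


def _attendance_shape(n_min: int, plateau_hours: tuple[float, float],
                      flat_until_min: float | None = None) -> np.ndarray:
    """Piecewise-smooth nightly bump on the minute grid [0, n_min).

    Quadratic ramp over the first hour (keeps the first half hour near
    zero), plateau at 1 until the configured hour, cosine decline to 0 at
    sunrise.
    """
    t = np.arange(n_min, dtype=float)
    s = np.ones(n_min)
    ramp = t < 60.0
    s[ramp] = (t[ramp] / 60.0) ** 2
    pe = plateau_hours[1] * 60.0 if flat_until_min is None else flat_until_min
    pe = min(pe, n_min - 1.0)
    tail = t > pe
    if np.any(tail) and n_min - 1 > pe:
        s[tail] *= 0.5 * (1.0 + np.cos(np.pi * (t[tail] - pe) / (n_min - 1 - pe)))
    return s


def simulate_attendance(config: ColonyConfig, schedule: NightSchedule,
                        seed: int | None = None) -> NightTruth:
    """Deterministic per-minute truth intensities for one night.

    Intensities are expectations (the random draws happen at render time),
    so the occupancy -> activity link is exactly multiplicative: both
    intensities are proportional to the expected number of occupied
    burrows. ``seed`` is accepted for interface symmetry; the truth record
    itself is deterministic given config and schedule.
    """
    del seed
    if not (config.season[0] <= schedule.date <= config.season[1]):
        raise ValueError(f"{schedule.date} outside configured season {config.season}")
    n_min = int((schedule.sunrise - schedule.sunset).total_seconds() // 60)
    if n_min <= 0:
        raise ValueError("zero-length night")

    s_air = _attendance_shape(n_min, config.plateau_hours)
    # ground calling stays high most of the night, dropping in the last hour
    s_gnd = _attendance_shape(n_min, config.plateau_hours, flat_until_min=n_min - 60.0)

    night_idx = (schedule.date - config.season[0]).days
    cyc = 1.0 + config.cycle_amplitude * np.sin(2 * np.pi * night_idx / config.trip_cycle_days)

    illum = schedule.moon_illumination[:n_min]
    above = schedule.moon_above[:n_min].astype(float)
    moon = np.exp(-config.moon_aversion * illum * above)

    occ = config.occupied_burrows
    lam_a = config.flight_intensity_scale * occ * s_air * cyc * moon
    lam_g = config.ground_call_scale * occ * s_gnd * cyc * moon
    return NightTruth(
        night_date=schedule.date,
        schedule=schedule,
        minute_starts=schedule.moon_times[:n_min],
        lam_aerial=lam_a,
        lam_ground=lam_g,
        camera_gain=config.camera_gain,
        radar_gain=config.radar_gain,
        call_params=config.call_params,
    )


def synth_call(
    kind: str,
    params: CallParams = CallParams(),
    fs: int = SAMPLE_RATE,
    seed: int | None = None,
    base_hz: float | None = None,
    duration_s: float | None = None,
) -> np.ndarray:
    """Synthesize one call waveform, peak amplitude 1.0.

    chatter: harmonic carrier (base + integer harmonics, 6 dB/harmonic
    roll-off) gated by a raised-cosine pulse train whose rate accelerates
    across the call. purr: amplitude-modulated buzz in the 800-1,000 Hz
    band ending in a convex upward sweep toward 1,600 Hz.
    """
    rng = np.random.default_rng(seed)
    if kind == "chatter":
        lo, hi = params.chatter_base_hz
        f0 = float(rng.uniform(lo, hi)) if base_hz is None else float(base_hz)
        if not (lo <= f0 <= hi):
            raise ValueError(f"chatter base {f0} Hz outside species band [{lo}, {hi}]")
        dur = params.chatter_duration_s if duration_s is None else duration_s
        t = np.arange(int(dur * fs)) / fs
        r0, r1 = params.chatter_pulse_rate_hz
        # accelerating pulse phase: rate ramps r0 -> r1
        phase = r0 * t + (r1 - r0) * t**2 / (2 * dur)
        env = (0.5 * (1.0 - np.cos(2 * np.pi * phase))) ** 2
        carrier = np.zeros_like(t)
        for h in range(1, params.chatter_harmonics + 1):
            carrier += (0.5 ** (h - 1)) * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
        x = env * carrier
    elif kind == "purr":
        lo, hi = params.purr_buzz_hz
        fb = float(rng.uniform(lo, hi)) if base_hz is None else float(base_hz)
        if not (lo <= fb <= hi):
            raise ValueError(f"purr buzz {fb} Hz outside species band [{lo}, {hi}]")
        dur = params.purr_bout_s if duration_s is None else duration_s
        sweep_dur = min(0.5, dur / 3.0)
        t = np.arange(int(dur * fs)) / fs
        buzz_t = t[t < dur - sweep_dur]
        env = (0.5 * (1.0 - np.cos(2 * np.pi * params.purr_pulse_rate_hz * buzz_t))) ** 2
        buzz = env * np.sin(2 * np.pi * fb * buzz_t + rng.uniform(0, 2 * np.pi))
        st = t[: len(t) - len(buzz_t)]
        if len(st):
            s_lo, s_hi = params.purr_sweep_hz
            # convex ascending sweep: instantaneous freq s_lo + (s_hi-s_lo)*(u^2)
            u = st / st[-1] if st[-1] > 0 else st
            inst = s_lo + (s_hi - s_lo) * u**2
            ph = 2 * np.pi * np.cumsum(inst) / fs
            sweep = np.sin(ph) * np.hanning(2 * len(st))[len(st):] * 1.0
            x = np.concatenate([buzz, sweep])
        else:
            x = buzz
    else:
        raise ValueError(f"unknown call kind {kind!r}")
    peak = np.abs(x).max()
    return x / peak if peak > 0 else x


@dataclass(frozen=True)
class NoiseSpec:
    """Ambient soundscape: stationary wind/surf beds plus sparse low-frequency
    wave-crash transients (real surf is not perfectly stationary)."""

    wind_level: float = 0.01
    surf_level: float = 0.01
    crash_rate_per_min: float = 2.0
    crash_level: float = 0.05


def _ambient_noise(n: int, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Diffuse background: low-passed wind + band-limited surf + crashes."""
    out = np.zeros(n, dtype=np.float32)
    if noise.wind_level > 0:
        b, a = butter(2, 500 / (SAMPLE_RATE / 2), "low")
        out += (noise.wind_level * lfilter(b, a, rng.standard_normal(n))).astype(np.float32)
    if noise.surf_level > 0:
        b, a = butter(2, [50 / (SAMPLE_RATE / 2), 700 / (SAMPLE_RATE / 2)], "band")
        out += (noise.surf_level * lfilter(b, a, rng.standard_normal(n))).astype(np.float32)
    if noise.crash_rate_per_min > 0 and noise.crash_level > 0:
        b, a = butter(2, 400 / (SAMPLE_RATE / 2), "low")
        n_crash = rng.poisson(noise.crash_rate_per_min * n / (60 * SAMPLE_RATE))
        dur = int(0.4 * SAMPLE_RATE)
        env = np.hanning(dur).astype(np.float32)
        for _ in range(int(n_crash)):
            i0 = int(rng.integers(0, max(n - dur, 1)))
            burst = lfilter(b, a, rng.standard_normal(dur)).astype(np.float32)
            seg = min(dur, n - i0)
            out[i0 : i0 + seg] += noise.crash_level * env[:seg] * burst[:seg]
    return out


def render_audio(
    truth: NightTruth,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    interval: tuple[datetime, datetime] | None = None,
    placement: str = "poisson",
    call_amp: tuple[float, float] = (0.3, 0.7),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render labelled audio for a night (or a sub-interval of it).

    Calls are placed by an inhomogeneous Poisson draw from the per-minute
    intensities (``placement='per_clip'`` instead deterministically starts
    one chatter at every 2-s clip boundary — a saturated soundscape). The
    label table marks, for every 2-s clip on the sunset-anchored grid,
    whether >= 1 aerial and/or ground call overlaps it; overlapping calls
    are permitted and labelled once per clip per kind.
    """
    if not np.isfinite(truth.lam_aerial).all() or not np.isfinite(truth.lam_ground).all():
        raise ValueError("truth intensities must be finite")
    sunset = _naive_utc(truth.schedule.sunset)
    if interval is None:
        start, end = sunset, sunset + timedelta(minutes=truth.n_minutes)
    else:
        start, end = _naive_utc(interval[0]), _naive_utc(interval[1])
    dur_s = (end - start).total_seconds()
    if dur_s <= 0:
        raise ValueError("empty render interval")
    if dur_s > 14 * 3600:
        raise ValueError("refusing to render > 14 h of audio in one buffer")
    # align the render to the sunset-anchored 2-s grid
    rel0 = (start - sunset).total_seconds()
    if abs(rel0 % CLIP_SECONDS) > 1e-9:
        raise ValueError("interval start must sit on the sunset-anchored 2-s grid")

    rng = np.random.default_rng(seed)
    n = int(round(dur_s * SAMPLE_RATE))
    has_noise = noise.wind_level or noise.surf_level or (noise.crash_rate_per_min and noise.crash_level)
    buf = _ambient_noise(n, noise, rng) if has_noise else np.zeros(n, dtype=np.float32)

    events: list[tuple[float, float, str]] = []  # (t_start_s rel, dur_s, kind)

    def _add(wave: np.ndarray, t_rel: float):
        i0 = int(round(t_rel * SAMPLE_RATE))
        if i0 >= n:
            return
        seg = wave[: n - i0]
        buf[i0 : i0 + len(seg)] += seg.astype(np.float32)

    if placement == "per_clip":
        k = int(dur_s // CLIP_SECONDS)
        for i in range(k):
            w = synth_call("chatter", truth.call_params, seed=int(rng.integers(2**31)))
            amp = rng.uniform(*call_amp)
            _add(amp * w, i * CLIP_SECONDS)
            events.append((i * CLIP_SECONDS, len(w) / SAMPLE_RATE, "aerial"))
    elif placement == "poisson":
        m0 = int(rel0 // 60)
        m1 = int(np.ceil((rel0 + dur_s) / 60))
        for m in range(m0, min(m1, truth.n_minutes)):
            t_min = m * 60.0 - rel0  # minute start relative to buffer
            for lam, kind in ((truth.lam_aerial[m], "aerial"), (truth.lam_ground[m], "ground")):
                cnt = rng.poisson(lam)
                for _ in range(int(cnt)):
                    t_rel = t_min + rng.uniform(0, 60.0)
                    if t_rel < 0 or t_rel >= dur_s:
                        continue
                    w = synth_call(
                        "chatter" if kind == "aerial" else "purr",
                        truth.call_params,
                        seed=int(rng.integers(2**31)),
                    )
                    amp = rng.uniform(*call_amp)
                    _add(amp * w, t_rel)
                    events.append((t_rel, len(w) / SAMPLE_RATE, kind))
    else:
        raise ValueError(f"unknown placement {placement!r}")

    np.clip(buf, -1.0, 1.0, out=buf)

    n_clips = int(dur_s // CLIP_SECONDS)
    aerial = np.zeros(n_clips, dtype=bool)
    ground = np.zeros(n_clips, dtype=bool)
    n_air = np.zeros(n_clips, dtype=int)   # call onsets per clip
    n_gnd = np.zeros(n_clips, dtype=int)
    for t_rel, d, kind in events:
        c0 = int(t_rel // CLIP_SECONDS)
        c1 = int((t_rel + d) // CLIP_SECONDS)
        if 0 <= c0 < n_clips:
            (n_air if kind == "aerial" else n_gnd)[c0] += 1
        for c in range(max(c0, 0), min(c1, n_clips - 1) + 1):
            (aerial if kind == "aerial" else ground)[c] = True
    labels = pd.DataFrame(
        {
            "clip_start": [start + timedelta(seconds=i * CLIP_SECONDS) for i in range(n_clips)],
            "aerial": aerial,
            "ground": ground,
            "n_aerial_onsets": n_air,
            "n_ground_onsets": n_gnd,
        }
    )
    return buf, labels


def render_night_audio(
    truth: NightTruth,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    wav_path=None,
    labels_path=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the full night (sunset to sunrise) and optionally write WAV/CSV."""
    samples, labels = render_audio(truth, noise=noise, seed=seed)
    if wav_path is not None:
        write_wav(wav_path, samples)
    if labels_path is not None:
        labels.to_csv(labels_path, index=False)
    return samples, labels


def synth_camera_bursts(
    truth: NightTruth,
    design: CameraDesign = CameraDesign(),
    seed: int = 0,
    category_props: np.ndarray = DEFAULT_CATEGORY_PROPS,
) -> pd.DataFrame:
    """Per-frame detection counts for every burst of the night's active window.

    Burst start times step by the design interval through the local-clock
    active window (intersected with the night); detections per frame are
    Poisson with mean equal to the truth camera intensity at the burst
    midpoint, and each detection falls into a category by the configured
    multinomial (default: the pooled clear/eye-shine/wing/blur shares).
    """
    if design.frames_per_burst <= 0:
        raise ValueError("design must have >= 1 frame per burst")
    props = np.asarray(category_props, dtype=float)
    props = props / props.sum()
    rng = np.random.default_rng(seed)
    off = timedelta(hours=truth.schedule.local_utc_offset)
    # local 01:00-03:00 on the morning after the night's evening date
    morning = truth.night_date + timedelta(days=1)
    w0 = datetime(morning.year, morning.month, morning.day, design.active_window_local[0]) - off
    w1 = datetime(morning.year, morning.month, morning.day, design.active_window_local[1]) - off
    sunset = _naive_utc(truth.schedule.sunset)
    sunrise = _naive_utc(truth.schedule.sunrise)
    w0, w1 = max(w0, sunset), min(w1, sunrise)
    rows = []
    t = w0
    cam_ids = range(design.cameras_per_plot)
    while t < w1:
        mid = t + timedelta(seconds=design.burst_duration_s / 2)
        lam = truth.camera_intensity(mid)
        for cam in cam_ids:
            counts = rng.poisson(lam, size=design.frames_per_burst)
            cats = np.zeros((design.frames_per_burst, len(CATEGORIES)), dtype=int)
            for i, c in enumerate(counts):
                if c > 0:
                    cats[i] = rng.multinomial(c, props)
            for i in range(design.frames_per_burst):
                rows.append(
                    {
                        "night_date": truth.night_date.isoformat(),
                        "camera": cam,
                        "burst_start": t,
                        "frame_index": i,
                        "n_clear": cats[i, 0],
                        "n_eye_shine": cats[i, 1],
                        "n_wing": cats[i, 2],
                        "n_blur": cats[i, 3],
                    }
                )
        t = t + timedelta(minutes=design.burst_interval_min)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RadarFrameConfig:
    """Georeferenced radar screen-capture geometry."""

    frame_period_s: float = 2.4
    image_size: tuple[int, int] = (120, 120)   # (rows, cols)
    meters_per_pixel: float = 25.0
    center_px: tuple[int, int] = (60, 60)      # colony center (row, col)
    survey_radius_m: float = 1500.0

    def __post_init__(self):
        if self.meters_per_pixel <= 0:
            raise ValueError("meters_per_pixel must be positive")


def synth_radar_night(
    truth: NightTruth,
    framecfg: RadarFrameConfig = RadarFrameConfig(),
    seed: int = 0,
    interval: tuple[datetime, datetime] | None = None,
    frame_period_s: float | None = None,
    speckle_density: float = 0.002,
    value_threshold: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a stack of radar value-channel frames plus the clutter mask.

    Each frame carries (a) static land/wave clutter inside the mask region,
    (b) bright 2x2 target blobs (value above threshold) whose count per
    frame is Poisson with mean equal to the truth radar intensity, placed
    in the annulus around the colony, and (c) sub-threshold speckle.
    Returns (frames, land_mask): frames (n, H, W) float32 in [0, 1];
    land_mask bool (True where static clutter sits).
    """
    H, W = framecfg.image_size
    r_px = framecfg.survey_radius_m / framecfg.meters_per_pixel
    if r_px * 2 > max(H, W) * 2:
        raise ValueError("frame smaller than grid extent")
    period = framecfg.frame_period_s if frame_period_s is None else frame_period_s
    sunset = _naive_utc(truth.schedule.sunset)
    if interval is None:
        start, end = sunset, sunset + timedelta(minutes=truth.n_minutes)
    else:
        start, end = _naive_utc(interval[0]), _naive_utc(interval[1])
    n_frames = int((end - start).total_seconds() // period)
    if n_frames <= 0:
        raise ValueError("interval shorter than one frame period")

    rng = np.random.default_rng(seed)
    land = np.zeros((H, W), dtype=bool)
    land[: H // 4, :] = True  # coastline block along the top of the screen

    rows_g, cols_g = np.mgrid[0:H, 0:W]
    dist = np.hypot(rows_g - framecfg.center_px[0], cols_g - framecfg.center_px[1])
    annulus = (dist <= min(r_px, min(H, W) / 2 - 2)) & ~land
    ann_idx = np.flatnonzero(annulus[: H - 1, : W - 1].ravel())
    frames = np.zeros((n_frames, H, W), dtype=np.float32)
    for k in range(n_frames):
        f = frames[k]
        f[land] = 0.85 + 0.05 * rng.random(int(land.sum()))
        if speckle_density > 0:
            spk = rng.random((H, W)) < speckle_density
            f[spk & ~land] = rng.uniform(0.05, value_threshold * 0.8)
        t = start + timedelta(seconds=k * period)
        n_blobs = rng.poisson(truth.radar_intensity(t))
        if n_blobs and len(ann_idx):
            choice = rng.choice(ann_idx, size=n_blobs)
            rr, cc = np.unravel_index(choice, (H - 1, W - 1))
            for r, c in zip(rr, cc):
                f[r : r + 2, c : c + 2] = np.maximum(
                    f[r : r + 2, c : c + 2], rng.uniform(0.6, 0.95)
                )
    return frames, land
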