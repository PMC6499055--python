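"""Synthetic colony generator: attendance, calls, soundscape, camera, radar."""

from datetime import date, timedelta

import numpy as np
import pytest

from colonypulse.acoustic_pipeline import DEFAULT_SPECTRAL, stft_magnitude
from colonypulse.camera_counts import CameraDesign
from colonypulse.night_schedule import compute_night
from colonypulse.radar_pixels import PixelCriteria, build_mask, detect_pixels
from colonypulse.study import SITE_LAT, SITE_LON, SITE_UTC_OFFSET
from colonypulse.synthetic_colony import (
    CallParams,
    ColonyConfig,
    DEFAULT_CATEGORY_PROPS,
    NoiseSpec,
    RadarFrameConfig,
    render_audio,
    simulate_attendance,
    synth_call,
    synth_camera_bursts,
    synth_radar_night,
)

SILENT = NoiseSpec(0, 0, 0, 0)


def _truth(config, d=date(2015, 7, 10)):
    sched = compute_night(SITE_LAT, SITE_LON, d, SITE_UTC_OFFSET)
    return simulate_attendance(config, sched)


class TestAttendance:
    def test_empty_colony_has_zero_intensity(self):
        t = _truth(ColonyConfig(occupancy_prob=0.0))
        assert np.all(t.lam_aerial == 0) and np.all(t.lam_ground == 0)

    def test_moon_aversion_suppresses_on_full_moon(self):
        full = date(2015, 7, 2)
        base = _truth(ColonyConfig(moon_aversion=0.0), full)
        averse = _truth(ColonyConfig(moon_aversion=2.0), full)
        assert averse.lam_aerial.mean() < base.lam_aerial.mean()

    def test_expected_total_matches_generative_resummation(self):
        """Oracle: re-derive the per-minute intensity from the generative
        formula (shape x cycle x moon x occupancy) and re-sum it."""
        cfg = ColonyConfig(occupancy_prob=0.4, moon_aversion=1.3)
        t = _truth(cfg)
        sched = t.schedule
        n = t.n_minutes
        minutes = np.arange(n, dtype=float)
        shape = np.ones(n)
        shape[minutes < 60] = (minutes[minutes < 60] / 60.0) ** 2
        pe = cfg.plateau_hours[1] * 60
        tail = minutes > pe
        shape[tail] *= 0.5 * (1 + np.cos(np.pi * (minutes[tail] - pe) / (n - 1 - pe)))
        night_idx = (sched.date - cfg.season[0]).days
        cyc = 1 + cfg.cycle_amplitude * np.sin(2 * np.pi * night_idx / cfg.trip_cycle_days)
        moon = np.exp(-cfg.moon_aversion * sched.moon_illumination[:n]
                      * sched.moon_above[:n])
        occupied = cfg.occupancy_prob * cfg.burrow_density * 250.0
        expected = (cfg.flight_intensity_scale * occupied * shape * cyc * moon).sum()
        assert t.expected_total_aerial() == pytest.approx(expected, rel=1e-9)

    def test_attendance_shape_ramp_plateau_decline(self):
        t = _truth(ColonyConfig())
        lam = t.lam_aerial
        peak = lam.max()
        assert lam[:30].mean() < 0.2 * peak          # near zero first half hour
        assert lam[150:330].min() > 0.8 * peak       # plateau hours ~2.5-5.5
        assert lam[-30:].mean() < 0.2 * peak         # near zero by sunrise

    def test_doubling_occupancy_doubles_intensities(self):
        lo = _truth(ColonyConfig(occupancy_prob=0.3))
        hi = _truth(ColonyConfig(occupancy_prob=0.6))
        assert hi.expected_total_ground() == pytest.approx(2 * lo.expected_total_ground())
        assert hi.expected_total_aerial() >= lo.expected_total_aerial()

    def test_out_of_season_rejected(self):
        with pytest.raises(ValueError):
            _truth(ColonyConfig(), d=date(2015, 12, 1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ColonyConfig(occupancy_prob=1.5)
        with pytest.raises(ValueError):
            ColonyConfig(moon_aversion=-1)
        with pytest.raises(ValueError):
            ColonyConfig(plateau_hours=(6, 2))


class TestCalls:
    def test_chatter_peak_at_base_frequency(self):
        w = synth_call("chatter", base_hz=1419.0, seed=3)
        pad = np.zeros(32000)
        pad[: len(w)] = w
        spec = (stft_magnitude(pad) ** 2).mean(axis=0)
        bw = DEFAULT_SPECTRAL.bin_width_hz
        assert abs(int(spec.argmax()) - round(1419 / bw)) <= 1

    def test_purr_energy_concentrated_low(self):
        w = synth_call("purr", seed=4, duration_s=2.0)
        spec = (stft_magnitude(w[:32000]) ** 2).mean(axis=0)
        f = DEFAULT_SPECTRAL.bin_centers_hz()
        assert spec[f < 1700].sum() / spec.sum() >= 0.6

    @pytest.mark.parametrize("kind", ["chatter", "purr"])
    def test_amplitude_scale_invariant_spectrum_and_peak(self, kind):
        w = synth_call(kind, seed=5, duration_s=2.0)
        assert np.abs(w).max() <= 1.0
        s1 = stft_magnitude(np.pad(w, (0, max(0, 32000 - len(w))))[:32000])
        s2 = stft_magnitude(np.pad(2 * w, (0, max(0, 32000 - len(w))))[:32000])
        n1 = s1 / np.linalg.norm(s1)
        n2 = s2 / np.linalg.norm(s2)
        assert np.allclose(n1, n2, atol=1e-12)

    def test_out_of_band_base_frequency_rejected(self):
        with pytest.raises(ValueError):
            synth_call("chatter", base_hz=2500.0)
        with pytest.raises(ValueError):
            synth_call("purr", base_hz=500.0)
        with pytest.raises(ValueError):
            synth_call("squawk")


class TestRenderAudio:
    def test_silence_when_no_calls_no_noise(self):
        t = _truth(ColonyConfig(occupancy_prob=0.0))
        iv = (t.schedule.sunset, t.schedule.sunset + timedelta(minutes=2))
        samples, labels = render_audio(t, noise=SILENT, seed=0, interval=iv)
        assert np.all(samples == 0)
        assert not labels["aerial"].any() and not labels["ground"].any()
        assert len(labels) == 60

    def test_saturated_placement_labels_every_clip(self):
        t = _truth(ColonyConfig())
        iv = (t.schedule.sunset, t.schedule.sunset + timedelta(minutes=1))
        _, labels = render_audio(t, noise=SILENT, seed=0, interval=iv, placement="per_clip")
        assert labels["aerial"].all()
        assert len(labels) == 30  # detection ceiling per minute

    def test_poisson_totals_match_intensity(self):
        """Realized onset counts across seeded renders stay within 3 SD of
        the Poisson mean implied by the per-minute intensities."""
        t = _truth(ColonyConfig(occupancy_prob=0.5))
        iv = (t.schedule.sunset + timedelta(minutes=180),
              t.schedule.sunset + timedelta(minutes=190))
        lam_total = t.lam_aerial[180:190].sum() + t.lam_ground[180:190].sum()
        totals = []
        for s in range(20):
            _, labels = render_audio(t, noise=SILENT, seed=s, interval=iv)
            totals.append(labels["n_aerial_onsets"].sum() + labels["n_ground_onsets"].sum())
        mean_tot = np.mean(totals)
        se = np.sqrt(lam_total / 20)
        assert abs(mean_tot - lam_total) < 3 * se

    def test_reproducible_under_seed(self):
        t = _truth(ColonyConfig())
        iv = (t.schedule.sunset, t.schedule.sunset + timedelta(minutes=1))
        s1, l1 = render_audio(t, seed=42, interval=iv)
        s2, l2 = render_audio(t, seed=42, interval=iv)
        assert np.array_equal(s1, s2)
        assert l1.equals(l2)

    def test_duration_guard(self):
        t = _truth(ColonyConfig())
        iv = (t.schedule.sunset, t.schedule.sunset + timedelta(hours=15))
        with pytest.raises(ValueError):
            render_audio(t, interval=iv)


class TestCameraSynthesis:
    def test_zero_intensity_zero_counts(self):
        t = _truth(ColonyConfig(occupancy_prob=0.0))
        df = synth_camera_bursts(t, CameraDesign(), seed=0)
        assert df[["n_clear", "n_eye_shine", "n_wing", "n_blur"]].to_numpy().sum() == 0

    def test_category_shares_converge_to_default_multinomial(self):
        t = _truth(ColonyConfig(occupancy_prob=0.9, camera_gain=2.0))
        df = synth_camera_bursts(t, CameraDesign(), seed=1)
        totals = df[["n_clear", "n_eye_shine", "n_wing", "n_blur"]].sum().to_numpy(float)
        shares = totals / totals.sum()
        assert totals.sum() > 10_000
        assert np.allclose(shares, DEFAULT_CATEGORY_PROPS, atol=0.01)

    def test_frame_bookkeeping(self):
        t = _truth(ColonyConfig())
        design = CameraDesign(burst_interval_min=10)
        df = synth_camera_bursts(t, design, seed=2)
        n_bursts = df.groupby(["burst_start", "camera"]).ngroups
        assert len(df) == n_bursts * design.frames_per_burst
        assert df.groupby(["burst_start", "camera"]).size().eq(99).all()

    def test_zero_frames_per_burst_rejected(self):
        t = _truth(ColonyConfig())
        with pytest.raises(ValueError):
            synth_camera_bursts(t, CameraDesign(frames_per_burst=0), seed=0)

    def test_reproducible_under_seed(self):
        t = _truth(ColonyConfig())
        a = synth_camera_bursts(t, CameraDesign(), seed=9)
        b = synth_camera_bursts(t, CameraDesign(), seed=9)
        assert a.equals(b)


class TestRadarSynthesis:
    def _short(self, config, **kw):
        t = _truth(config)
        iv = (t.schedule.sunset + timedelta(minutes=200),
              t.schedule.sunset + timedelta(minutes=202))
        return synth_radar_night(t, RadarFrameConfig(), seed=5, interval=iv, **kw)

    def test_zero_intensity_no_speckle_gives_no_targets(self):
        frames, land = self._short(ColonyConfig(occupancy_prob=0.0), speckle_density=0.0)
        mask = build_mask(frames, persistence_q=0.9)
        for f in frames[:5]:
            assert detect_pixels(f, mask).sum() == 0

    def test_speckle_stays_below_threshold(self):
        frames, land = self._short(ColonyConfig(occupancy_prob=0.0))
        assert float(frames[0][~land].max(initial=0.0)) < PixelCriteria().value_min

    def test_targets_present_when_colony_active(self):
        frames, land = self._short(ColonyConfig(occupancy_prob=0.9, radar_gain=2.0))
        mask = build_mask(frames, persistence_q=0.9)
        counts = [int(detect_pixels(f, mask).sum()) for f in frames]
        assert max(counts) > 0
        assert all(c % 1 == 0 for c in counts)

    def test_reproducible_under_seed(self):
        a, _ = self._short(ColonyConfig())
        b, _ = self._short(ColonyConfig())
        assert np.array_equal(a, b)
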