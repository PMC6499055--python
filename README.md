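# colonypulse

Multi-sensor attendance monitoring for nocturnal burrow-nesting seabird
colonies — built around Leach's storm-petrel (*Hydrobates leucorhoa*), whose
colonies are visited only at night and are effectively uncountable by direct
observation. The package implements, as one tested pipeline, the remote
indices used to track such colonies and the statistics that compare them
against burrow occupancy (the ground truth from physically inspecting nests):

- **Acoustic call detection** — night recordings (16 kHz) are cut into 2-s
  clips; each clip gets a 187-bin spectrogram (372-sample FFT, 87.5% overlap)
  and a 610-element multiresolution feature vector (61 half-overlapping bands
  × 10 spectro-temporal operators). A CART tree pre-selects features and a
  small feed-forward network scores each clip for the aerial *chatter* call
  (threshold 0.99) and the burrow *purr* call (threshold 0.50). Detection is
  clip-binary, so rates saturate at 30 detections/min.
- **Flux-sensitivity QC** — a recording-quality scalar built from the mean
  and fourth-power-mean spectrum over a 5-clip context; it is exactly 0 for
  dead microphones, electrical fuzz, and diffuse wind/surf noise, and minutes
  with zero mean flux are dropped from every rate denominator.
- **Band-limited acoustic energy** — mean relative energy in 1,376–1,462 Hz,
  the chatter's peak band; unlike the detection rate it keeps growing with
  overlapping calls past saturation.
- **Camera counts** — 99-frame/49.5-s IR bursts converted to birds/min with
  four detection categories (clear / eye-shine / wing / blur) and the
  >75%-clear countability rule.
- **Radar pixel densities** — screen-capture frames masked for persistent
  clutter, thresholded in HSV, speckle-filtered by 8-connected components
  (extent ≥ 2 px), and summarized as pixels per hectare within 500 m and
  50 m of the colony.
- **Comparison layer** — burrow occupancy/density summaries, simple OLS with
  F tests, chi-square saturation contrasts, Wilcoxon rank-sum tests, and the
  logistic call-saturation model
  `rate = asymptote / (1 + exp((xmidpt − x)/scale))` with asymptote = 30 and
  xmidpt = 15 calls/min fixed, compared to a linear fit by Gaussian AIC.

Because the original field recordings are not distributable, the package
includes a first-class synthetic colony generator (`synthetic_colony`):
per-minute attendance intensities with the ramp–plateau–decline night shape,
multiplicative moonlight aversion, 2–3 day trip cycles, occupancy coupling;
synthesized chatter/purr calls; labelled night audio; camera burst tables;
and radar frame stacks — all byte-reproducible under a seed. Solar and lunar
timing come from a built-in ephemeris (`night_schedule`), cross-checked in
tests against an independently coded solar routine.

## Worked example

Simulate one mid-July night at a dense plot, render a 10-minute window from
the standard post-sunset comparison interval, and run the full acoustic
chain:

```python
from datetime import date
import numpy as np
from colonypulse import (ColonyConfig, CameraDesign, RateWindow, compute_night,
                         resolve_window, simulate_attendance)
from colonypulse.feature_bank import build_band_layout
from colonypulse.study import (SITE_LAT, SITE_LON, SITE_UTC_OFFSET,
                               process_window, train_call_models)
from colonypulse.synthetic_colony import render_audio, synth_camera_bursts
from colonypulse.call_classifier import predict
from colonypulse.acoustic_pipeline import QualityRecord, qc_filter
from colonypulse.acoustic_indices import per_minute_rates

night = compute_night(SITE_LAT, SITE_LON, date(2015, 7, 10), SITE_UTC_OFFSET)
print(f"sunset {night.sunset}Z  sunrise {night.sunrise}Z  "
      f"moon illumination {night.mean_illumination:.2f}")

colony = ColonyConfig(burrow_density=5.0, occupancy_prob=0.7)
truth = simulate_attendance(colony, night)
print(f"occupied burrows: {colony.occupied_burrows:.0f}  "
      f"peak aerial intensity: {truth.lam_aerial.max():.1f} calls/min")

fbank = build_band_layout()
models = train_call_models(fbank, seed=7)   # trains on synthesized clips, ~1 min

window = RateWindow("sunset", 120, 130)     # 10 min inside the 120-240 window
start, end = resolve_window(night, window)
samples, labels = render_audio(truth, seed=7, interval=(start, end))
res = process_window(samples, start, fbank)
quality = [QualityRecord(t, f) for t, f in zip(res.clip_starts, res.flux)]
events = predict(models["aerial"], res.features, clip_starts=res.clip_starts)
series = per_minute_rates(events, retained_minutes=qc_filter(quality),
                          span=(start, end))
print(f"aerial rate {np.nanmean(series.counts):.1f} calls/min "
      f"(true clip occupancy {labels['aerial'].mean():.2f}), "
      f"band energy {res.band_energy.mean():.5f}")

bursts = synth_camera_bursts(truth, CameraDesign(burst_interval_min=15), seed=7)
print(f"camera bursts: {bursts.groupby(['burst_start','camera']).ngroups}, "
      f"detections {bursts[['n_clear','n_eye_shine','n_wing','n_blur']].to_numpy().sum()}")
```

Output:

```
sunset 2015-07-11 03:48:56Z  sunrise 2015-07-11 12:56:44Z  moon illumination 0.23
occupied burrows: 875  peak aerial intensity: 43.7 calls/min
aerial rate 25.3 calls/min (true clip occupancy 0.93), band energy 0.00693
camera bursts: 24, detections 1932
```

Reading it: at 875 occupied burrows the simulated plateau traffic (43.7
expected calls/min) exceeds the 30/min clip-binarization ceiling, and even in
the post-sunset window 93% of 2-s clips contain a chatter — the detected rate
(25.3/min) is pressing against saturation, which is exactly the regime where
the band-energy index (0.00693 full-scale units) carries the remaining
abundance signal. The 24 bursts are 8 burst times × 3 cameras over the
01:00–03:00 design window.

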