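# Methods

`colonypulse` re-implements, as a tested pipeline, a multi-sensor monitoring
analysis for a nocturnal burrow-nesting seabird colony (Leach's storm-petrel,
*Hydrobates leucorhoa*): passive acoustic call detection and band-limited
energy, infrared camera counts, marine-radar pixel densities, burrow-occupancy
surveys, and the statistics that compare these indices. Because the original
field recordings and manual labels are not distributable, the package ships a
first-class synthetic colony generator that produces ground-truthed inputs for
every sensor; the tests and the acceptance study validate the pipeline against
that truth.

## Night frame

Every sensor samples from local sunset to sunrise, so the night — labelled by
the evening's calendar date — is the common frame. `night_schedule` computes
geometric sunset/sunrise (altitude-0 crossings on a 1-minute grid, no
refraction correction) from a compact ecliptic-longitude solar position, and a
minute-resolution lunar track (truncated lunar theory: the six largest
longitude terms and four latitude terms). Illuminated fraction is
(1 − cos ψ)/2 with ψ the geocentric elongation; the sun/moon distance-ratio
correction (<0.3%) is ignored. "Moon up" means geometric altitude > 0° with no
parallax or refraction — these are behavioural covariates sampled per minute,
not astronomy products. The test suite cross-checks rise/set against a second,
independently formulated solar routine (NOAA Fourier-series declination and
equation of time) to within ±5 minutes, and checks the phase extremes against
the known July 2015 lunar calendar. Timestamps are stored in UTC with an
explicit site UTC offset; local-clock windows (camera bursts at 01:00–03:00)
are resolved through that offset, never implicitly.

## Synthetic colony

`simulate_attendance` produces deterministic per-minute expected intensities;
all randomness happens at render time, so the occupancy→activity link is
exactly multiplicative and auditable:

- **Nightly shape** — quadratic ramp over the first hour (activity near zero
  in the first half hour), plateau from the end of the ramp until hour 6
  after sunset, cosine decline to zero at sunrise. Ground (purr) calling
  keeps the plateau until one hour before sunrise. The shape is a design
  choice consistent with the qualitative pattern radar and acoustics show
  (low first hour, high through hours 2–6, low by dawn).
- **Moonlight** — multiplicative suppression `exp(−aversion × illumination)`
  while the moon is above the horizon. The direction of the effect is well
  documented; its strength is not, so `moon_aversion` (default 1.0) is a free
  configuration parameter, not a calibrated value.
- **Foraging-trip cycle** — sinusoidal night-to-night modulation with period
  `trip_cycle_days` (default 2.5 d, amplitude 0.3), mirroring the 2–3 day
  autocorrelation structure seen in call rates.
- **Occupancy coupling** — both call intensities are proportional to the
  expected number of occupied burrows (occupancy probability × burrow density
  × plot area). Aerial gain defaults to 0.05 call events/min per occupied
  burrow so that the densest plots simulated (4.6 occupied burrows/m² on a
  250 m² plot) drive the soundscape well past the 30 detections/min ceiling,
  while the sparsest (0.03/m²) stay near zero; ground bouts use 0.001
  bouts/min per occupied burrow (bouts are long, so clip coverage is ~15×
  the bout rate).

Calls are synthesized from the species' published acoustic structure: the
chatter (aerial) call is a harmonic stack with base frequency 1–2 kHz (6 dB
per-harmonic roll-off) gated by a raised-cosine pulse train accelerating from
8 to 16 Hz over a 1.5-s call; the purr (ground) call is an amplitude-modulated
buzz at 800–1,000 Hz in long bouts (default 30 s) ending with a convex upward
sweep from 750 toward 1,600 Hz. Night audio is rendered at 16 kHz/16-bit by
inhomogeneous Poisson placement of calls over an ambient bed of low-passed
wind noise, band-limited surf noise, and sparse 0.4-s wave-crash transients
(default 2/min) — real surf is not perfectly stationary, and those transients
keep quiet-but-working minutes from being confused with a dead microphone by
the QC stage. Overlapping calls are allowed and labelled once per clip per
kind, which is precisely what produces detection saturation. A `per_clip`
placement mode deterministically starts one chatter in every 2-s clip to
construct fully saturated audio.

Camera bursts draw per-frame detection counts as Poisson with mean
proportional to the aerial intensity at the burst midpoint (`camera_gain`,
default 0.02 birds/frame per call/min); each detection is assigned to
clear/eye-shine/wing/blur by a multinomial with pooled default shares
0.747/0.085/0.060/0.109 (renormalized; the printed shares sum to 100.1%).
Radar frames carry static land clutter, sub-threshold speckle, and 2×2 target
blobs whose per-frame count is Poisson with mean `radar_gain × aerial
intensity`. Every generated artifact is byte-reproducible under a fixed seed.

What the generator does *not* emulate: rain, multi-species choruses (other
species appear only as noise), microphone degradation over time, radar wave
clutter beyond the static mask, and photorealistic IR imagery (camera counts
are generated directly). Passing tests therefore demonstrate that the
pipeline recovers truth under the stated statistical structure, not that the
classifier would match field performance on real recordings.

## Acoustic pipeline

Recordings are cut into non-overlapping 2-s clips on a grid anchored at
sunset (trailing partial clip dropped; stereo mono-mixed). Spectrograms use a
372-sample Hann window — 187 positive-frequency bins at fs/372 ≈ 43.01 Hz.
The nominal 0.875 overlap implies a fractional hop of 46.5 samples; the hop
is fixed at 46 samples (overlap 0.8763), the closest integer. Bin centers sit
at i × 43.01 Hz, i = 0…186; the "0–8041 Hz" labelling convention is 187 bins
× 43 Hz.

**Flux-sensitivity.** For a 5-clip context (2 clips each side; edges use what
exists), per frequency bin A(f) = mean |S| and G(f) = (mean |S|⁴)^¼; G lies
between the mean and the max spectrum. The quality scalar is

    F = max(0, k · log10( max_f [G(f)/A(f)] / c0 )),  k = 40, c0 = 1.9.

For stationary Gaussian noise the per-bin expectation of G/A is
8^¼/√(π/2) ≈ 1.342 regardless of the noise spectrum (each bin is normalized
by its own level); the maximum over 187 bins of finite, overlapping-frame
estimates sits near 1.7, so c0 = 1.9 clamps dead microphones, broadband fuzz,
and diffuse wind/surf to exactly 0 with margin, while transient calls (bin
ratios ≳ 5) score well above zero and increase with SNR. k = 40 places busy
clips on a ~0–120 scale. Minutes whose mean flux-sensitivity is 0 are removed
from all rate denominators (they become null, never zero).

## Feature bank and classifier

Each clip yields 610 features: 61 half-overlapping bands (36 of width
312.5 Hz, 16 of 687.5 Hz, 6 of 1437.5 Hz, 2 of 2937.5 Hz, plus one full-range
band; edges snapped to the bin grid) × 10 operators computed from the band
power time series: mean (tone), max (transient), temporal flux, adaptive
local-peak count (click), spectral entropy, temporal entropy, 2–20 Hz
modulation-energy fraction, skewness, kurtosis, and autocorrelation-peak
harmonicity. The per-resolution band split and the operator set are
reconstructions — only the 61-band/610-feature totals and the five resolution
widths are fixed by the source design — so the layout is serialized (JSON
sidecar) with every output for auditability. Energy-type operators (tone,
transient, flux) scale with amplitude²; the shape and periodicity operators
are amplitude-invariant; click counts can flip by ±1 under rescaling because
they are integer counts against an adaptive threshold.

Classification is a two-stage design: a CART decision tree ranks features by
impurity importance, a grid over subset sizes (default 25/50/100) picks the
count that maximizes validation sensitivity at the operating threshold, and
the selected features feed a fully connected network (two hidden layers,
64/32, ReLU, cross-entropy). Training runs to convergence (adam, ≤500 epochs,
L2 1e-5) rather than early-stopping: early-stopped networks leave the output
layer under-saturated, so unambiguous calls score ~0.94–0.98 and fall below
the 0.99 aerial operating threshold; an `early_stopping` flag restores the
alternative. Thresholds default to 0.99 (aerial) and 0.50 (ground). Detection
is clip-binary — one event per 2-s clip per kind — hence the hard ceiling of
30 accepted detections per minute. Evaluation reports accuracy =
TP/(TP+FP) among accepted detections and sensitivity = accepted-TP/condition
positives.

## Indices

Accepted detections aggregate to per-minute rates (≤30), hourly means over
QC-retained minutes, windowed nightly means (standard windows: 120–240 min
after sunset and 120–60 min before sunrise for aerial; 440–120 min before
sunrise for ground), and 29-night lunar-window means (center ± 14 nights,
closed on both ends). The band-limited energy index is the mean relative
spectral magnitude over the three bins centered at 1376/1419/1462 Hz,
averaged per clip, then per hour/night; "relative" means amplitudes are on
the full-scale [−1, 1] audio scale and no noise correction is applied. Energy
keeps rising with call overlap after the rate index has saturated, which is
why the two are kept side by side. Hourly energy averages over clips (not raw
STFT frames); with a fixed clip grid the two differ only in tail effects.

Radar frames are reduced by: persistence mask (pixels bright in ≥90% of
frames are clutter), HSV thresholding (saturation ≥ 0, value ≥ 0.4),
8-connected component filtering keeping components whose bounding-box major
dimension is ≥ 2 px ("diameter = 2" read as a minimum), and 1-ha grid
aggregation anchored at the colony center within 500 m and 50 m, at 1-minute
or hourly intervals. Cells count toward the mean when their square intersects
the analysis disc with positive area; pixels strictly inside the radius are
assigned to their cell, so per-cell counts conserve totals exactly.

Camera bursts (99 frames / 49.5 s) convert to birds/min by dividing the
combined four-category total by 0.825 min; a night is countable only if >75%
of frames are clear in ≥3 bursts. Quadrat surveys average per-quadrat
densities (SE across quadrats); censuses divide counts by summed plot area
(rectangle 250 m², circle π·49 m²). Unknown-status burrows are excluded from
numerator and denominator.

## Comparison statistics

Simple OLS (slope, R², adjusted R², F = (R²/1)/((1−R²)/(n−2)), p from
F(1, n−2)) treats nights as independent. Saturation frequency uses a 2×2
Pearson chi-square (no continuity correction) on saturated (≥20 calls/min)
vs not, by group. Island/month contrasts use the Wilcoxon rank-sum test:
exact for tie-free samples of ≤10 per group, normal approximation with tie
correction otherwise; fully tied data give p = 1.

The call-saturation model links a bounded aerial call rate to an abundance
covariate x (nightly acoustic energy):

    rate(x) = asymptote / (1 + exp((xmidpt − x) / scale))

with asymptote fixed at 30 calls/min and xmidpt at 15 by default; only
`scale` — the covariate change that moves the rate from 1/2 to ~3/4 of the
asymptote — is estimated by nonlinear least squares. Model comparison uses
Gaussian AIC with σ² profiled out (k = mean-function parameters + 1), making
logistic and linear AICs commensurable. When the covariate lives on an
arbitrary scale (as the relative energy index does — its values are far from
15), the midpoint is not meaningful a priori; `fit_saturation(..., xmidpt=None)`
estimates it too, and a fully free 3-parameter variant sits behind
`free_asymptote=True`. The end-to-end study uses the free-midpoint variant.
Binomial GAMs for hourly rates and mixed-effects camera models are out of
scope: the pipeline exports tidy hourly covariate tables (rates, flux, moon
state) for external fitting instead.

## End-to-end study (`study.run_occupancy_study`)

Eight plot-seasons span occupied densities 0.03–4.6 burrows/m² (log-spaced;
burrow density 5/m², occupancy probability set accordingly), two nights each
(July 10 and 15, 2015, at the southern-Oregon site coordinates), classifiers
trained freshly from the given seed. Problem sizes are the package's choice
for a single-CPU run: per night, two 20-minute audio sub-windows are rendered
and fully processed — one starting 180 min before sunrise (inside the
440–120-min pre-sunrise ground window; aerial traffic is still near plateau
there, supplying the saturation model's rate/energy pairs) and one starting
120 min before sunrise (the standard non-peak aerial comparison window).
Window offsets are expressed from sunset in whole minutes so each window sits
on the sunset-anchored 2-s clip grid. Camera bursts cover the full 01:00–
03:00 design. Season-mean indices regress on true occupied density (n = 8);
nightly (energy, rate) pairs (n = 16) feed the logistic-vs-linear AIC
comparison. Radar is validated separately on constructed and short synthetic
stacks (its index is proportional to the same aerial intensity by
construction, so including it in the regression study would test nothing the
camera index does not).

## Numerical choices and degenerate inputs

- STFT is computed by strided framing + batched real FFT (identical values to
  the reference scipy path, verified in tests); audio buffers are float32.
- Entropy of an all-zero distribution is 0 by convention; silence yields an
  all-zero feature vector; flux-sensitivity of empty or all-zero contexts is 0.
- Curve fits that fail to converge are flagged in the result object, never
  silently replaced; zero-variance regressors raise.
- `render_audio` refuses intervals >14 h; off-grid interval starts raise
  rather than being silently shifted.
- Seeds: every stochastic routine takes an explicit seed; child seeds are
  drawn below 2³¹.

## Known limitations

- The flux-sensitivity scalar matches the published contract (ingredients,
  zero conditions, 0–120 scale, ordering) but the original formula and its
  exact scaling are unpublished; constants k and c0 are this package's
  documented calibration.
- The per-resolution band split (36/16/6/2+1) and the 10 operators are
  reconstructions; models trained on one layout are not transferable to
  another (the layout hash travels with the model bundle).
- Classifier performance numbers on real field recordings are not
  reproducible here and are not claimed; synthetic accuracy/sensitivity are
  properties of the generator's separability.
- Energy is not corrected for non-target sound in 1376–1462 Hz; in synthetic
  nights the ambient bed is designed to sit mostly below that band.
- Occupancy regressions treat nights and plot-seasons as independent, as the
  comparison layer assumes; no autocorrelation correction is applied.
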