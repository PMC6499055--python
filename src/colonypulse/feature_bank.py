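"""Multiresolution spectro-temporal feature bank (61 bands x 10 operators).

Each 2-second clip spectrogram is summarized in 61 half-overlapping
frequency bands drawn from four finite resolutions (312.5, 687.5, 1437.5
and 2937.5 Hz wide) plus one full-range band, with 10 feature operators per
band — 610 candidate features per clip. Band edges are snapped to the
43.01 Hz spectrogram bin grid, and the (band, operator) ordering is fixed
and serialized alongside every output so downstream models are auditable.

The operator set spans spectral level (tone, transient), temporal change
(flux, click count), distributional shape (spectral/temporal entropy,
skewness, kurtosis), and periodic structure (2-20 Hz modulation fraction,
autocorrelation harmonicity). Energy-type operators scale with squared
amplitude; the shape/periodicity operators are amplitude-invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as _fft

from .acoustic_pipeline import DEFAULT_SPECTRAL, ClipSpectrogram, SpectralConfig

__all__ = [
    "FEATURE_TYPES",
    "BandSpec",
    "FeatureBankConfig",
    "FeatureVector",
    "build_band_layout",
    "extract_features",
    "extract_features_batch",
]

# fixed operator order; index = position in each band's 10-feature block
FEATURE_TYPES = (
    "tone",            # mean band power
    "transient",       # max frame band power
    "flux",            # mean abs frame-to-frame band power change
    "click",           # local-maxima count above adaptive threshold
    "spectral_entropy",
    "temporal_entropy",
    "modulation_2_20", # fraction of band-power modulation energy in 2-20 Hz
    "skewness",
    "kurtosis",
    "harmonicity",     # peak normalized autocorrelation (lag >= min lag)
)

# half-overlapping band widths in Hz; counts chosen to cover ~0-5.8 kHz,
# the species' call band, and to total 61 with the full-range band
_RESOLUTIONS = ((312.5, 36), (687.5, 16), (1437.5, 6), (2937.5, 2))


@dataclass(frozen=True)
class BandSpec:
    low_hz: float
    high_hz: float
    resolution_hz: float  # nominal width class; inf marks the full-range band

    def bin_slice(self, cfg: SpectralConfig) -> tuple[int, int]:
        """Half-open bin index range [lo, hi) after snapping edges to the grid."""
        bw = cfg.bin_width_hz
        lo = int(round(self.low_hz / bw))
        hi = int(round(self.high_hz / bw))
        return max(lo, 0), min(max(hi, lo + 1), cfg.n_bins)


@dataclass
class FeatureBankConfig:
    bands: tuple[BandSpec, ...]
    spectral: SpectralConfig = field(default_factory=SpectralConfig)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_features(self) -> int:
        return len(self.bands) * len(FEATURE_TYPES)

    def feature_names(self) -> list[str]:
        return [
            f"b{i:02d}_{int(b.low_hz)}_{int(b.high_hz)}_{t}"
            for i, b in enumerate(self.bands)
            for t in FEATURE_TYPES
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_types": list(FEATURE_TYPES),
                "bands": [
                    {"low_hz": b.low_hz, "high_hz": b.high_hz, "resolution_hz": b.resolution_hz}
                    for b in self.bands
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str, spectral: SpectralConfig = DEFAULT_SPECTRAL):
        obj = json.loads(text)
        if tuple(obj["feature_types"]) != FEATURE_TYPES:
            raise ValueError("feature-type order mismatch")
        bands = tuple(
            BandSpec(b["low_hz"], b["high_hz"], b["resolution_hz"]) for b in obj["bands"]
        )
        return cls(bands=bands, spectral=spectral)


@dataclass
class FeatureVector:
    clip_start: object
    values: np.ndarray  # length 610, ordered (band, feature_type)


def build_band_layout(spectral: SpectralConfig = DEFAULT_SPECTRAL) -> FeatureBankConfig:
    """Construct the default 61-band layout (36/16/6/2 finite-width + full range)."""
    bands: list[BandSpec] = []
    for width, count in _RESOLUTIONS:
        step = width / 2.0  # half-overlap
        for k in range(count):
            bands.append(BandSpec(k * step, k * step + width, width))
    nyq = spectral.sample_rate / 2.0
    bands.append(BandSpec(0.0, nyq, float("inf")))
    cfg = FeatureBankConfig(bands=tuple(bands), spectral=spectral)
    if cfg.n_bands != 61 or cfg.n_features != 610:
        raise ValueError(
            f"band layout must give 61 bands / 610 features, got {cfg.n_bands}/{cfg.n_features}"
        )
    return cfg


def _band_matrix(cfg: FeatureBankConfig) -> np.ndarray:
    """(n_bands, n_bins) 0/1 membership matrix."""
    B = np.zeros((cfg.n_bands, cfg.spectral.n_bins))
    for i, b in enumerate(cfg.bands):
        lo, hi = b.bin_slice(cfg.spectral)
        B[i, lo:hi] = 1.0
    return B


def _entropy(p: np.ndarray, axis: int) -> np.ndarray:
    """Shannon entropy of a nonnegative array normalized along ``axis``;
    all-zero slices give 0 by convention."""
    tot = p.sum(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(tot > 0, p / np.where(tot > 0, tot, 1.0), 0.0)
        h = -np.where(q > 0, q * np.log(q), 0.0).sum(axis=axis)
    return h


def extract_features_batch(
    spectrograms: Sequence[ClipSpectrogram] | np.ndarray,
    cfg: FeatureBankConfig,
) -> np.ndarray:
    """Feature matrix (n_clips, 610) for a batch of equal-shape spectrograms.

    Vectorized over clips and bands: all operators are computed from the
    per-band power time series X[c, b, t] = sum of squared magnitudes over
    the band's bins at frame t, plus the per-band mean spectrum.
    """
    if isinstance(spectrograms, np.ndarray):
        mags = spectrograms
    else:
        mags = np.stack([s.frames for s in spectrograms])  # (C, T, F)
    power = np.square(mags.astype(np.float32))
    B = _band_matrix(cfg).astype(np.float32)    # (Nb, F)
    X = np.swapaxes(power @ B.T, 1, 2)          # band power series (C, Nb, T)
    X = np.ascontiguousarray(X)
    C, Nb, T = X.shape

    feats = np.empty((C, Nb, len(FEATURE_TYPES)), dtype=np.float64)
    mu = X.mean(axis=2, keepdims=True)
    sd = X.std(axis=2, keepdims=True)
    degen = sd[:, :, 0] == 0
    feats[:, :, 0] = mu[:, :, 0]                            # tone
    feats[:, :, 1] = X.max(axis=2)                          # transient
    feats[:, :, 2] = np.abs(np.diff(X, axis=2)).mean(axis=2)  # flux

    # click: local maxima above mean + 2 sd of the band series
    thr = mu + 2.0 * sd
    mid = X[:, :, 1:-1]
    is_peak = (mid > X[:, :, :-2]) & (mid >= X[:, :, 2:]) & (mid > thr)
    feats[:, :, 3] = is_peak.sum(axis=2)
    feats[:, :, 3][degen] = 0.0

    # spectral entropy over the band's bins (mean power spectrum)
    mean_spec = power.mean(axis=1)                          # (C, F)
    spec_h = np.empty((C, Nb))
    for i, b in enumerate(cfg.bands):
        lo, hi = b.bin_slice(cfg.spectral)
        spec_h[:, i] = _entropy(mean_spec[:, lo:hi], axis=1)
    feats[:, :, 4] = spec_h
    feats[:, :, 5] = _entropy(X, axis=2)                    # temporal entropy

    # modulation spectrum of the band power series
    frame_rate = cfg.spectral.sample_rate / cfg.spectral.hop
    Xc = X - mu
    M = np.square(np.abs(_fft.rfft(Xc, axis=2)))          # (C, Nb, T//2+1)
    mfreq = _fft.rfftfreq(T, d=1.0 / frame_rate)
    band_sel = (mfreq >= 2.0) & (mfreq <= 20.0)
    tot_mod = M[:, :, 1:].sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot_mod > 0, M[:, :, band_sel].sum(axis=2) / np.where(tot_mod > 0, tot_mod, 1.0), 0.0)
    feats[:, :, 6] = frac

    # standardized temporal moments
    with np.errstate(invalid="ignore", divide="ignore"):
        z = Xc / np.where(sd > 0, sd, 1.0)
    z2 = z * z
    feats[:, :, 7] = (z2 * z).mean(axis=2)
    feats[:, :, 7][degen] = 0.0
    feats[:, :, 8] = (z2 * z2).mean(axis=2)
    feats[:, :, 8][degen] = 0.0

    # harmonicity: max normalized autocorrelation at lags >= ~5 ms of frames
    ac = _fft.irfft(M, n=T, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ac0 = ac[:, :, :1]
        acn = ac / np.where(ac0 > 0, ac0, 1.0)
        acn[np.broadcast_to(ac0 <= 0, acn.shape)] = 0.0
    min_lag = max(2, int(round(frame_rate * 0.005)))
    max_lag = T // 2
    if max_lag > min_lag:
        feats[:, :, 9] = acn[:, :, min_lag:max_lag].max(axis=2)
    else:
        feats[:, :, 9] = 0.0
    feats[:, :, 9][degen] = 0.0

    out = feats.reshape(C, Nb * len(FEATURE_TYPES))
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


def extract_features(spec: ClipSpectrogram, cfg: FeatureBankConfig) -> FeatureVector:
    """610-element feature vector for one clip spectrogram."""
    if spec.n_bins != cfg.spectral.n_bins:
        raise ValueError(f"expected {cfg.spectral.n_bins} bins, got {spec.n_bins}")
    vals = extract_features_batch(np.asarray(spec.frames)[None, :, :], cfg)[0]
    return FeatureVector(clip_start=spec.clip_start, values=vals)
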