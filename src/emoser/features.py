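"""Three-channel log-Mel spectrogram features.

The front end converts a waveform into a t x f x 3 tensor: channel 0 is
the static log-Mel spectrogram (Hamming-windowed framing, power spectrum,
triangular Mel filterbank, natural log with an additive floor), channel 1
its regression delta and channel 2 the delta of the delta, the standard
"static + deltas + delta-deltas" representation used throughout the SER
literature.

The regression delta of a frame sequence m_i with half-width N is

    d_i = sum_{n=1..N} n (m_{i+n} - m_{i-n}) / (2 sum_{n=1..N} n^2)

with out-of-range frames replicated from the edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio import AudioClip, TooShortError, resample, standardize

__all__ = [
    "FeatureConfig", "LogMelFeature", "frame_power_spectrum",
    "mel_filterbank", "log_mel", "delta", "extract_features",
    "save_features", "load_features", "CHANNEL_NAMES",
]

CHANNEL_NAMES = ("static", "deltas", "delta-deltas")


@dataclass
class FeatureConfig:
    """Front-end parameters.

    Defaults: 25 ms Hamming windows, 10 ms hop, regression half-width
    N = 2, 64 Mel bands (so that three frequency poolings by 4 collapse
    the Mel axis to a single band), FFT size = next power of two at or
    above the window length, 16 kHz working rate.
    """

    sample_rate: int = 16000
    window_ms: float = 25.0
    hop_ms: float = 10.0
    n_mels: int = 64
    delta_width: int = 2
    fft_size: int | None = None
    log_floor: float = 1e-10
    fmin: float = 0.0
    fmax: float | None = None

    def __post_init__(self) -> None:
        if not (self.window_ms > self.hop_ms > 0):
            raise ValueError("require window_ms > hop_ms > 0")
        if self.delta_width < 1:
            raise ValueError("delta_width must be >= 1")
        if self.n_mels < 8:
            raise ValueError("n_mels must be >= 8")

    @property
    def win_samples(self) -> int:
        return int(round(self.sample_rate * self.window_ms / 1000.0))

    @property
    def hop_samples(self) -> int:
        return int(round(self.sample_rate * self.hop_ms / 1000.0))

    @property
    def n_fft(self) -> int:
        if self.fft_size is not None:
            return self.fft_size
        n = 1
        while n < self.win_samples:
            n *= 2
        return n

    def to_dict(self) -> dict:
        return {
            "sample_rate": self.sample_rate, "window_ms": self.window_ms,
            "hop_ms": self.hop_ms, "n_mels": self.n_mels,
            "delta_width": self.delta_width, "fft_size": self.fft_size,
            "log_floor": self.log_floor, "fmin": self.fmin, "fmax": self.fmax,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**d)


@dataclass
class LogMelFeature:
    """t x f x 3 log-Mel tensor with per-frame center times (seconds)."""

    values: np.ndarray
    frame_times: np.ndarray
    clip_id: str = ""
    speaker_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("values must be a [t][f][3] array")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_mels(self) -> int:
        return self.values.shape[1]

    def channels(self, indices) -> np.ndarray:
        """Select a channel subset (for the feature-ablation harness)."""
        indices = list(indices)
        if not indices:
            raise ValueError("channel subset must be non-empty")
        return self.values[:, :, indices]


def frame_power_spectrum(clip: AudioClip, cfg: FeatureConfig) -> np.ndarray:
    """Hamming-windowed framing followed by the DFT power spectrum.

    Returns a [t][n_fft//2 + 1] nonnegative matrix with
    t = 1 + floor((L - win) / hop).  Clips at another rate are resampled
    to ``cfg.sample_rate`` first.
    """
    clip = resample(clip, cfg.sample_rate)
    x = clip.samples
    win, hop = cfg.win_samples, cfg.hop_samples
    if x.size < win:
        raise TooShortError(
            f"clip {clip.clip_id!r}: {x.size} samples < one {win}-sample window")
    n_frames = 1 + (x.size - win) // hop
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[::hop][:n_frames]
    frames = frames * np.hamming(win)
    spec = np.fft.rfft(frames, n=cfg.n_fft, axis=1)
    return np.abs(spec) ** 2


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular Mel filterbank, shape [n_mels][n_fft//2 + 1]."""
    if fmax is None:
        fmax = sample_rate / 2.0

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, bin_freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bin_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def log_mel(power: np.ndarray, cfg: FeatureConfig,
            filterbank: np.ndarray | None = None) -> np.ndarray:
    """Apply the Mel filterbank and the natural log with an additive floor."""
    power = np.asarray(power, dtype=np.float64)
    if np.any(power < 0):
        raise ValueError("power spectrum must be nonnegative")
    if filterbank is None:
        filterbank = mel_filterbank(cfg.n_mels, cfg.n_fft, cfg.sample_rate,
                                    cfg.fmin, cfg.fmax)
    return np.log(power @ filterbank.T + cfg.log_floor)


def delta(x: np.ndarray, n: int) -> np.ndarray:
    """Per-band regression delta with edge replication; same shape as x."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a [t][f] matrix")
    if n < 1:
        raise ValueError("regression half-width must be >= 1")
    t = x.shape[0]
    xp = np.pad(x, ((n, n), (0, 0)), mode="edge")
    num = np.zeros_like(x)
    for k in range(1, n + 1):
        num += k * (xp[n + k:n + k + t] - xp[n - k:n - k + t])
    denom = 2.0 * sum(k * k for k in range(1, n + 1))
    return num / denom


def extract_features(clip: AudioClip, cfg: FeatureConfig | None = None,
                     zscore: bool = True) -> LogMelFeature:
    """Full front end: z-score, frame, log-Mel, deltas, delta-deltas.

    ``zscore=False`` skips the waveform standardization (useful when the
    caller has already normalized, or to study gain behaviour).
    """
    if cfg is None:
        cfg = FeatureConfig()
    if zscore:
        clip = standardize(clip)
    power = frame_power_spectrum(clip, cfg)
    static = log_mel(power, cfg)
    d1 = delta(static, cfg.delta_width)
    d2 = delta(d1, cfg.delta_width)
    values = np.stack([static, d1, d2], axis=-1)
    times = (np.arange(static.shape[0]) * cfg.hop_samples
             + cfg.win_samples / 2.0) / cfg.sample_rate
    return LogMelFeature(values, times, clip_id=clip.clip_id,
                         speaker_id=clip.speaker_id, label=clip.label)


def save_features(path: str | Path, feat: LogMelFeature,
                  cfg: FeatureConfig) -> None:
    """Cache a feature tensor as .npy with a JSON sidecar for the config."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), feat.values)
    sidecar = {
        "config": cfg.to_dict(), "clip_id": feat.clip_id,
        "speaker_id": feat.speaker_id, "label": feat.label,
        "frame_times": feat.frame_times.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_features(path: str | Path) -> tuple[LogMelFeature, FeatureConfig]:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    feat = LogMelFeature(values, np.asarray(meta["frame_times"]),
                         clip_id=meta["clip_id"], speaker_id=meta["speaker_id"],
                         label=meta["label"])
    return feat, FeatureConfig.from_dict(meta["config"])
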