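"""Audio clip container, WAV I/O, resampling and z-score standardization.

A clip is a mono float64 waveform plus the metadata the rest of the
pipeline needs: a speaker identifier (for speaker-independent folds), an
optional categorical emotion label and an opaque clip id.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import gcd
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly


class AudioError(ValueError):
    """Invalid audio input."""


class ZeroVarianceError(AudioError):
    """A constant signal cannot be z-scored."""


class TooShortError(AudioError):
    """Clip shorter than one analysis window."""


@dataclass
class AudioClip:
    samples: np.ndarray
    sample_rate: int
    clip_id: str = ""
    speaker_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise AudioError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise AudioError("samples must be finite")
        if int(self.sample_rate) <= 0:
            raise AudioError("sample_rate must be a positive integer")
        self.sample_rate = int(self.sample_rate)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


def read_wav(path: str | Path, clip_id: str | None = None,
             speaker_id: str = "", label: str | None = None) -> AudioClip:
    """Read a RIFF WAV file as a mono float clip.

    Integer PCM is rescaled to [-1, 1); stereo is downmixed by channel
    averaging.
    """
    sr, data = wavfile.read(str(path))
    if data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype.kind == "i":
        data = data.astype(np.float64) / float(2 ** (8 * data.dtype.itemsize - 1))
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioClip(data, int(sr),
                     clip_id=clip_id if clip_id is not None else Path(path).stem,
                     speaker_id=speaker_id, label=label)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 32-bit float WAV (amplitudes clipped to [-1, 1])."""
    wavfile.write(str(path), clip.sample_rate,
                  np.clip(clip.samples, -1.0, 1.0).astype(np.float32))


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Polyphase resampling to ``target_rate`` (no-op if already there)."""
    if target_rate == clip.sample_rate:
        return clip
    g = gcd(int(target_rate), clip.sample_rate)
    y = resample_poly(clip.samples, target_rate // g, clip.sample_rate // g)
    return replace(clip, samples=y, sample_rate=int(target_rate))


def standardize(clip: AudioClip) -> AudioClip:
    """z-score the waveform (population standard deviation).

    Raises :class:`ZeroVarianceError` for a constant signal.
    """
    mu = clip.samples.mean()
    sigma = clip.samples.std()  # ddof=0
    if sigma < 1e-12:
        raise ZeroVarianceError(
            f"clip {clip.clip_id!r} has (near-)zero variance; cannot z-score")
    return replace(clip, samples=(clip.samples - mu) / sigma)
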