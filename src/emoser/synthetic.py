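"""Synthetic labeled-audio generator.

Emotion classes are emulated as amplitude-modulated multi-tone signals
whose carrier bands and modulation rates differ per class; speakers are
a nuisance factor implemented as a per-speaker pitch offset and noise
floor.  This reproduces the statistical structure the recognition
pipeline relies on — classes separable in the (log-Mel) spectral domain,
speaker variation orthogonal to class — while keeping ground truth exact
and generation instant.  No attempt is made at naturalistic speech.

The trial-record generator additionally emulates the downstream
annotation study: two defendant groups with group-specific emotion
distributions, several utterances per defendant, and three simulated
expert annotations per utterance obtained by corrupting the true label
with a configurable error rate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio import AudioClip, write_wav

__all__ = [
    "SynthSpec", "GroupSpec", "TrialSpec", "TrialRecord", "Utterance",
    "class_profile", "speaker_profile", "generate_clip", "generate_dataset",
    "generate_trial_records", "write_dataset", "COURT_EMOTIONS",
]

#: the emotion categories observed in the courtroom analysis
COURT_EMOTIONS = ("angry", "neutral", "fear")


@dataclass
class SynthSpec:
    """Study conditions for the synthetic corpus.

    Defaults give 3 classes x 5 speakers x 4 clips = 60 balanced clips
    of 1 s at 16 kHz with a 20 dB SNR — spectrally well separated classes
    (600 Hz apart) against moderate speaker offsets (within +-60 Hz).
    ``band_separation_hz`` is the separability knob: widening it moves
    class carriers further apart.
    """

    n_classes: int = 3
    n_speakers: int = 5
    clips_per_speaker_per_class: int = 4
    duration_s: float = 1.0
    sample_rate: int = 16000
    base_freq_hz: float = 400.0
    band_separation_hz: float = 600.0
    mod_rate_base_hz: float = 2.0
    mod_rate_step_hz: float = 1.5
    mod_depth: float = 0.5
    speaker_offset_span_hz: float = 120.0
    snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.n_speakers < 2:
            raise ValueError("need >= 2 classes and >= 2 speakers")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite (use a large value "
                             "for an effectively noise-free clip)")

    def class_labels(self) -> list[str]:
        return [f"class{k}" for k in range(self.n_classes)]

    def speaker_ids(self) -> list[str]:
        return [f"spk{s:02d}" for s in range(self.n_speakers)]


def class_profile(spec: SynthSpec, class_id: int) -> dict:
    """Carrier frequencies and modulation rate of one emotion class."""
    center = spec.base_freq_hz + spec.band_separation_hz * class_id
    return {
        "center_hz": center,
        # a weak upper partial makes the band structure richer than a
        # single line without moving the spectral peak
        "tones_hz": (center, 1.5 * center),
        "tone_amps": (1.0, 0.3),
        "mod_rate_hz": spec.mod_rate_base_hz + spec.mod_rate_step_hz * class_id,
    }


def speaker_profile(spec: SynthSpec, speaker_idx: int) -> dict:
    """Pitch offset and noise-floor tweak of one speaker."""
    if spec.n_speakers == 1:
        offset = 0.0
    else:
        offset = np.linspace(-0.5, 0.5, spec.n_speakers)[speaker_idx] \
            * spec.speaker_offset_span_hz
    noise_db = np.linspace(-2.0, 2.0, spec.n_speakers)[speaker_idx]
    return {"pitch_offset_hz": float(offset), "snr_offset_db": float(noise_db)}


def _clip_rng(spec: SynthSpec, class_id: int, speaker_idx: int,
              clip_idx: int, seed: int | None) -> np.random.Generator:
    root = spec.seed if seed is None else seed
    return np.random.default_rng(
        np.random.SeedSequence((root, class_id, speaker_idx, clip_idx)))


def generate_clip(class_id: int, speaker_idx: int, spec: SynthSpec,
                  seed: int | None = None, clip_idx: int = 0) -> AudioClip:
    """One synthetic utterance; bit-identical for identical arguments."""
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id {class_id} out of range")
    if not 0 <= speaker_idx < spec.n_speakers:
        raise ValueError(f"speaker_idx {speaker_idx} out of range")
    rng = _clip_rng(spec, class_id, speaker_idx, clip_idx, seed)
    cp = class_profile(spec, class_id)
    sp = speaker_profile(spec, speaker_idx)
    n = int(round(spec.duration_s * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    sig = np.zeros(n)
    for f0, amp in zip(cp["tones_hz"], cp["tone_amps"]):
        phase = rng.uniform(0, 2 * np.pi)
        sig += amp * np.sin(2 * np.pi * (f0 + sp["pitch_offset_hz"]) * t
                            + phase)
    mod_phase = rng.uniform(0, 2 * np.pi)
    sig *= 1.0 + spec.mod_depth * np.sin(
        2 * np.pi * cp["mod_rate_hz"] * t + mod_phase)
    snr_db = spec.snr_db + sp["snr_offset_db"]
    sig_power = float(np.mean(sig ** 2))
    noise_power = sig_power / (10.0 ** (snr_db / 10.0))
    sig = sig + rng.normal(0.0, np.sqrt(noise_power), size=n)
    sig /= np.max(np.abs(sig))
    return AudioClip(
        sig, spec.sample_rate,
        clip_id=f"c{class_id}_s{speaker_idx:02d}_{clip_idx:03d}",
        speaker_id=spec.speaker_ids()[speaker_idx],
        label=spec.class_labels()[class_id])


def generate_dataset(spec: SynthSpec) -> list[AudioClip]:
    """Balanced corpus: n_speakers x n_classes x clips_per_speaker_per_class."""
    clips = []
    for speaker_idx in range(spec.n_speakers):
        for class_id in range(spec.n_classes):
            for clip_idx in range(spec.clips_per_speaker_per_class):
                clips.append(generate_clip(class_id, speaker_idx, spec,
                                           clip_idx=clip_idx))
    return clips


def write_dataset(clips, out_dir: str | Path,
                  manifest_name: str = "manifest.csv") -> Path:
    """Write WAV files plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / manifest_name
    with manifest.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["clip_id", "path", "speaker_id", "label"])
        for clip in clips:
            path = out_dir / f"{clip.clip_id}.wav"
            write_wav(path, clip)
            w.writerow([clip.clip_id, path.name, clip.speaker_id, clip.label])
    return manifest


# ---------------------------------------------------------------------------
# trial records (annotation/association stand-in)


@dataclass
class GroupSpec:
    """One defendant group and its emotion distribution."""

    name: str
    n_defendants: int
    emotion_probs: dict  # emotion -> probability, sums to 1

    def __post_init__(self) -> None:
        total = sum(self.emotion_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"emotion_probs must sum to 1, got {total}")


@dataclass
class TrialSpec:
    """Conditions of the synthetic courtroom study.

    Default group emotion distributions are the empirical person-level
    proportions of the two published defendant groups: 13/6/8 out of 27
    (angry/neutral/fear) with addiction, 5/18/4 without.
    """

    groups: tuple = (
        GroupSpec("addiction", 27,
                  {"angry": 13 / 27, "neutral": 6 / 27, "fear": 8 / 27}),
        GroupSpec("non-addiction", 27,
                  {"angry": 5 / 27, "neutral": 18 / 27, "fear": 4 / 27}),
    )
    clips_per_defendant: int = 3
    expert_error_rate: float = 0.1
    expression_rate: float = 0.7  # share of clips showing the person emotion
    n_experts: int = 3
    seed: int = 0
    audio: SynthSpec | None = None  # set to synthesize waveforms


@dataclass
class Utterance:
    clip_id: str
    true_label: str
    expert_labels: tuple
    clip: AudioClip | None = None


@dataclass
class TrialRecord:
    defendant_id: str
    group: str
    person_emotion: str  # planted ground truth
    utterances: list = field(default_factory=list)


def generate_trial_records(spec: TrialSpec) -> list[TrialRecord]:
    """Simulate defendants, utterances and expert annotations.

    Each defendant draws a person-level emotion from their group's
    distribution.  A non-neutral defendant expresses that emotion on a
    ``expression_rate`` share of clips (neutral otherwise, so the
    person-labeling rule is actually exercised); each expert reports the
    true clip label with probability 1 - expert_error_rate, else a
    uniformly random other emotion.
    """
    rng = np.random.default_rng(spec.seed)
    emotions = list(COURT_EMOTIONS)
    records = []
    for group in spec.groups:
        labels = list(group.emotion_probs)
        probs = np.array([group.emotion_probs[e] for e in labels])
        for d in range(group.n_defendants):
            person_emotion = labels[rng.choice(len(labels), p=probs)]
            rec = TrialRecord(
                defendant_id=f"{group.name}_{d:03d}", group=group.name,
                person_emotion=person_emotion)
            for u in range(spec.clips_per_defendant):
                if person_emotion == "neutral":
                    true = "neutral"
                elif u == 0 or rng.random() < spec.expression_rate:
                    # at least one clip always expresses the emotion
                    true = person_emotion
                else:
                    true = "neutral"
                experts = []
                for _ in range(spec.n_experts):
                    if rng.random() < spec.expert_error_rate:
                        others = [e for e in emotions if e != true]
                        experts.append(others[rng.choice(len(others))])
                    else:
                        experts.append(true)
                clip = None
                if spec.audio is not None:
                    class_id = emotions.index(true) % spec.audio.n_classes
                    speaker_idx = (len(records)) % spec.audio.n_speakers
                    clip = generate_clip(class_id, speaker_idx, spec.audio,
                                         clip_idx=u)
                rec.utterances.append(Utterance(
                    clip_id=f"{rec.defendant_id}_u{u}", true_label=true,
                    expert_labels=tuple(experts), clip=clip))
            records.append(rec)
    return records


def write_trial_manifest(records, path: str | Path) -> Path:
    """Manifest CSV: clip_id, defendant_id, group, expert1..3."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["clip_id", "defendant_id", "group",
                    "expert1", "expert2", "expert3"])
        for rec in records:
            for utt in rec.utterances:
                row = [utt.clip_id, rec.defendant_id, rec.group]
                row += list(utt.expert_labels[:3])
                w.writerow(row)
    return path
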