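"""Berlin Emotional Database (Emo-DB) loader.

Emo-DB (http://emodb.bilderbar.info) contains 535 German utterances by
10 professional actors in 7 emotion categories.  Filenames encode the
metadata, e.g. ``03a01Wa.wav``: speaker 03, text a01, emotion code W
(Wut/anger), version a.  This module only indexes a locally available
copy — it never downloads anything.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .audio import AudioClip, read_wav

__all__ = ["EMOTION_CODES", "EMODB_CLASSES", "CorpusIndex",
           "parse_emodb_filename", "load_corpus", "EmodbParseError"]

#: German emotion-code letters -> English labels
EMOTION_CODES = {
    "W": "anger",     # Wut
    "L": "boredom",   # Langeweile
    "E": "disgust",   # Ekel
    "A": "fear",      # Angst
    "F": "joy",       # Freude
    "T": "sadness",   # Trauer
    "N": "neutral",
}

#: fixed one-hot label order (alphabetical)
EMODB_CLASSES = ("anger", "boredom", "disgust", "fear", "joy", "neutral",
                 "sadness")

_NAME_RE = re.compile(r"^(\d{2})([ab]\d{2})([WLEAFTN])([a-z]\d?)$")


class EmodbParseError(ValueError):
    """Filename does not follow the Emo-DB convention."""


def parse_emodb_filename(name: str) -> tuple[str, str]:
    """(speaker_id, emotion) from an Emo-DB filename.

    Convention: 2-digit speaker, text code (a01..b10), emotion letter in
    WLEAFTN, version letter (optionally with a digit).
    """
    stem = Path(name).stem
    m = _NAME_RE.match(stem)
    if not m:
        raise EmodbParseError(
            f"{name!r} does not match the Emo-DB pattern "
            "<speaker:2 digits><text:[ab]NN><emotion:WLEAFTN><version>.wav")
    speaker, _text, code, _version = m.groups()
    return speaker, EMOTION_CODES[code]


@dataclass
class CorpusIndex:
    entries: pd.DataFrame  # columns: path, speaker_id, label, utterance_code
    class_counts: dict = field(default_factory=dict)
    n_skipped: int = 0

    @property
    def n_utterances(self) -> int:
        return len(self.entries)

    @property
    def speakers(self) -> list[str]:
        return sorted(self.entries["speaker_id"].unique())


def load_corpus(root_dir: str | Path,
                load_audio: bool = True) -> tuple[CorpusIndex,
                                                  list[AudioClip]]:
    """Index (and optionally read) every parseable WAV under ``root_dir``.

    Unparseable filenames are skipped with a warning count; an empty or
    missing directory raises.  With the canonical corpus the index has
    535 entries, 10 speakers and 7 classes.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    wavs = sorted(root.rglob("*.wav"))
    if not wavs:
        raise FileNotFoundError(f"no WAV files under {root}")
    rows, clips, skipped = [], [], 0
    for path in wavs:
        try:
            speaker, emotion = parse_emodb_filename(path.name)
        except EmodbParseError:
            skipped += 1
            continue
        rows.append({"path": str(path), "speaker_id": speaker,
                     "label": emotion, "utterance_code": path.stem})
        if load_audio:
            clips.append(read_wav(path, clip_id=path.stem,
                                  speaker_id=speaker, label=emotion))
    if skipped:
        warnings.warn(f"skipped {skipped} non-conforming file(s)")
    if not rows:
        raise FileNotFoundError(f"no Emo-DB-named WAV files under {root}")
    entries = pd.DataFrame(rows)
    counts = entries["label"].value_counts().to_dict()
    index = CorpusIndex(entries=entries, class_counts=counts,
                        n_skipped=skipped)
    return index, clips


def write_manifest(index: CorpusIndex, path: str | Path) -> Path:
    """Manifest CSV with the same schema as the synthetic generator's."""
    path = Path(path)
    df = index.entries.rename(columns={"utterance_code": "clip_id"})
    df[["clip_id", "path", "speaker_id", "label"]].to_csv(path, index=False)
    return path
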