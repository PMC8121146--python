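"""Chord-label parsing, key normalization, and encoding schemes.

Chord annotations arrive as ``ROOT[:QUALITY][/BASS]`` tokens (the syntax used
by hand-transcribed pop-chart annotation corpora).  Analysis happens on
*key-normalized* chords: each chord is re-expressed as the interval in
semitones from the song's tonic plus a quality token, so that chord
distributions are invariant under transposition.

Two encodings are supported:

``full``
    The quality token is kept as annotated (triad plus extensions up to the
    seventh and beyond): an open-ended vocabulary.
``root_third``
    Every chord is folded onto its root and third quality only, giving a
    closed 24-symbol alphabet (12 intervals x {major, minor}).  Chords
    without a third (suspensions, power chords) have no image and are
    dropped by default.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Optional

__all__ = [
    "ChordLabel",
    "KeyContext",
    "RelativeChord",
    "NO_CHORD",
    "ChordParseError",
    "DEFAULT_THIRD_FOLD",
    "ROOT_THIRD_VOCAB_SIZE",
    "parse_chord_label",
    "pitch_class",
    "pitch_class_name",
    "normalize_to_key",
    "reduce_to_root_third",
    "root_third_vocabulary",
]

# Natural-letter pitch classes; accidentals offset by +/-1 semitone each.
_LETTER_PC = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}
_PC_NAME = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]

#: Annotation tokens that mean "no sounding chord"; the parser returns the
#: :data:`NO_CHORD` sentinel for these and downstream operations skip them.
NO_CHORD_TOKENS = frozenset({"N", "&pause", "*", "X"})

_ROOT_RE = re.compile(r"^([A-G])([#b]{0,2})$")
_QUALITY_RE = re.compile(r"^[A-Za-z0-9#b()+\-*/]+$")


class ChordParseError(ValueError):
    """Raised for a chord token that does not match the grammar."""

    def __init__(self, text: str, line: Optional[int] = None):
        self.text = text
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"cannot parse chord token {text!r}{where}")


class _NoChord:
    """Sentinel for no-chord annotation tokens ('N', '&pause', ...)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_CHORD"


NO_CHORD = _NoChord()


def pitch_class(name) -> int:
    """Map a note name (letter plus optional accidentals) or an int to 0-11.

    Enharmonic spellings fold onto the same class (``Db`` == ``C#`` == 1).
    """
    if isinstance(name, int):
        if not 0 <= name <= 11:
            raise ValueError(f"pitch class out of range: {name}")
        return name
    m = _ROOT_RE.match(name.strip())
    if m is None:
        raise ValueError(f"not a note name: {name!r}")
    letter, accidentals = m.groups()
    pc = _LETTER_PC[letter]
    for a in accidentals:
        pc += 1 if a == "#" else -1
    return pc % 12


def pitch_class_name(pc: int) -> str:
    """Canonical (sharp-preferring) name for a pitch class."""
    return _PC_NAME[pc % 12]


@dataclass(frozen=True)
class ChordLabel:
    """An absolute chord: root pitch class, quality token, original text."""

    root: int
    quality: str
    raw: str

    def canonical(self) -> str:
        return f"{pitch_class_name(self.root)}:{self.quality}"


@dataclass(frozen=True)
class KeyContext:
    """Tonal context a chord is heard against: tonic pitch class and mode."""

    tonic: int
    mode: str = "unspecified"

    def __post_init__(self):
        if not 0 <= self.tonic <= 11:
            raise ValueError(f"tonic out of range: {self.tonic}")
        if self.mode not in ("major", "minor", "unspecified"):
            raise ValueError(f"unknown mode: {self.mode!r}")


@dataclass(frozen=True, order=True)
class RelativeChord:
    """A chord relative to the key: semitones from tonic plus quality.

    This is the unit whose corpus probability defines harmonic surprise.
    The canonical string form ``"<interval>:<quality>"`` is unique per
    (interval, quality) pair and is used as the vocabulary key everywhere.
    """

    interval: int
    quality: str

    def __post_init__(self):
        if not 0 <= self.interval <= 11:
            raise ValueError(f"interval out of range: {self.interval}")

    def canonical(self) -> str:
        return f"{self.interval}:{self.quality}"

    @classmethod
    def from_canonical(cls, text: str) -> "RelativeChord":
        interval, _, quality = text.partition(":")
        return cls(int(interval), quality)


def parse_chord_label(text: str, line: Optional[int] = None):
    """Parse one annotation token into a :class:`ChordLabel`.

    Grammar: ``ROOT[:QUALITY][/BASS]`` with ``ROOT`` a letter A-G plus
    optional accidentals.  A missing quality defaults to ``maj``.  Bass /
    inversion suffixes are discarded.  No-chord tokens return the
    :data:`NO_CHORD` sentinel.

    Raises :class:`ChordParseError` naming the offending text (and line,
    when given) for anything else.
    """
    token = text.strip()
    if token in NO_CHORD_TOKENS:
        return NO_CHORD
    if not token:
        raise ChordParseError(text, line)
    # Discard inversion: everything after the first '/'.
    token, _, _bass = token.partition("/")
    root_part, sep, quality = token.partition(":")
    m = _ROOT_RE.match(root_part)
    if m is None:
        raise ChordParseError(text, line)
    if sep and not quality:
        raise ChordParseError(text, line)
    if not sep:
        quality = "maj"
    elif not _QUALITY_RE.match(quality):
        raise ChordParseError(text, line)
    return ChordLabel(root=pitch_class(root_part), quality=quality, raw=text.strip())


def normalize_to_key(chord: ChordLabel, key: KeyContext) -> RelativeChord:
    """Express *chord* relative to *key*: interval = (root - tonic) mod 12."""
    if chord is NO_CHORD:
        raise ValueError("cannot normalize the no-chord sentinel")
    return RelativeChord((chord.root - key.tonic) % 12, chord.quality)


# Fold table from annotated quality tokens onto third quality.  ``None``
# marks thirdless chords, which have no image in the root-third alphabet.
DEFAULT_THIRD_FOLD: Dict[str, Optional[str]] = {
    # major third family
    "major": "major",
    "maj": "major",
    "maj7": "major",
    "maj6": "major",
    "6": "major",
    "7": "major",
    "9": "major",
    "maj9": "major",
    "maj11": "major",
    "maj13": "major",
    "11": "major",
    "13": "major",
    "add9": "major",
    "aug": "major",
    "aug7": "major",
    # minor third family
    "minor": "minor",
    "min": "minor",
    "min7": "minor",
    "min6": "minor",
    "min9": "minor",
    "min11": "minor",
    "min13": "minor",
    "minmaj7": "minor",
    "dim": "minor",
    "dim7": "minor",
    "hdim7": "minor",
    # no third
    "sus2": None,
    "sus4": None,
    "sus4(b7)": None,
    "5": None,
    "1": None,
}

ROOT_THIRD_VOCAB_SIZE = 24


def reduce_to_root_third(
    chord: RelativeChord,
    fold: Optional[Dict[str, Optional[str]]] = None,
) -> Optional[RelativeChord]:
    """Fold a chord onto the 24-symbol root-third alphabet.

    Returns a chord with quality ``major`` or ``minor``, or ``None`` when the
    quality has no third (the default policy drops such chords).  A quality
    token absent from the fold table raises ``ValueError`` so silent
    vocabulary corruption is impossible; callers wanting different behaviour
    pass an extended table.
    """
    table = DEFAULT_THIRD_FOLD if fold is None else fold
    if chord.quality not in table:
        raise ValueError(f"no third-fold rule for quality {chord.quality!r}")
    third = table[chord.quality]
    if third is None:
        return None
    return RelativeChord(chord.interval, third)


def root_third_vocabulary():
    """The full 24-chord root-third alphabet, in (interval, quality) order."""
    return [
        RelativeChord(i, q) for i in range(12) for q in ("major", "minor")
    ]
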