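"""Corpus containers and I/O.

Two on-disk forms are supported:

* a dialect of the hand-transcription annotation format used by pop-chart
  chord corpora (``#``-prefixed headers, then timestamped lines of
  ``|``-delimited bars);
* a tidy tab-separated interchange table, one row per chord occurrence,
  which round-trips losslessly and is the format the synthetic generator
  and the analysis pipeline exchange.

Songs hold *key-normalized* chords (:class:`~harmonic_surprise.chords.RelativeChord`);
the annotation reader normalizes against the tonic in force at each chord's
position, so files that modulate mid-song are handled consistently.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import pandas as pd

from .chords import (
    NO_CHORD,
    ChordParseError,
    KeyContext,
    RelativeChord,
    normalize_to_key,
    parse_chord_label,
    pitch_class,
)

__all__ = [
    "Section",
    "Song",
    "Corpus",
    "CorpusFormatError",
    "INTERCHANGE_COLUMNS",
    "read_annotation_file",
    "read_corpus_table",
    "write_corpus_table",
    "apply_fixed_windows",
]


class CorpusFormatError(ValueError):
    """Malformed corpus file (annotation dialect or interchange table)."""


@dataclass
class Section:
    """A labelled stretch of a song with its chords in time order."""

    label: str
    chords: List[RelativeChord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.chords)


@dataclass
class Song:
    """A chord-annotated song with chart metadata.

    ``release_year``/``release_month`` give month-granular release dates
    (time bins are month-bounded).  ``peak_position`` is the best chart rank
    attained (1 = top of the chart); ``weeks_on_chart`` breaks rank ties.
    Chart metadata may be absent on songs read from bare annotation files.
    """

    id: str
    release_year: Optional[int] = None
    release_month: Optional[int] = None
    peak_position: Optional[int] = None
    weeks_on_chart: Optional[int] = None
    genre: Optional[str] = None
    sections: List[Section] = field(default_factory=list)
    key: Optional[KeyContext] = None

    @property
    def release_date(self) -> Tuple[int, int]:
        if self.release_year is None or self.release_month is None:
            raise ValueError(f"song {self.id!r} has no release date")
        return (self.release_year, self.release_month)

    @property
    def release_frac_year(self) -> float:
        """Release date as a fractional year (year + (month-1)/12)."""
        y, m = self.release_date
        return y + (m - 1) / 12.0

    def iter_chords(self) -> Iterator[RelativeChord]:
        for sec in self.sections:
            yield from sec.chords

    @property
    def n_chords(self) -> int:
        return sum(len(s) for s in self.sections)


@dataclass
class Corpus:
    """A collection of songs plus the encoding scheme they use."""

    songs: List[Song]
    encoding: str = "full"
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.id for s in self.songs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusFormatError(f"duplicate song ids: {dupes}")
        if self.encoding not in ("full", "root_third"):
            raise ValueError(f"unknown encoding: {self.encoding!r}")

    def __len__(self) -> int:
        return len(self.songs)

    def song(self, song_id: str) -> Song:
        for s in self.songs:
            if s.id == song_id:
                return s
        raise KeyError(song_id)


# --------------------------------------------------------------------------
# Annotation dialect
# --------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^#\s*(\w+)\s*:\s*(.*?)\s*$")
# A section label token: a short name ending with ',' before the first bar,
# e.g. "A," or "verse,".
_LABEL_RE = re.compile(r"^[A-Za-z][\w' -]*$")


def read_annotation_file(path_or_buffer, song_id: Optional[str] = None) -> Song:
    """Parse one annotation file into a :class:`Song` (no chart metadata).

    Dialect: ``#``-prefixed header lines (``# title:``, ``# artist:``,
    ``# tonic:``, ``# metre:``) followed by body lines of the form
    ``time<TAB>content``.  Content starts with optional comma-terminated
    section-label tokens, then ``|``-delimited bars of chord tokens.  A
    ``.`` token repeats the previous chord; no-chord tokens are skipped.
    Later ``# tonic:`` lines change the key for subsequent chords, so
    modulating songs are normalized against the tonic active at each
    position.

    A missing tonic header is an error: without it key normalization is
    impossible.
    """
    if hasattr(path_or_buffer, "read"):
        lines = path_or_buffer.read().splitlines()
        name = song_id or "<buffer>"
    else:
        with open(path_or_buffer, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        name = song_id or str(path_or_buffer)

    headers: Dict[str, str] = {}
    key: Optional[KeyContext] = None
    sections: List[Section] = []
    current: Optional[Section] = None
    last_chord: Optional[RelativeChord] = None

    for lineno, rawline in enumerate(lines, start=1):
        line = rawline.rstrip()
        if not line.strip():
            continue
        m = _HEADER_RE.match(line)
        if m:
            field_name, value = m.group(1).lower(), m.group(2)
            headers.setdefault(field_name, value)
            if field_name == "tonic":
                key = KeyContext(tonic=pitch_class(value))
            continue
        if line.lstrip().startswith("#"):
            continue  # comment
        if "\t" not in line:
            raise CorpusFormatError(
                f"{name}: line {lineno}: expected 'time<TAB>content'"
            )
        _time, content = line.split("\t", 1)
        content = content.strip()
        if content in ("end", "Z", ""):
            continue
        if key is None:
            raise CorpusFormatError(
                f"{name}: line {lineno}: chords before any '# tonic:' header"
            )
        bars = content.split("|")
        prefix = bars[0].strip()
        if prefix:
            # comma-terminated label tokens open a new section
            labels = [t.strip() for t in prefix.split(",") if t.strip()]
            for tok in labels:
                if not _LABEL_RE.match(tok):
                    raise CorpusFormatError(
                        f"{name}: line {lineno}: bad section label {tok!r}"
                    )
            if labels:
                current = Section(label=" ".join(labels))
                sections.append(current)
        for bar in bars[1:]:
            for tok in bar.split():
                if tok == ".":
                    chord = last_chord
                    if chord is None:
                        continue
                else:
                    try:
                        parsed = parse_chord_label(tok, line=lineno)
                    except ChordParseError as exc:
                        raise CorpusFormatError(f"{name}: {exc}") from exc
                    if parsed is NO_CHORD:
                        last_chord = None
                        continue
                    chord = normalize_to_key(parsed, key)
                if current is None:
                    current = Section(label="section_0")
                    sections.append(current)
                current.chords.append(chord)
                last_chord = chord

    if key is None:
        raise CorpusFormatError(f"{name}: no '# tonic:' header")
    title = headers.get("title")
    sid = song_id or title or name
    return Song(id=sid, sections=sections, key=key)


# --------------------------------------------------------------------------
# Interchange table
# --------------------------------------------------------------------------

INTERCHANGE_COLUMNS = [
    "song_id",
    "release_year",
    "release_month",
    "peak_position",
    "weeks_on_chart",
    "genre",
    "section_index",
    "section_label",
    "chord_interval",
    "chord_quality",
]


def corpus_to_frame(corpus: Corpus) -> pd.DataFrame:
    """Flatten a corpus to the tidy one-row-per-chord interchange frame."""
    rows = []
    for song in corpus.songs:
        for si, sec in enumerate(song.sections):
            for ch in sec.chords:
                rows.append(
                    (
                        song.id,
                        song.release_year,
                        song.release_month,
                        song.peak_position,
                        song.weeks_on_chart,
                        song.genre if song.genre is not None else "",
                        si,
                        sec.label,
                        ch.interval,
                        ch.quality,
                    )
                )
    return pd.DataFrame(rows, columns=INTERCHANGE_COLUMNS)


def write_corpus_table(corpus: Corpus, path) -> None:
    """Write the tab-separated interchange table (header always present)."""
    if corpus.encoding == "root_third":
        bad = {
            ch.quality
            for s in corpus.songs
            for ch in s.iter_chords()
            if ch.quality not in ("major", "minor")
        }
        if bad:
            raise CorpusFormatError(
                f"root_third corpus contains non-root-third qualities: {sorted(bad)}"
            )
    frame = corpus_to_frame(corpus)
    frame.to_csv(path, sep="\t", index=False)


def read_corpus_table(path_or_buffer, encoding: Optional[str] = None) -> Corpus:
    """Read an interchange table back into a :class:`Corpus`.

    Rows are grouped into songs and sections preserving file order.  Within
    a song, ``section_index`` must be non-decreasing and start at 0 — a
    repeated-out-of-order index indicates duplicated or shuffled rows and is
    rejected.
    """
    frame = pd.read_csv(
        path_or_buffer, sep="\t", dtype={"genre": "string"}, keep_default_na=True
    )
    missing = [c for c in INTERCHANGE_COLUMNS if c not in frame.columns]
    if missing:
        raise CorpusFormatError(f"missing required columns: {missing}")

    songs: List[Song] = []
    seen_ids = set()
    for song_id, g in frame.groupby("song_id", sort=False):
        if song_id in seen_ids:  # pragma: no cover - groupby prevents this
            raise CorpusFormatError(f"duplicate song id {song_id!r}")
        seen_ids.add(song_id)
        first = g.iloc[0]
        genre = first["genre"]
        genre = None if pd.isna(genre) or genre == "" else str(genre)
        song = Song(
            id=str(song_id),
            release_year=int(first["release_year"]),
            release_month=int(first["release_month"]),
            peak_position=int(first["peak_position"]),
            weeks_on_chart=int(first["weeks_on_chart"]),
            genre=genre,
        )
        prev_index = -1
        current: Optional[Section] = None
        for row in g.itertuples(index=False):
            si = int(row.section_index)
            if si == prev_index + 1:
                current = Section(label=str(row.section_label))
                song.sections.append(current)
                prev_index = si
            elif si != prev_index:
                raise CorpusFormatError(
                    f"song {song_id!r}: section_index {si} out of order "
                    f"(previous {prev_index}); rows duplicated or shuffled?"
                )
            current.chords.append(
                RelativeChord(int(row.chord_interval), str(row.chord_quality))
            )
        songs.append(song)

    if encoding is None:
        qualities = {
            ch.quality for s in songs for ch in s.iter_chords()
        }
        encoding = (
            "root_third"
            if qualities and qualities <= {"major", "minor"}
            else "full"
        )
    return Corpus(songs=songs, encoding=encoding)


def apply_fixed_windows(song: Song, window: int = 16) -> Song:
    """Re-section a song into consecutive fixed-length windows of chords.

    Stand-in sectioning for sources without structural annotations.  The
    final window keeps the remainder (it may be shorter than *window*).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    chords = list(song.iter_chords())
    sections = [
        Section(label=f"W{i // window}", chords=chords[i : i + window])
        for i in range(0, len(chords), window)
    ]
    return replace(song, sections=sections)
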