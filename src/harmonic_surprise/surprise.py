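"""Zeroth-order harmonic surprise.

A baseline chord distribution is estimated from the songs released inside a
fixed early time window.  With ``M_j`` the number of occurrences of the
unique chord ``C_j`` and ``N`` unique chords in the window, the probability
of a chord is its marginal relative frequency

    P(C_j) = M_j / sum_i M_i

and its surprise, in bits, is the information content

    S(C_j) = -log2 P(C_j).

The model is zeroth order: chord ordering carries no weight.  Per song, two
summaries are computed:

* **absolute surprise** — the mean surprise of the song's chords;
* **contrastive surprise** — the standard deviation across sections of the
  per-section mean surprises (how much the song's sections differ in how
  surprising they are).

Chords absent from the baseline vocabulary have infinite surprise under the
plug-in estimate; the default policy excludes them from the means and counts
them (``n_excluded``).  Laplace-smoothed and capped alternatives are
available.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .chords import RelativeChord
from .corpus_io import Corpus, Song

__all__ = [
    "ChordDistribution",
    "SurpriseProfile",
    "OOV_POLICIES",
    "build_distribution",
    "chord_surprise",
    "song_absolute_surprise",
    "song_contrastive_surprise",
    "corpus_surprise_profiles",
]

DateTuple = Tuple[int, int]  # (year, month)

#: Out-of-vocabulary policies.
#: ``exclude``  — drop the chord from the song mean, count it in n_excluded.
#: ``laplace``  — score it as an unseen category under add-one smoothing,
#:               S = -log2(1 / (total + N + 1)).
#: ``cap``      — score it at the ceiling -log2(1 / (total + 1)).
OOV_POLICIES = ("exclude", "laplace", "cap")


def _month_index(date: DateTuple) -> int:
    y, m = date
    if not 1 <= m <= 12:
        raise ValueError(f"month out of range in date {date}")
    return y * 12 + (m - 1)


@dataclass
class ChordDistribution:
    """Chord counts and probabilities over a baseline window."""

    counts: Dict[str, int]
    window: Tuple[DateTuple, DateTuple]
    _probs: Dict[str, float] = field(init=False, repr=False)
    _surprises: Dict[str, float] = field(init=False, repr=False)

    def __post_init__(self):
        if not self.counts:
            raise ValueError("empty chord distribution")
        if any(m < 1 for m in self.counts.values()):
            raise ValueError("all chord counts must be >= 1")
        total = sum(self.counts.values())
        self._probs = {c: m / total for c, m in self.counts.items()}
        self._surprises = {c: -math.log2(p) for c, p in self._probs.items()}

    @property
    def total(self) -> int:
        """Total chord occurrences in the window (sum of M_j)."""
        return sum(self.counts.values())

    @property
    def N(self) -> int:
        """Number of unique chords in the window."""
        return len(self.counts)

    def probability(self, chord) -> float:
        return self._probs[_canonical(chord)]

    def __contains__(self, chord) -> bool:
        return _canonical(chord) in self.counts

    def entropy(self) -> float:
        """Shannon entropy of the distribution, in bits."""
        p = np.fromiter(self._probs.values(), dtype=float)
        return float(-(p * np.log2(p)).sum())


def _canonical(chord) -> str:
    if isinstance(chord, RelativeChord):
        return chord.canonical()
    return str(chord)


def build_distribution(corpus: Corpus, window: Tuple[DateTuple, DateTuple]) -> ChordDistribution:
    """Count chords of all songs released inside *window* (month-inclusive).

    Raises ``ValueError`` when no chord occurrence falls in the window —
    a surprise baseline cannot be empty.
    """
    start, end = _month_index(window[0]), _month_index(window[1])
    if end < start:
        raise ValueError(f"window end precedes start: {window}")
    counts: Dict[str, int] = {}
    for song in corpus.songs:
        mi = _month_index(song.release_date)
        if start <= mi <= end:
            for ch in song.iter_chords():
                key = ch.canonical()
                counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise ValueError(f"no chord occurrences in baseline window {window}")
    return ChordDistribution(counts=counts, window=tuple(window))


class OOVChord(KeyError):
    """Signalled for a chord outside the baseline vocabulary."""


def chord_surprise(dist: ChordDistribution, chord) -> float:
    """Surprise of one chord in bits: -log2 P(C_j).

    Raises :class:`OOVChord` for chords outside the vocabulary; callers
    apply their out-of-vocabulary policy.
    """
    key = _canonical(chord)
    try:
        return dist._surprises[key]
    except KeyError:
        raise OOVChord(key) from None


def _oov_surprise(dist: ChordDistribution, policy: str) -> Optional[float]:
    if policy == "exclude":
        return None
    if policy == "laplace":
        return -math.log2(1.0 / (dist.total + dist.N + 1))
    if policy == "cap":
        return -math.log2(1.0 / (dist.total + 1))
    raise ValueError(f"unknown OOV policy {policy!r}; choose from {OOV_POLICIES}")


def _section_surprises(
    section_chords: Iterable[RelativeChord],
    dist: ChordDistribution,
    policy: str,
) -> Tuple[List[float], int]:
    """Per-chord surprises for one section plus the number excluded."""
    oov_value = _oov_surprise(dist, policy)
    values: List[float] = []
    excluded = 0
    for ch in section_chords:
        key = ch.canonical()
        s = dist._surprises.get(key)
        if s is None:
            if oov_value is None:
                excluded += 1
                continue
            s = oov_value
        values.append(s)
    return values, excluded


def song_absolute_surprise(
    song: Song, dist: ChordDistribution, policy: str = "exclude"
) -> Tuple[float, int]:
    """Mean chord surprise of a song in bits, plus the excluded-chord count.

    Returns ``(nan, n_excluded)`` when every chord is out of vocabulary
    (under the exclude policy); such songs are dropped from aggregates.
    """
    values: List[float] = []
    excluded = 0
    for sec in song.sections:
        v, e = _section_surprises(sec.chords, dist, policy)
        values.extend(v)
        excluded += e
    if not values:
        return (float("nan"), excluded)
    return (float(np.mean(values)), excluded)


def song_contrastive_surprise(
    song: Song, dist: ChordDistribution, policy: str = "exclude"
) -> float:
    """SD across sections of per-section mean surprises, in bits.

    Sample standard deviation (n-1 denominator).  Undefined (``nan``) with
    fewer than two sections containing at least one scoreable chord.
    """
    means: List[float] = []
    for sec in song.sections:
        v, _e = _section_surprises(sec.chords, dist, policy)
        if v:
            means.append(float(np.mean(v)))
    if len(means) < 2:
        return float("nan")
    return float(np.std(means, ddof=1))


@dataclass
class SurpriseProfile:
    """Per-song surprise summary."""

    song_id: str
    per_chord_surprise: List[float]
    absolute: float
    section_means: List[float]
    contrastive: float
    n_excluded: int


def corpus_surprise_profiles(
    corpus: Corpus, dist: ChordDistribution, policy: str = "exclude"
) -> pd.DataFrame:
    """Score every song; returns one tidy row per song.

    Columns: song_id, release_year, release_month, peak_position,
    weeks_on_chart, genre, n_chords, n_excluded, n_sections_used,
    absolute, contrastive.  Songs with no scoreable chord have ``nan``
    absolute surprise; songs with fewer than two scoreable sections have
    ``nan`` contrastive surprise.
    """
    rows = []
    for song in corpus.songs:
        absolute, excluded = song_absolute_surprise(song, dist, policy)
        contrastive = song_contrastive_surprise(song, dist, policy)
        n_used = sum(
            1
            for sec in song.sections
            if _section_surprises(sec.chords, dist, policy)[0]
        )
        rows.append(
            (
                song.id,
                song.release_year,
                song.release_month,
                song.peak_position,
                song.weeks_on_chart,
                song.genre,
                song.n_chords,
                excluded,
                n_used,
                absolute,
                contrastive,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "song_id",
            "release_year",
            "release_month",
            "peak_position",
            "weeks_on_chart",
            "genre",
            "n_chords",
            "n_excluded",
            "n_sections_used",
            "absolute",
            "contrastive",
        ],
    )
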