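"""Preference quartiles and release-date time bins.

Songs are ranked by peak chart position (1 = best), with weeks-on-chart
breaking ties and song id as a final deterministic tie-break.  Two quartile
rules are provided:

* **global** — rank the whole corpus; the top floor(n/4) songs are Q1 and
  the bottom floor(n/4) are Q4 (for a 545-song corpus: 136 each);
* **grouped** — partition songs by (release year, genre) and apply the
  global rule inside each group, which controls for genre-specific chart
  dynamics; groups smaller than 4 contribute no Q1/Q4 members.

Time bins are month-bounded, inclusive on both ends.  The two default bin
sets cover a 1958-1991 chart corpus (with a long first bin serving as the
surprise baseline) and a 2000-2019 corpus in four 5-year bins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .corpus_io import Corpus, Song

__all__ = [
    "TimeBin",
    "HISTORIC_BINS",
    "MODERN_BINS",
    "rank_songs",
    "classify_quartiles_global",
    "classify_quartiles_grouped",
    "assign_time_bins",
    "bins_from_config",
]

logger = logging.getLogger(__name__)

Q1, MID, Q4 = "Q1", "MID", "Q4"


@dataclass(frozen=True)
class TimeBin:
    """A named, month-bounded release period (inclusive on both ends)."""

    name: str
    start: Tuple[int, int]
    end: Tuple[int, int]

    def __post_init__(self):
        if self._mi(self.end) < self._mi(self.start):
            raise ValueError(f"bin {self.name!r} ends before it starts")

    @staticmethod
    def _mi(date: Tuple[int, int]) -> int:
        y, m = date
        if not 1 <= m <= 12:
            raise ValueError(f"month out of range in {date}")
        return y * 12 + (m - 1)

    def __contains__(self, date: Tuple[int, int]) -> bool:
        return self._mi(self.start) <= self._mi(date) <= self._mi(self.end)


#: Four bins over a 1958-1991 chart corpus; the long first bin doubles as
#: the baseline window for the surprise distribution.
HISTORIC_BINS: List[TimeBin] = [
    TimeBin("bin1", (1958, 8), (1975, 1)),
    TimeBin("bin2", (1975, 2), (1980, 7)),
    TimeBin("bin3", (1980, 8), (1986, 1)),
    TimeBin("bin4", (1986, 2), (1991, 11)),
]

#: Four 5-year bins over a 2000-2019 chart corpus.
MODERN_BINS: List[TimeBin] = [
    TimeBin("bin1", (2000, 1), (2004, 12)),
    TimeBin("bin2", (2005, 1), (2009, 12)),
    TimeBin("bin3", (2010, 1), (2014, 12)),
    TimeBin("bin4", (2015, 1), (2019, 12)),
]


def rank_songs(songs: Iterable[Song]) -> List[Song]:
    """Order songs best-first: peak position ascending, weeks-on-chart
    descending, song id ascending (fully deterministic)."""
    songs = list(songs)
    missing = [
        s.id for s in songs if s.peak_position is None or s.weeks_on_chart is None
    ]
    if missing:
        raise ValueError(f"songs missing chart metadata: {sorted(missing)}")
    return sorted(songs, key=lambda s: (s.peak_position, -s.weeks_on_chart, s.id))


def _classify(songs: Sequence[Song]) -> Dict[str, str]:
    ranked = rank_songs(songs)
    n = len(ranked)
    k = n // 4
    assignment = {s.id: MID for s in ranked}
    for s in ranked[:k]:
        assignment[s.id] = Q1
    for s in ranked[n - k :]:
        assignment[s.id] = Q4
    return assignment


def classify_quartiles_global(corpus) -> Dict[str, str]:
    """Quartile labels for every song under the whole-corpus ranking rule.

    Returns a map song_id -> 'Q1' | 'MID' | 'Q4' with exactly floor(n/4)
    songs in each extreme quartile.  Requires at least 4 songs.
    """
    songs = corpus.songs if isinstance(corpus, Corpus) else list(corpus)
    if len(songs) < 4:
        raise ValueError(f"need >= 4 songs to form quartiles, got {len(songs)}")
    return _classify(songs)


def classify_quartiles_grouped(
    corpus,
    keys: Tuple[str, ...] = ("release_year", "genre"),
) -> Dict[str, str]:
    """Quartile labels with ranking applied within (year, genre) groups.

    Groups of fewer than 4 songs cannot form quartiles; their songs are
    labelled MID and a warning is logged.
    """
    songs = corpus.songs if isinstance(corpus, Corpus) else list(corpus)
    groups: Dict[tuple, List[Song]] = {}
    for s in songs:
        key = tuple(getattr(s, k) for k in keys)
        groups.setdefault(key, []).append(s)
    assignment: Dict[str, str] = {}
    for key, members in groups.items():
        if len(members) < 4:
            logger.warning(
                "group %s has %d song(s) (<4); contributes no Q1/Q4 members",
                key,
                len(members),
            )
            assignment.update({s.id: MID for s in members})
        else:
            assignment.update(_classify(members))
    return assignment


def assign_time_bins(
    corpus, bins: Optional[Sequence[TimeBin]] = None
) -> Dict[str, TimeBin]:
    """Map each song id to the bin containing its release date.

    Bins must not overlap; a song outside every bin (or inside two) is an
    error naming the song.  Default bin set is chosen by corpus span:
    the 1958-1991 set if the earliest release predates 2000, else the
    2000-2019 set.
    """
    songs = corpus.songs if isinstance(corpus, Corpus) else list(corpus)
    if bins is None:
        earliest = min(s.release_year for s in songs)
        bins = HISTORIC_BINS if earliest < 2000 else MODERN_BINS
    assignment: Dict[str, TimeBin] = {}
    for s in songs:
        hits = [b for b in bins if s.release_date in b]
        if not hits:
            raise ValueError(
                f"song {s.id!r} released {s.release_date} falls in no time bin"
            )
        if len(hits) > 1:
            raise ValueError(
                f"song {s.id!r} released {s.release_date} falls in "
                f"overlapping bins {[b.name for b in hits]}"
            )
        assignment[s.id] = hits[0]
    return assignment


def _parse_ym(text: str) -> Tuple[int, int]:
    y, _, m = str(text).partition("-")
    return (int(y), int(m))


def bins_from_config(entries: Sequence[dict]) -> List[TimeBin]:
    """Build bins from config entries ``{name, start: 'YYYY-MM', end: 'YYYY-MM'}``."""
    return [
        TimeBin(str(e["name"]), _parse_ym(e["start"]), _parse_ym(e["end"]))
        for e in entries
    ]
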