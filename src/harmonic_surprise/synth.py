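"""Synthetic chart-corpus generator.

Generates corpora with the statistical structure the surprise analysis
assumes, so every pipeline stage is testable without external data:

* a long-tailed (Zipf) baseline chord distribution over a root-third
  vocabulary, heavy on tonic/dominant/subdominant chords;
* per-year drift of each song's sampling distribution toward the rare tail,
  with a *steeper* drift for the songs destined for the top quartile
  (surprise inflation);
* section structure with controllable between-section surprise
  heterogeneity (what contrastive surprise measures);
* chart ranks coupled to the drift tier, so re-deriving quartiles from peak
  position recovers the generative tiers;
* an optional new-chord mode that occasionally substitutes chords from a
  reserve of extended-quality labels, more often in the top tier, so
  first-appearance analyses have signal.

The drift construction is exact in expectation.  Chords are sampled from
the mixture ``Q_w = (1 - w) P + w R`` where ``P`` is the Zipf baseline and
``R`` is uniform over the rare half of the vocabulary (spreading the tail
mass keeps individual tail chords rare, and hence surprising, even after
mixing).  Scored against any fixed reference distribution ``F``, the
expected surprise of a draw from ``Q_w`` is *linear* in ``w``:

    E[S | w] = CE(P, F) + w * g(F),    g(F) = sum_c (R_c - P_c) S_F(c).

The analysis pipeline scores songs against the empirical distribution of
the first time bin — which the generator's own mixing has flattened — so
the relevant reference is not ``P`` but the expected first-bin mixture
``Pbar = (1 - wbar) P + wbar R``.  The generator solves the one-dimensional
fixed point (``wbar`` depends on the drift schedule, which depends on
``g(Pbar)``) and sets ``w(t) = w0 + beta * t / g(Pbar)``, which makes the
expected absolute-surprise slope, *as the pipeline measures it*, exactly
``beta`` bits/year per tier.  The floor ``w0`` leaves room for symmetric
per-section offsets without truncation at ``w = 0`` (truncation would bend
the trend).  Section offsets are uniform with standard deviation
``contrast`` (in bits), which is what makes contrastive surprise respond
to the ``contrast_*`` knobs.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .chords import RelativeChord
from .corpus_io import Corpus, Section, Song

__all__ = ["SynthConfig", "generate_corpus", "make_fixture", "FIXTURE_NAMES"]

# Root-third chords ordered by stylized prevalence (tonic/dominant/
# subdominant majors first, relative/secondary minors next, chromatic
# roots last).  The Zipf rank of a chord is its position in this list.
ROOT_THIRD_ORDER: List[Tuple[int, str]] = [
    (0, "major"), (7, "major"), (5, "major"), (9, "minor"),
    (2, "minor"), (4, "minor"), (10, "major"), (2, "major"),
    (4, "major"), (9, "major"), (0, "minor"), (5, "minor"),
    (7, "minor"), (11, "minor"), (3, "major"), (8, "major"),
    (1, "major"), (6, "minor"), (11, "major"), (6, "major"),
    (10, "minor"), (1, "minor"), (8, "minor"), (3, "minor"),
]

# Extended qualities used by the new-chord reserve pool (full encoding).
_EXTENDED_QUALITIES = [
    "maj7", "min7", "7", "maj9", "min9", "9", "maj6", "min6",
    "11", "13", "dim", "aug", "minmaj7", "hdim7", "dim7", "add9",
]

TIERS = ("Q1", "MID", "Q4")


@dataclass
class SynthConfig:
    """Generator parameters.

    Defaults describe a two-decade chart corpus at root-third encoding with
    surprise inflation three times steeper in the top tier than the bottom
    (0.09 vs 0.03 bits/year), 200 charting songs per year.
    """

    vocab_size: int = 24
    zipf_exponent: float = 1.2
    start_year: int = 2000
    n_years: int = 20
    songs_per_year: int = 200
    sections_per_song: Tuple[int, int] = (4, 8)
    chords_per_section: Tuple[int, int] = (8, 24)
    drift_q1: float = 0.09      # bits/year, top-tier surprise inflation
    drift_q4: float = 0.03      # bits/year, bottom tier
    contrast_q1: float = 0.08   # bits, SD of per-section surprise offsets
    contrast_q4: float = 0.05
    baseline_years: int = 5     # years assumed to form the scoring baseline
    rank_noise: float = 0.25    # bits, noise on the within-year rank score
    rank_mode: str = "tier"     # 'tier' | 'surprise'
    new_chord_mode: bool = False
    novel_rate: float = 0.004   # per-chord substitution rate, MID tier
    reserve_size: int = 96
    seed: int = 0

    def __post_init__(self):
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        if min(self.drift_q1, self.drift_q4, self.contrast_q1,
               self.contrast_q4, self.rank_noise, self.novel_rate) < 0:
            raise ValueError("rates and scales must be >= 0")
        if self.drift_q1 < self.drift_q4:
            raise ValueError("inflation scenarios require drift_q1 >= drift_q4")
        if self.rank_mode not in ("tier", "surprise"):
            raise ValueError("rank_mode must be 'tier' or 'surprise'")
        lo, hi = self.sections_per_song
        if not (1 <= lo <= hi):
            raise ValueError("bad sections_per_song range")
        lo, hi = self.chords_per_section
        if not (1 <= lo <= hi):
            raise ValueError("bad chords_per_section range")
        if self.songs_per_year < 4:
            raise ValueError("songs_per_year must be >= 4 to form tiers")
        if self.baseline_years < 1:
            raise ValueError("baseline_years must be >= 1")


def _vocabulary(size: int) -> List[RelativeChord]:
    vocab = [RelativeChord(i, q) for i, q in ROOT_THIRD_ORDER[:size]]
    if size > len(ROOT_THIRD_ORDER):
        extra = []
        k = 0
        while len(vocab) + len(extra) < size:
            q = _EXTENDED_QUALITIES[k % len(_EXTENDED_QUALITIES)]
            interval = (k * 7) % 12  # spread roots over the circle of fifths
            cand = RelativeChord(interval, f"{q}")
            if cand not in vocab and cand not in extra:
                extra.append(cand)
            k += 1
            if k > 50 * size:  # pragma: no cover - defensive
                raise ValueError("cannot build a vocabulary that large")
        vocab.extend(extra)
    return vocab


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    p = ranks**-exponent
    return p / p.sum()


def _reserve_pool(core: List[RelativeChord], size: int) -> List[RelativeChord]:
    pool: List[RelativeChord] = []
    core_set = set(core)
    for q in _EXTENDED_QUALITIES:
        for interval in range(12):
            cand = RelativeChord(interval, q)
            if cand not in core_set:
                pool.append(cand)
            if len(pool) == size:
                return pool
    return pool


def _tail_target(p: np.ndarray) -> np.ndarray:
    """Uniform distribution over the rare half of the vocabulary."""
    size = len(p)
    n_tail = max(1, size // 2)
    r = np.zeros(size)
    r[size - n_tail :] = 1.0 / n_tail
    return r


def _calibrate_gain(
    p: np.ndarray,
    r: np.ndarray,
    c_max: float,
    drift_mean: float,
    baseline_years: int,
) -> float:
    """Solve for g = sum (R-P) * surprise(Pbar), the bits-per-mixing-weight
    gain against the expected first-bin reference Pbar.

    Pbar is itself a mixture at the mean baseline-era weight
    wbar = w0 + drift_mean * tbar / g, so g is a one-dimensional fixed
    point; the iteration is monotone and converges quickly.
    """
    s_p = -np.log2(p)
    g = float(((r - p) * s_p).sum())  # gain against the pure baseline
    if g <= 0:
        raise ValueError("degenerate baseline: zipf_exponent must be > 0")
    t_bar = (baseline_years - 1) / 2.0
    for _ in range(200):
        w0 = math.sqrt(3.0) * c_max / g
        w_bar = w0 + drift_mean * t_bar / g
        if w_bar >= 1.0:
            raise ValueError(
                "infeasible ranges: baseline-era mixing weight reaches 1; "
                "reduce drift or contrast, or enlarge the vocabulary"
            )
        p_bar = (1.0 - w_bar) * p + w_bar * r
        g_new = float(((r - p) * (-np.log2(p_bar))).sum())
        if g_new <= 0:
            raise ValueError(
                "infeasible ranges: tail mixing destroys the surprise "
                "gradient; reduce drift or contrast"
            )
        if abs(g_new - g) < 1e-12:
            return g_new
        g = g_new
    return g


def generate_corpus(config: SynthConfig) -> Corpus:
    """Generate a corpus; a pure function of the config (which holds the seed).

    The designated drift tier of every song is recorded in
    ``corpus.provenance['tiers']`` so parameter-recovery checks can condition
    on generative truth; the analysis pipeline itself re-derives quartiles
    from peak positions via the cohort rules.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    vocab = _vocabulary(cfg.vocab_size)
    p = _zipf_probs(cfg.vocab_size, cfg.zipf_exponent)
    surprise = -np.log2(p)
    r = _tail_target(p)

    n = cfg.songs_per_year
    k4 = n // 4
    drift = {"Q1": cfg.drift_q1, "Q4": cfg.drift_q4,
             "MID": 0.5 * (cfg.drift_q1 + cfg.drift_q4)}
    contrast = {"Q1": cfg.contrast_q1, "Q4": cfg.contrast_q4,
                "MID": 0.5 * (cfg.contrast_q1 + cfg.contrast_q4)}
    drift_mean = (k4 * (drift["Q1"] + drift["Q4"]) + (n - 2 * k4) * drift["MID"]) / n
    baseline_years = min(cfg.baseline_years, cfg.n_years)
    g = _calibrate_gain(p, r, max(contrast.values()), drift_mean,
                        baseline_years)
    # uniform(-a, a) has SD a/sqrt(3); a is in mixing-weight units
    half_width = {q: math.sqrt(3.0) * contrast[q] / g for q in TIERS}
    w0 = max(half_width.values())
    w_max = (
        w0 + max(drift.values()) * max(cfg.n_years - 1, 0) / g
        + max(half_width.values())
    )
    if w_max > 1.0:
        raise ValueError(
            f"infeasible ranges: peak mixing weight {w_max:.3f} > 1; "
            "reduce drift, contrast, or n_years, or enlarge the vocabulary"
        )

    reserve = _reserve_pool(vocab, cfg.reserve_size) if cfg.new_chord_mode else []
    if cfg.new_chord_mode:
        reserve_probs = _zipf_probs(len(reserve), 1.5)
        novel_rate = {"Q1": 2.0 * cfg.novel_rate, "MID": cfg.novel_rate,
                      "Q4": 0.5 * cfg.novel_rate}

    genres = ("pop", "rock", "rnb", "country")
    tier_of_index = ["Q1"] * k4 + ["MID"] * (n - 2 * k4) + ["Q4"] * k4

    songs: List[Song] = []
    tiers: Dict[str, str] = {}
    for t in range(cfg.n_years):
        year = cfg.start_year + t
        year_songs: List[Song] = []
        scores = np.empty(n)
        for i in range(n):
            tier = tier_of_index[i]
            song_id = f"s{year}-{i:04d}"
            tiers[song_id] = tier
            w_base = w0 + drift[tier] * t / g
            n_sec = int(rng.integers(cfg.sections_per_song[0],
                                     cfg.sections_per_song[1] + 1))
            sections: List[Section] = []
            total_bits = 0.0
            total_chords = 0
            for si in range(n_sec):
                a = half_width[tier]
                w_s = w_base + (rng.uniform(-a, a) if a > 0 else 0.0)
                probs = (1.0 - w_s) * p + w_s * r
                n_ch = int(rng.integers(cfg.chords_per_section[0],
                                        cfg.chords_per_section[1] + 1))
                ids = rng.choice(cfg.vocab_size, size=n_ch, p=probs)
                chords = [vocab[j] for j in ids]
                total_bits += float(surprise[ids].sum())
                total_chords += n_ch
                if cfg.new_chord_mode:
                    nu = min(1.0, novel_rate[tier] * (1 + t))
                    hits = np.nonzero(rng.random(n_ch) < nu)[0]
                    for h in hits:
                        ridx = int(rng.choice(len(reserve), p=reserve_probs))
                        chords[h] = reserve[ridx]
                sections.append(Section(label=f"S{si}", chords=chords))
            realized = total_bits / total_chords
            if cfg.rank_mode == "surprise":
                scores[i] = realized + rng.normal(0.0, cfg.rank_noise)
            else:
                # rank within fixed tier blocks; noisy surprise orders
                # songs inside each block only
                scores[i] = (
                    -TIERS.index(tier) * 1e6
                    + realized
                    + rng.normal(0.0, cfg.rank_noise)
                )
            year_songs.append(
                Song(
                    id=song_id,
                    release_year=year,
                    release_month=int(rng.integers(1, 13)),
                    genre=genres[int(rng.integers(len(genres)))],
                    sections=sections,
                )
            )
        # best score -> peak position 1
        order = np.argsort(-scores, kind="stable")
        for rank, idx in enumerate(order, start=1):
            song = year_songs[idx]
            song.peak_position = rank
            song.weeks_on_chart = max(
                1, int(round(1 + 40.0 * (n - rank) / n + rng.normal(0.0, 3.0)))
            )
        songs.extend(year_songs)

    encoding = "full" if cfg.new_chord_mode else (
        "root_third" if cfg.vocab_size <= len(ROOT_THIRD_ORDER) else "full"
    )
    return Corpus(
        songs=songs,
        encoding=encoding,
        provenance={
            "generator": "harmonic_surprise.synth",
            "config": asdict(cfg),
            "tiers": tiers,
            "bits_per_mixing_weight": g,
            "mixing_floor": w0,
        },
    )


# --------------------------------------------------------------------------
# Hand-sized fixtures
# --------------------------------------------------------------------------

FIXTURE_NAMES = ("toy6", "tie_break", "oov")


def _rc(text: str) -> RelativeChord:
    return RelativeChord.from_canonical(text)


def _toy6() -> Corpus:
    """Six songs, two one-year bins; all surprise values are hand-checkable.

    The year-2000 songs (s1, s2) define the baseline: chord counts
    0:major x8, 7:major x4, 5:major x2, 9:minor x2 (total 16), so the
    probabilities are 1/2, 1/4, 1/8, 1/8 and the surprises 1, 2, 3, 3 bits.
    """
    M, D, S4, Rm = "0:major", "7:major", "5:major", "9:minor"

    def song(sid, year, peak, weeks, secs):
        return Song(
            id=sid, release_year=year, release_month=6,
            peak_position=peak, weeks_on_chart=weeks, genre="pop",
            sections=[
                Section(label=f"S{i}", chords=[_rc(c) for c in chords])
                for i, chords in enumerate(secs)
            ],
        )

    songs = [
        # baseline year: absolute 1.5 / 2.0; contrastive 0 / sqrt(2)
        song("s1", 2000, 2, 10, [[M, M, D, D], [M, M, D, D]]),
        song("s2", 2000, 5, 4, [[M, M, M, M], [S4, S4, Rm, Rm]]),
        # second year
        song("s3", 2001, 1, 20, [[S4, Rm], [S4, Rm]]),          # abs 3.0, contr 0
        song("s4", 2001, 2, 8, [[M, D], [S4, Rm]]),             # abs 2.25
        song("s5", 2001, 6, 3, [[M, M], [M, "2:minor"]]),       # one OOV chord
        song("s6", 2001, 7, 2, [[M, M, M, M]]),                 # single section
    ]
    return Corpus(songs=songs, encoding="root_third",
                  provenance={"fixture": "toy6"})


def _tie_break() -> Corpus:
    """Songs sharing peak positions, distinguishable only by weeks or id."""
    chords = [_rc("0:major"), _rc("7:major")]

    def song(sid, peak, weeks):
        return Song(id=sid, release_year=2000, release_month=1,
                    peak_position=peak, weeks_on_chart=weeks, genre="pop",
                    sections=[Section(label="S0", chords=list(chords))])

    return Corpus(
        songs=[
            song("a", 1, 10), song("b", 1, 2),   # weeks break the tie
            song("c", 2, 5), song("d", 2, 5),    # full tie: id order
            song("e", 3, 1),
        ],
        encoding="root_third",
        provenance={"fixture": "tie_break"},
    )


def _oov() -> Corpus:
    """A baseline song plus a later song containing an unseen chord."""
    return Corpus(
        songs=[
            Song(id="base", release_year=2000, release_month=1,
                 peak_position=1, weeks_on_chart=10, genre="pop",
                 sections=[Section(label="S0",
                                   chords=[_rc("0:major"), _rc("7:major")])]),
            Song(id="novel", release_year=2001, release_month=1,
                 peak_position=2, weeks_on_chart=5, genre="pop",
                 sections=[Section(label="S0",
                                   chords=[_rc("0:major"), _rc("6:minor")])]),
        ],
        encoding="root_third",
        provenance={"fixture": "oov"},
    )


def make_fixture(name: str) -> Corpus:
    """Return one of the documented hand-sized corpora by name."""
    builders = {"toy6": _toy6, "tie_break": _tie_break, "oov": _oov}
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return builders[name]()
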