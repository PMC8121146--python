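"""Baseline distribution estimation and per-song surprise summaries."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from harmonic_surprise.chords import KeyContext, RelativeChord, parse_chord_label, normalize_to_key
from harmonic_surprise.corpus_io import Corpus, Section, Song
from harmonic_surprise.surprise import (
    OOVChord,
    build_distribution,
    chord_surprise,
    corpus_surprise_profiles,
    song_absolute_surprise,
    song_contrastive_surprise,
)


def _one_song_corpus(chords, year=2000):
    song = Song(id="s", release_year=year, release_month=6, peak_position=1,
                weeks_on_chart=1,
                sections=[Section("S0", [RelativeChord.from_canonical(c)
                                         for c in chords])])
    return Corpus(songs=[song])


def test_distribution_probabilities_follow_relative_frequencies():
    corpus = _one_song_corpus(["0:major"] * 3 + ["7:major"])
    dist = build_distribution(corpus, ((2000, 1), (2000, 12)))
    assert dist.N == 2
    assert dist.total == 4
    assert dist.probability("0:major") == pytest.approx(0.75)
    assert dist.probability("7:major") == pytest.approx(0.25)
    assert sum(dist.probability(c) for c in dist.counts) == pytest.approx(1.0, abs=1e-12)


def test_empty_window_is_an_error():
    corpus = _one_song_corpus(["0:major"])
    with pytest.raises(ValueError, match="no chord occurrences"):
        build_distribution(corpus, ((1990, 1), (1990, 12)))


def test_chord_surprise_values():
    dist = build_distribution(
        _one_song_corpus(["0:major"] * 3 + ["7:major"]), ((2000, 1), (2000, 12))
    )
    # -log2(0.75) = 2 - log2(3), frozen from an independent evaluation
    assert chord_surprise(dist, "0:major") == pytest.approx(0.415037499278844, abs=1e-12)
    certain = build_distribution(_one_song_corpus(["0:major"]), ((2000, 1), (2000, 12)))
    assert chord_surprise(certain, "0:major") == 0.0
    half = build_distribution(
        _one_song_corpus(["0:major", "7:major"]), ((2000, 1), (2000, 12))
    )
    assert chord_surprise(half, "0:major") == pytest.approx(1.0)
    with pytest.raises(OOVChord):
        chord_surprise(dist, "5:major")


# Hand-worked toy corpus: year-2000 baseline counts 0:major x8, 7:major x4,
# 5:major x2, 9:minor x2 -> surprises 1, 2, 3, 3 bits.
TOY6_EXPECTED = {
    # song_id: (absolute, contrastive, n_excluded)
    "s1": (1.5, 0.0, 0),
    "s2": (2.0, math.sqrt(2.0), 0),
    "s3": (3.0, 0.0, 0),
    "s4": (2.25, math.sqrt(((1.5 - 2.25) ** 2 + (3.0 - 2.25) ** 2)), 0),
    "s5": (1.0, 0.0, 1),       # one out-of-vocabulary chord excluded
    "s6": (1.0, float("nan"), 0),  # single section: contrastive undefined
}


def test_toy_corpus_profiles_match_hand_computation(toy6, toy6_baseline):
    profiles = corpus_surprise_profiles(toy6, toy6_baseline).set_index("song_id")
    for sid, (absolute, contrastive, n_excluded) in TOY6_EXPECTED.items():
        row = profiles.loc[sid]
        assert row["absolute"] == pytest.approx(absolute), sid
        if math.isnan(contrastive):
            assert math.isnan(row["contrastive"]), sid
        else:
            assert row["contrastive"] == pytest.approx(contrastive), sid
        assert row["n_excluded"] == n_excluded, sid


def test_mean_surprise_example_with_oov_exclusion(toy6_baseline):
    # song {A, A, X} with S(A)=1 bit and X out of vocabulary
    song = Song(id="x", release_year=2001, release_month=1,
                sections=[Section("S0", [RelativeChord(0, "major"),
                                         RelativeChord(0, "major"),
                                         RelativeChord(2, "minor")])])
    absolute, excluded = song_absolute_surprise(song, toy6_baseline)
    assert absolute == pytest.approx(1.0)
    assert excluded == 1


def test_all_oov_song_is_undefined(toy6_baseline):
    song = Song(id="x", release_year=2001, release_month=1,
                sections=[Section("S0", [RelativeChord(1, "minor")])])
    absolute, excluded = song_absolute_surprise(song, toy6_baseline)
    assert math.isnan(absolute) and excluded == 1


def test_oov_policies_score_unseen_chords(toy6_baseline):
    song = Song(id="x", release_year=2001, release_month=1,
                sections=[Section("S0", [RelativeChord(2, "minor")])])
    total, n = toy6_baseline.total, toy6_baseline.N
    lap, e1 = song_absolute_surprise(song, toy6_baseline, policy="laplace")
    cap, e2 = song_absolute_surprise(song, toy6_baseline, policy="cap")
    assert lap == pytest.approx(math.log2(total + n + 1))
    assert cap == pytest.approx(math.log2(total + 1))
    assert e1 == e2 == 0


def test_contrastive_surprise_closed_forms(toy6, toy6_baseline):
    s2 = toy6.song("s2")
    assert song_contrastive_surprise(s2, toy6_baseline) == pytest.approx(math.sqrt(2))
    s6 = toy6.song("s6")
    assert math.isnan(song_contrastive_surprise(s6, toy6_baseline))


def test_self_entropy_identity(small_synth):
    """Scoring the baseline window against its own distribution averages to
    the distribution's Shannon entropy, which is at most log2(N)."""
    window = ((2000, 1), (2004, 12))
    dist = build_distribution(small_synth, window)
    total_bits = sum(
        dist.counts[c] * chord_surprise(dist, c) for c in dist.counts
    )
    mean_self_surprise = total_bits / dist.total
    assert mean_self_surprise == pytest.approx(dist.entropy(), abs=1e-10)
    assert mean_self_surprise <= math.log2(dist.N) + 1e-12


@given(counts=st.lists(st.integers(1, 50), min_size=2, max_size=10))
def test_more_frequent_chords_are_less_surprising(counts):
    chords = [f"{i % 12}:major" if i < 12 else f"{i % 12}:minor"
              for i in range(len(counts))]
    corpus = _one_song_corpus(
        [c for c, m in zip(chords, counts) for _ in range(m)]
    )
    dist = build_distribution(corpus, ((2000, 1), (2000, 12)))
    for a, ma in zip(chords, counts):
        for b, mb in zip(chords, counts):
            if ma > mb:
                assert chord_surprise(dist, a) < chord_surprise(dist, b)


@pytest.mark.parametrize("shift", [1, 5, 11])
def test_surprise_is_invariant_under_transposition(shift):
    """Transposing every chord and tonic by the same interval leaves all
    surprise values unchanged (key normalization property)."""
    names = ["C", "G", "A", "F", "D", "E"]
    key = KeyContext(0)

    def corpus_for(offset):
        songs = []
        for si, root in enumerate(names):
            base = parse_chord_label(root)
            chord = normalize_to_key(
                type(base)(root=(base.root + offset) % 12,
                           quality=base.quality, raw=base.raw),
                KeyContext((key.tonic + offset) % 12),
            )
            songs.append(
                Song(id=f"s{si}", release_year=2000, release_month=1,
                     peak_position=si + 1, weeks_on_chart=1,
                     sections=[Section("S0", [chord] * (si + 1))])
            )
        return Corpus(songs=songs)

    base = corpus_for(0)
    moved = corpus_for(shift)
    window = ((2000, 1), (2000, 12))
    p0 = corpus_surprise_profiles(base, build_distribution(base, window))
    p1 = corpus_surprise_profiles(moved, build_distribution(moved, window))
    assert np.allclose(p0["absolute"], p1["absolute"])
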