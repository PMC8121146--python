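"""Trend tests, slope comparison, t-tests, and the new-chord analysis.

Independent oracles used here:

* the Jonckheere–Terpstra exact path is checked against a brute-force
  oracle that enumerates *every* permutation of the pooled sample
  (``itertools.permutations``), a different enumeration strategy from the
  implementation's combination recursion;
* OLS trend fits are checked against direct normal-equation solutions;
* first-appearance chord sets are checked against a full-scan set-difference
  oracle.
"""
import itertools
import math

import numpy as np
import pytest

from harmonic_surprise.corpus_io import Corpus, Section, Song
from harmonic_surprise.chords import RelativeChord
from harmonic_surprise.stats import (
    TrendResult,
    chi_square_two_counts,
    compare_slopes,
    fit_trend,
    jonckheere_terpstra,
    new_chord_report,
    two_sample_t,
)

# ------------------------------------------------------------------ JT ----


def _jt_oracle(groups):
    """Brute-force J statistic (ties at 1/2) without vectorization."""
    J = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[j]:
                    J += 1.0 if x < y else (0.5 if x == y else 0.0)
    return J


def _jt_exact_p_oracle(groups):
    """One-sided p by exhaustive enumeration of all n! permutations of the
    pooled sample into the observed group sizes."""
    pooled = [x for g in groups for x in g]
    sizes = [len(g) for g in groups]
    j_obs = _jt_oracle(groups)
    count = total = 0
    for perm in itertools.permutations(pooled):
        regrouped, pos = [], 0
        for s in sizes:
            regrouped.append(perm[pos : pos + s])
            pos += s
        total += 1
        if _jt_oracle(regrouped) >= j_obs - 1e-9:
            count += 1
    return count / total


def test_perfectly_ordered_groups_attain_the_maximal_statistic():
    result = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
    assert result.J == 12  # all 12 cross pairs concordant
    assert result.method == "exact"
    # only 1 of the C(6,2)*C(4,2)=90 distinct assignments reaches J=12
    assert result.p == pytest.approx(1 / 90)


def test_all_tied_data_gives_half_the_cross_pairs():
    result = jonckheere_terpstra([[5, 5], [5, 5], [5, 5]])
    assert result.J == pytest.approx(6.0)  # 12 cross pairs, all at 1/2


def test_reversing_group_order_flips_the_tail():
    groups = [[1.0, 2.5], [2.0, 4.0], [5.0, 6.0]]
    inc = jonckheere_terpstra(groups)
    dec = jonckheere_terpstra(groups[::-1])
    # J(reversed) = (total cross pairs) - J, and the exact tail probabilities
    # satisfy P(J' >= C - j) = P(J <= j)
    assert inc.J + dec.J == pytest.approx(12.0)


@pytest.mark.parametrize(
    "groups",
    [
        [[1, 2], [3, 4], [5, 6]],
        [[1.0, 2.5], [2.0, 4.0], [5.0]],
        [[3, 1], [2, 2], [4]],          # ties across groups
        [[1, 1, 1], [1, 2], [2, 3]],    # heavy ties
        [[5, 6], [1, 2], [3, 4]],       # anti-ordered
    ],
)
def test_exact_pvalue_matches_exhaustive_permutation_oracle(groups):
    result = jonckheere_terpstra(groups)
    assert result.method == "exact"
    assert result.J == pytest.approx(_jt_oracle(groups))
    assert result.p == pytest.approx(_jt_exact_p_oracle(groups))


def test_large_samples_use_the_tie_corrected_normal_approximation():
    rng = np.random.default_rng(3)
    groups = [rng.normal(loc, 1.0, size=30) for loc in (0.0, 0.5, 1.0)]
    result = jonckheere_terpstra(groups)
    assert result.method == "normal"
    assert result.z is not None and result.z > 0
    assert 0 < result.p < 0.05


def test_fewer_than_two_groups_is_an_error():
    with pytest.raises(ValueError, match="2 nonempty groups"):
        jonckheere_terpstra([[1, 2, 3]])


# ----------------------------------------------------------------- OLS ----


def _ols_oracle(t, y):
    """Normal-equation slope, intercept, and slope SE."""
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sigma2 = (resid @ resid) / (len(t) - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta[1], beta[0], math.sqrt(cov[1, 1])


def test_exact_line_has_zero_slope_error():
    t = np.array([0.0, 1.0, 2.0, 3.0])
    fit = fit_trend(t, 2 * t + 1)
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.slope_se == pytest.approx(0.0, abs=1e-12)


def test_constant_response_has_zero_slope():
    fit = fit_trend([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])
    assert fit.slope == pytest.approx(0.0, abs=1e-12)


def test_fit_matches_normal_equation_oracle():
    rng = np.random.default_rng(11)
    t = rng.uniform(0, 10, size=40)
    y = 1.3 + 0.07 * t + rng.normal(0, 0.5, size=40)
    fit = fit_trend(t, y)
    slope, intercept, se = _ols_oracle(t, y)
    assert fit.slope == pytest.approx(slope, abs=1e-10)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)
    assert fit.slope_se == pytest.approx(se, abs=1e-10)


def test_degenerate_times_are_rejected():
    with pytest.raises(ValueError, match="identical"):
        fit_trend([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# -------------------------------------------------------- slope test ------


def test_equal_slopes_give_t_zero_p_one():
    a = TrendResult(slope=0.09, intercept=0, slope_se=0.0, n=10)
    b = TrendResult(slope=0.09, intercept=0, slope_se=0.0, n=10)
    result = compare_slopes(a, b)
    assert result.t == 0.0 and result.p == 1.0 and result.degenerate


def test_degrees_of_freedom_are_n1_plus_n2_minus_4():
    a = TrendResult(slope=0.096, intercept=0, slope_se=0.01, n=136)
    b = TrendResult(slope=0.032, intercept=0, slope_se=0.01, n=136)
    result = compare_slopes(a, b)
    assert result.df == 268
    assert result.t == pytest.approx((0.096 - 0.032) / math.hypot(0.01, 0.01))


def test_zero_se_with_unequal_slopes_is_degenerate():
    a = TrendResult(slope=1.0, intercept=0, slope_se=0.0, n=10)
    b = TrendResult(slope=0.0, intercept=0, slope_se=0.0, n=10)
    result = compare_slopes(a, b)
    assert result.degenerate and result.p == 0.0


def test_null_slope_difference_follows_student_t():
    """Under equal generative slopes, the statistic follows T(df) (KS)."""
    rng = np.random.default_rng(42)
    stats = []
    for _ in range(2000):
        t1 = rng.uniform(0, 10, 30)
        t2 = rng.uniform(0, 10, 30)
        y1 = 0.05 * t1 + rng.normal(0, 1, 30)
        y2 = 0.05 * t2 + rng.normal(0, 1, 30)
        result = compare_slopes(fit_trend(t1, y1), fit_trend(t2, y2))
        stats.append(result.t)
    from scipy import stats as sps

    ks = sps.kstest(stats, sps.t(df=56).cdf)
    assert ks.pvalue > 0.01


# ---------------------------------------------------------- t-test --------


def test_identical_samples_give_t_zero():
    t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_swapping_samples_negates_t():
    t1, p1 = two_sample_t([1, 2, 3], [4, 5, 7])
    t2, p2 = two_sample_t([4, 5, 7], [1, 2, 3])
    assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


def test_welch_statistic_matches_hand_computation():
    # x=(1,2), y=(4,6): means 1.5, 5; variances 0.5, 2
    # t = (1.5-5)/sqrt(0.5/2 + 2/2) = -3.5/sqrt(1.25)
    t, _p = two_sample_t([1.0, 2.0], [4.0, 6.0])
    assert t == pytest.approx(-3.5 / math.sqrt(1.25), abs=1e-12)


def test_pooled_variant_differs_when_variances_do():
    x = [1.0, 2.0, 3.0, 4.0]
    y = [10.0, 30.0, 50.0, 70.0]
    t_w, _ = two_sample_t(x, y, variant="welch")
    t_p, _ = two_sample_t(x, y, variant="pooled")
    assert t_w == pytest.approx(t_p)  # equal n: statistics coincide
    with pytest.raises(ValueError):
        two_sample_t(x, y, variant="bogus")


# -------------------------------------------------------- chi-square ------


@pytest.mark.parametrize(
    "c1,c2,expected",
    [(10, 10, 0.0), (20, 0, 20.0), (133, 34, (133 - 83.5) ** 2 / 83.5 * 2)],
)
def test_chi_square_against_equal_expectation(c1, c2, expected):
    chi2, df, p = chi_square_two_counts(c1, c2)
    assert chi2 == pytest.approx(expected)
    assert df == 1
    from scipy.stats import chi2 as chi2_dist

    assert p == pytest.approx(float(chi2_dist.sf(expected, 1)))


def test_chi_square_rejects_double_zero():
    with pytest.raises(ValueError):
        chi_square_two_counts(0, 0)


# -------------------------------------------------------- new chords ------


def _make_corpus(songs_spec):
    """songs_spec: list of (id, year, peak, [chord canonicals])."""
    songs = [
        Song(id=sid, release_year=year, release_month=1, peak_position=peak,
             weeks_on_chart=1,
             sections=[Section("S0", [RelativeChord.from_canonical(c)
                                      for c in chords])])
        for sid, year, peak, chords in songs_spec
    ]
    return Corpus(songs=songs)


def test_new_chords_attributed_to_the_quartiles_containing_them():
    corpus = _make_corpus([
        ("a", 2000, 3, ["0:major", "7:major"]),
        ("b", 2001, 1, ["0:major", "4:minor", "9:minor"]),  # two new chords
        ("c", 2001, 9, ["0:major"]),
    ])
    quartiles = {"a": "MID", "b": "Q1", "c": "Q4"}
    report = new_chord_report(corpus, quartiles)
    assert report.new_by_year == {2001: {"4:minor", "9:minor"}}
    assert report.count_Q1 == 2 and report.count_Q4 == 0
    assert report.pct_Q1 == pytest.approx(100.0)


def test_stationary_vocabulary_yields_empty_sets():
    corpus = _make_corpus([
        ("a", 2000, 1, ["0:major", "7:major"]),
        ("b", 2001, 2, ["7:major", "0:major"]),
        ("c", 2002, 3, ["0:major"]),
    ])
    report = new_chord_report(corpus, {"a": "Q1", "b": "Q4", "c": "MID"})
    assert all(len(v) == 0 for v in report.new_by_year.values())
    assert report.chi2 is None and report.p is None


def test_first_appearances_match_full_scan_oracle():
    rng = np.random.default_rng(5)
    vocab = [f"{i}:{'major' if i % 2 else 'minor'}" for i in range(12)]
    spec = []
    for year in range(2000, 2006):
        for i in range(6):
            # reveal later vocabulary entries gradually
            limit = min(len(vocab), 4 + 2 * (year - 2000))
            chords = list(rng.choice(vocab[:limit], size=8))
            spec.append((f"s{year}-{i}", year, i + 1, chords))
    corpus = _make_corpus(spec)
    quartiles = {s.id: ("Q1" if s.peak_position <= 2 else
                        ("Q4" if s.peak_position >= 5 else "MID"))
                 for s in corpus.songs}
    report = new_chord_report(corpus, quartiles)

    # oracle: full scan, set difference year by year
    chords_by_year = {}
    for s in corpus.songs:
        chords_by_year.setdefault(s.release_year, set()).update(
            c.canonical() for c in s.iter_chords()
        )
    years = sorted(chords_by_year)
    seen = set(chords_by_year[years[0]])
    for y in years[1:]:
        expected_new = chords_by_year[y] - seen
        assert report.new_by_year[y] == expected_new
        seen |= chords_by_year[y]


def test_per_occurrence_mode_counts_multiplicity():
    corpus = _make_corpus([
        ("a", 2000, 5, ["0:major"]),
        ("b", 2001, 1, ["3:minor", "3:minor", "0:major"]),
    ])
    report = new_chord_report(corpus, {"a": "Q4", "b": "Q1"},
                              mode="per_occurrence")
    assert report.count_Q1 == 2 and report.count_Q4 == 0
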