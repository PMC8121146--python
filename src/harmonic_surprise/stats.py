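"""Inferential layer: ordered-trend tests, regression slopes, slope
equivalence, t-tests, and the new-chord-introduction analysis.

The headline question — does surprise against a fixed early baseline rise
faster in preferred (Q1) songs than in bottom-quartile (Q4) songs? — is
answered with three complementary tools:

* the Jonckheere–Terpstra test for a monotone trend of per-song surprise
  across a-priori ordered time bins, within each quartile;
* ordinary least squares of per-song surprise on fractional release year,
  within each quartile, giving a slope in bits/year with its standard
  error; and
* a two-slope equivalence test: with slopes b1, b2 and slope standard
  errors s1, s2 from independent fits of n1 and n2 points,

      t = (b1 - b2) / sqrt(s1^2 + s2^2)   ~   T(n1 + n2 - 4)

  under the null of equal slopes.

A separate analysis counts chords appearing for the first time in each
calendar year after the first, and asks (chi-square, df = 1) whether such
newly introduced chords show up more often in Q1 than Q4 songs.
"""
from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps

from .corpus_io import Corpus

__all__ = [
    "JTResult",
    "TrendResult",
    "SlopeTestResult",
    "NewChordReport",
    "jonckheere_terpstra",
    "fit_trend",
    "compare_slopes",
    "two_sample_t",
    "new_chord_report",
    "chi_square_two_counts",
]

#: Largest pooled sample size for which the Jonckheere–Terpstra p-value is
#: computed exactly by exhaustive enumeration of group assignments.
JT_EXACT_MAX_N = 12


@dataclass
class JTResult:
    """Jonckheere–Terpstra test outcome."""

    J: float
    z: Optional[float]
    p: float
    method: str
    n_groups: int = 0
    n_total: int = 0


@dataclass
class TrendResult:
    """OLS fit of surprise (bits) on release time (years)."""

    slope: float
    intercept: float
    slope_se: float
    n: int


@dataclass
class SlopeTestResult:
    """Two-independent-slopes equivalence test."""

    t: float
    df: int
    p: float
    degenerate: bool = False


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """J = sum over ordered group pairs of Mann-Whitney counts, ties at 1/2."""
    J = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = groups[i][:, None]
            b = groups[j][None, :]
            J += float((a < b).sum()) + 0.5 * float((a == b).sum())
    return J


def _jt_exact_pvalue(pooled: np.ndarray, sizes: Sequence[int], j_obs: float) -> float:
    """P(J >= j_obs) by exhaustive enumeration of all distinct assignments
    of the pooled observations to groups of the given sizes."""
    n = len(pooled)
    count_ge = 0
    total = 0
    indices = tuple(range(n))

    def recurse(remaining: Tuple[int, ...], gi: int, chosen: List[Tuple[int, ...]]):
        nonlocal count_ge, total
        if gi == len(sizes) - 1:
            groups = [np.asarray([pooled[k] for k in grp]) for grp in chosen]
            groups.append(np.asarray([pooled[k] for k in remaining]))
            total += 1
            # tolerance guards half-integer comparisons against float noise
            if _jt_statistic(groups) >= j_obs - 1e-9:
                count_ge += 1
            return
        for comb in itertools.combinations(remaining, sizes[gi]):
            comb_set = set(comb)
            rest = tuple(k for k in remaining if k not in comb_set)
            recurse(rest, gi + 1, chosen + [comb])

    recurse(indices, 0, [])
    return count_ge / total


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]], alternative: str = "increasing"
) -> JTResult:
    """Jonckheere–Terpstra test for a monotone trend across ordered groups.

    ``groups`` are samples in their a-priori order.  For a pooled sample of
    at most :data:`JT_EXACT_MAX_N` observations the one-sided p-value is
    exact (exhaustive enumeration of group assignments, correct under ties);
    otherwise the tie-corrected normal approximation is used.
    """
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    arrays = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(arrays) < 2:
        raise ValueError("need at least 2 nonempty groups")
    if alternative == "decreasing":
        arrays = arrays[::-1]

    sizes = [len(a) for a in arrays]
    n = sum(sizes)
    J = _jt_statistic(arrays)

    if n <= JT_EXACT_MAX_N:
        pooled = np.concatenate(arrays)
        p = _jt_exact_pvalue(pooled, sizes, J)
        return JTResult(J=J, z=None, p=p, method="exact",
                        n_groups=len(arrays), n_total=n)

    # Tie-corrected normal approximation (standard large-sample variance).
    pooled = np.concatenate(arrays)
    ties = np.asarray(list(Counter(pooled.tolist()).values()), dtype=float)
    ni = np.asarray(sizes, dtype=float)
    mu = (n * n - (ni**2).sum()) / 4.0
    A = (
        n * (n - 1) * (2 * n + 5)
        - (ni * (ni - 1) * (2 * ni + 5)).sum()
        - (ties * (ties - 1) * (2 * ties + 5)).sum()
    )
    B = (ni * (ni - 1) * (ni - 2)).sum() * (ties * (ties - 1) * (ties - 2)).sum()
    C = (ni * (ni - 1)).sum() * (ties * (ties - 1)).sum()
    var = A / 72.0 + B / (36.0 * n * (n - 1) * (n - 2)) + C / (8.0 * n * (n - 1))
    if var <= 0:
        raise ValueError("degenerate data: zero variance for the JT statistic")
    z = (J - mu) / math.sqrt(var)
    p = float(sps.norm.sf(z))
    return JTResult(J=J, z=z, p=p, method="normal",
                    n_groups=len(arrays), n_total=n)


def fit_trend(times: Sequence[float], values: Sequence[float]) -> TrendResult:
    """OLS of *values* (bits) on *times* (fractional years).

    Requires n >= 3 and at least two distinct time values.  The slope
    standard error is the usual OLS estimate with n - 2 residual degrees of
    freedom (zero for an exact fit).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-d and the same length")
    mask = ~(np.isnan(t) | np.isnan(y))
    t, y = t[mask], y[mask]
    n = len(t)
    if n < 3:
        raise ValueError(f"need >= 3 points to fit a trend, got {n}")
    if np.unique(t).size < 2:
        raise ValueError("degenerate fit: all time values identical")
    res = sps.linregress(t, y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        n=n,
    )


def compare_slopes(a: TrendResult, b: TrendResult) -> SlopeTestResult:
    """Test equality of two independently fitted slopes.

    t = (slope_a - slope_b)/sqrt(se_a^2 + se_b^2) on n_a + n_b - 4 degrees
    of freedom, two-sided.  With both standard errors zero the statistic is
    degenerate: equal slopes give (t=0, p=1); unequal slopes give an
    infinite statistic with p=0, flagged.
    """
    df = a.n + b.n - 4
    if df < 2:
        raise ValueError(f"too few points for the slope test (df={df})")
    pooled_se = math.hypot(a.slope_se, b.slope_se)
    diff = a.slope - b.slope
    if pooled_se == 0.0:
        if diff == 0.0:
            return SlopeTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        return SlopeTestResult(
            t=math.copysign(math.inf, diff), df=df, p=0.0, degenerate=True
        )
    t = diff / pooled_se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return SlopeTestResult(t=t, df=df, p=min(p, 1.0))


def two_sample_t(
    x: Sequence[float], y: Sequence[float], variant: str = "welch"
) -> Tuple[float, float]:
    """Two-sample t-test (two-sided): Welch by default, pooled optional."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def chi_square_two_counts(c1: float, c2: float) -> Tuple[float, int, float]:
    """Goodness of fit of two counts against equal expectation (df = 1)."""
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be nonnegative")
    if c1 + c2 == 0:
        raise ValueError("both counts zero: chi-square undefined")
    expected = (c1 + c2) / 2.0
    chi2 = (c1 - expected) ** 2 / expected + (c2 - expected) ** 2 / expected
    p = float(sps.chi2.sf(chi2, 1))
    return float(chi2), 1, p


@dataclass
class NewChordReport:
    """First-appearance chords per year and their quartile attribution.

    ``pct_Q1``/``pct_Q4`` use all newly introduced chords as denominator;
    ``pct_Q1_yearly_mean``/``pct_Q4_yearly_mean`` average the per-year
    shares instead (both denominators are reported because either reading
    of 'percentage of newly introduced chords' is defensible).
    """

    new_by_year: Dict[int, Set[str]]
    count_Q1: int
    count_Q4: int
    total_new: int
    pct_Q1: float
    pct_Q4: float
    pct_Q1_yearly_mean: float
    pct_Q4_yearly_mean: float
    chi2: Optional[float]
    df: Optional[int]
    p: Optional[float]


def new_chord_report(
    corpus: Corpus,
    quartiles: Dict[str, str],
    mode: str = "per_chord",
) -> NewChordReport:
    """Analyse chords appearing for the first time in each year.

    For every calendar year after the corpus's first, the set of canonical
    chords with no occurrence in any earlier year is found.  Each new chord
    is attributed to a quartile when some song of that quartile contains it
    in its introduction year — once per quartile in ``per_chord`` mode
    (default), or once per occurrence in ``per_occurrence`` mode.  The two
    counts are compared with a chi-square test against equal expectation.
    """
    if mode not in ("per_chord", "per_occurrence"):
        raise ValueError("mode must be 'per_chord' or 'per_occurrence'")
    years = sorted({s.release_year for s in corpus.songs})
    if len(years) < 2:
        raise ValueError("corpus must span at least 2 calendar years")

    # chord -> occurrence count per (year, quartile); and first year seen
    occ: Dict[str, Dict[int, Counter]] = {}
    first_year: Dict[str, int] = {}
    for song in corpus.songs:
        q = quartiles.get(song.id, "MID")
        y = song.release_year
        for ch in song.iter_chords():
            key = ch.canonical()
            occ.setdefault(key, {}).setdefault(y, Counter())[q] += 1
            if key not in first_year or y < first_year[key]:
                first_year[key] = y

    first_analysed = years[0]
    new_by_year: Dict[int, Set[str]] = {y: set() for y in years[1:]}
    for key, y0 in first_year.items():
        if y0 > first_analysed:
            new_by_year[y0].add(key)

    count_q1 = count_q4 = 0
    per_year_q1: List[float] = []
    per_year_q4: List[float] = []
    for y, chords in new_by_year.items():
        if not chords:
            continue
        y_q1 = y_q4 = 0
        for key in chords:
            quartile_counts = occ[key][y]
            if mode == "per_chord":
                y_q1 += 1 if quartile_counts.get("Q1", 0) > 0 else 0
                y_q4 += 1 if quartile_counts.get("Q4", 0) > 0 else 0
            else:
                y_q1 += quartile_counts.get("Q1", 0)
                y_q4 += quartile_counts.get("Q4", 0)
        count_q1 += y_q1
        count_q4 += y_q4
        denom = len(chords)
        per_year_q1.append(100.0 * y_q1 / denom)
        per_year_q4.append(100.0 * y_q4 / denom)

    total_new = sum(len(v) for v in new_by_year.values())
    if mode == "per_chord":
        denom_total = total_new
    else:
        denom_total = count_q1 + count_q4
    pct_q1 = 100.0 * count_q1 / denom_total if denom_total else float("nan")
    pct_q4 = 100.0 * count_q4 / denom_total if denom_total else float("nan")
    pct_q1_ym = float(np.mean(per_year_q1)) if per_year_q1 else float("nan")
    pct_q4_ym = float(np.mean(per_year_q4)) if per_year_q4 else float("nan")

    if count_q1 + count_q4 > 0:
        chi2, df, p = chi_square_two_counts(count_q1, count_q4)
    else:
        chi2 = df = p = None
    return NewChordReport(
        new_by_year=new_by_year,
        count_Q1=count_q1,
        count_Q4=count_q4,
        total_new=total_new,
        pct_Q1=pct_q1,
        pct_Q4=pct_q4,
        pct_Q1_yearly_mean=pct_q1_ym,
        pct_Q4_yearly_mean=pct_q4_ym,
        chi2=chi2,
        df=df,
        p=p,
    )
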