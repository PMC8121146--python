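# Methods

## The model

The package measures **zeroth-order harmonic surprise**: how improbable
each chord of a song is under a fixed reference distribution of chords, with
no account taken of chord order. Chords are first normalized to the song's
key — re-expressed as (interval from tonic, quality) — so that the measure
is transposition-invariant and chord counts pool across songs in different
keys. With `M_j` occurrences of the unique chord `C_j` in the baseline
window and `N` unique chords,

    P(C_j) = M_j / Σ_i M_i,        S(C_j) = −log₂ P(C_j)   [bits].

Two per-song summaries follow:

* **absolute surprise** — the mean of `S` over the song's chords;
* **contrastive surprise** — the sample standard deviation (n−1
  denominator) across sections of the per-section mean surprises.

The n−1 denominator is a deliberate choice: songs have few sections, where
the population SD would be noticeably biased downward. The reference
distribution is always estimated from the *earliest* time bin and held
fixed; rising surprise against that fixed baseline in later bins is the
"surprise inflation" the trend statistics quantify. Re-estimating the
baseline per bin is possible (`rebaseline_per_bin`) but defeats the
question and is exposed for exploration only.

### Encodings

Two chord encodings are supported. The *full* encoding keeps quality tokens
as annotated (triads with sixths/sevenths/extensions), an open vocabulary.
The *root-third* encoding folds every chord onto its root and third quality
only, a closed alphabet of exactly 24 symbols (12 intervals × {major,
minor}); chords without a third (sus2/sus4/power chords) have no image
there and are dropped by default, via an explicit, overridable fold table.
Surprise values are not comparable across encodings: a richer vocabulary
spreads probability mass thinner and raises all surprises.

### Out-of-vocabulary chords

`S` is undefined at `P = 0`, so chords absent from the baseline need a
policy. The default **excludes** them from song means and counts them
(`n_excluded`), keeping the surprise scale interpretable; a Laplace policy
scores them as an unseen 25th (…N+1-th) category under add-one smoothing,
`S = log₂(total + N + 1)`, and a cap policy scores them at
`log₂(total + 1)`. Exclusion also applies to contrastive summaries, for
consistency. Songs whose every chord is out of vocabulary get `NaN`
summaries and drop out of aggregates.

## Cohorts

Songs are ranked by peak chart position (1 best), ties broken by more weeks
on the chart, residual ties by song id so every run is deterministic. The
*global* quartile rule labels the top and bottom `floor(n/4)` of the whole
ranking Q1 and Q4 (545 songs → 136 each). The *grouped* rule applies the
same cut inside every (release-year × genre) group, controlling for
genre-specific chart dynamics; groups under 4 songs contribute nothing and
are logged. Time bins are month-bounded and inclusive at both ends; the two
built-in sets cover a 1958–1991 corpus (one long baseline bin, then three
5½-year bins) and a 2000–2019 corpus (four 5-year bins).

## Inference

* **Ordered trend.** The Jonckheere–Terpstra test is applied to per-song
  surprise grouped by time bin in bin order, one-sided for an increasing
  trend, separately within Q1 and Q4. Ties count ½. For pooled n ≤ 12 the
  p-value is exact (exhaustive enumeration over group assignments, valid
  under ties); above that, the large-sample normal approximation with the
  standard tie-corrected variance is used, without continuity correction.
  Monte-Carlo checks in the test suite put the empirical level at
  α = 0.05 within two Monte-Carlo standard errors for 4 × 25 groups.
* **Slopes.** Per-quartile trends are ordinary least squares of per-song
  surprise on fractional release year (year + (month−1)/12). Fitting
  per-song points rather than bin means maximizes the degrees of freedom
  and matches the slope-test df below.
* **Slope equivalence.** Two independently fitted slopes are compared with
  `t = (b₁ − b₂)/√(s₁² + s₂²)` on `n₁ + n₂ − 4` df, two-sided. With both
  standard errors zero the statistic is degenerate and flagged (t = 0,
  p = 1 when slopes agree; p = 0 otherwise).
* **Level differences.** Q1-vs-Q4 means over the post-baseline bins are
  compared with Welch's t-test (a pooled-variance variant is available);
  Welch is the default because quartile variances have no reason to agree.
* **New chords.** For each calendar year after the first, the set of
  canonical chords never seen in an earlier year is computed; each new
  chord is attributed to a quartile if some song of that quartile contains
  it in its introduction year (once per quartile by default; a
  per-occurrence mode is available). Q1-vs-Q4 counts are compared by a
  χ² goodness-of-fit test against equal expectation, df = 1. Because
  "percentage of newly introduced chords" admits two denominators, both
  are reported: the share of all new chords, and the mean of per-year
  shares.
* No multiple-testing correction is applied anywhere; results are reported
  test by test.

## Synthetic corpus generator

External chart corpora with hand-checked annotations are either large
downloads or proprietary, so the package ships a generator that produces
corpora with exactly the structure the analysis assumes. It emulates:

* a long-tailed baseline chord distribution — Zipf with exponent 1.2 over
  the 24 root-third chords, ordered by a stylized prevalence ranking
  (tonic/dominant/subdominant majors first, chromatic minors last);
* per-year drift of each song's chord distribution toward the rare tail,
  steeper for top-tier songs (defaults 0.09 vs 0.03 bits/year — a 3:1
  inflation ratio, with the middle tier halfway between);
* section structure (4–8 sections of 8–24 chords) with controllable
  between-section surprise heterogeneity (defaults 0.08/0.05 bits);
* chart ranks coupled to the drift tier, plus weeks-on-chart decreasing in
  rank with noise;
* optionally, gradual revelation of extended-quality chords (more often in
  the top tier) so new-chord analyses have signal.

### Exact drift calibration

Drift is implemented as mixing, not count manipulation: a section with
mixing weight `w` samples chords from `Q_w = (1−w)·P + w·R`, where `R` is
uniform over the *rare half* of the vocabulary. Spreading the tail target
over many chords matters: piling it onto the single rarest chord would make
that chord common in later years and destroy its surprise.

Scored against any fixed reference `F`, expected surprise is linear in the
mixing weight: `E[S|w] = CE(P, F) + w·g(F)` with
`g(F) = Σ_c (R_c − P_c)·S_F(c)`. The subtlety is which `F` the pipeline
actually uses: the *empirical first-bin distribution*, which the
generator's own mixing has already flattened relative to `P`. Calibrating
against `P` would under-deliver the configured bits/year by roughly a
factor of three at the default settings. The generator therefore computes
the expected first-bin mixture `P̄ = (1−w̄)P + w̄R` — `w̄` is the mean
mixing weight over the assumed baseline era (`baseline_years`, default 5,
matching the 5-year first bin of the modern bin set) — solves the
one-dimensional fixed point between `w̄` and `g(P̄)`, and sets

    w(t) = w0 + β_tier · t / g(P̄).

Expected measured surprise is then `const + β_tier·t` for every tier: the
configured drift is the slope the pipeline recovers, in expectation,
exactly. The floor `w0` equals the largest section-offset half-width so
that per-section offsets (uniform, SD = `contrast` bits) never truncate at
`w = 0`, which would bend the trend. Configurations whose peak weight
would exceed 1 — too much drift, contrast, or time for the vocabulary —
are rejected with an "infeasible ranges" error rather than silently
clipped. This bound is why the default contrast values are small: at a
24-chord vocabulary, 0.09 bits/year sustained for 20 years consumes most
of the feasible mixing range. (Real corpora showing 0.09-bits/year
inflation do so on a much richer chord vocabulary; the 24-symbol default
here is a deliberately compact test bed.)

### Rank assignment

Peak positions are assigned within each year. In the default `tier` mode,
ranks follow the generative tier blocks (top tier gets the best ranks),
ordered inside each block by noisy realized surprise — so rank correlates
with surprise through and within tiers, and re-deriving quartiles from
ranks recovers the tiers while still exercising the cohort module. A
literal `surprise` mode ranks purely by noisy realized surprise; it is
more naturalistic but conflates selection with drift: early on, when tiers
coincide, the top quartile selects lucky high-surprise songs, and this
selection pressure fades as tiers separate, biasing derived-quartile
slopes well below the configured drift. Parameter-recovery guarantees hold
in `tier` mode only.

### What the generator does not emulate

No harmonic syntax (chord order is exchangeable within a section), no key
modulations, no genre-specific chord distributions (genres are random
tags), no chart-week dynamics beyond a noisy monotone weeks-vs-rank rule,
and no listener model. Contrastive *inflation* is also not targeted: the
`contrast_*` scales are constant over time, and realized contrastive
surprise in fact declines mildly across years because the drifting mixture
concentrates on similarly-surprising tail chords, shrinking the
within-section sampling variance. Only absolute-surprise drift carries a
calibrated ground truth. Passing tests therefore demonstrate that the
*pipeline* is correct and well-calibrated under the assumed generative
structure — not that real chart corpora satisfy that structure.

## Numerical and design notes

* Probabilities use double precision throughout; distribution probabilities
  are validated to sum to 1 within 1e-12, and the OLS path is checked
  against direct normal-equation solutions to 1e-10.
* The JT exact path enumerates multiset assignments via combinations
  (≈ 35k assignments at n = 12, the cutoff), so exactness is testable
  against full-permutation oracles in seconds.
* Contrastive surprise is `NaN` (not 0) for songs with fewer than two
  scoreable sections; `NaN` propagates out of aggregates by exclusion.
* Annotation files are normalized against the tonic in force at each
  chord's position, so modulating songs are handled per-position; the
  interchange table stores already-normalized chords.
* Fixed-length windowing (default W = 16 chords) substitutes for section
  annotations when a source has none.
* All randomness flows from explicit integer seeds (`numpy` Generator);
  corpora, reports, and written tables are bit-reproducible given
  (config, seed).

## Problem sizes used in the test suite

Unit tests run on hand-sized fixtures (the six-song toy corpus whose
surprise values are computed by hand in the README). Calibration checks
use 2000–4000 Monte-Carlo replicates; parameter-recovery checks use 100
corpora at the default size (4 000 songs each, ≈ 380k chords). These sizes
were chosen so the whole suite completes in a few minutes on one CPU while
keeping Monte-Carlo standard errors small relative to the asserted
tolerances.
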