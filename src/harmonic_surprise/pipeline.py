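"""End-to-end analysis orchestration.

``run_analysis`` takes a corpus plus a run configuration and produces the
full report bundle: per-song surprise profiles, per-bin quartile means with
standard errors, trend tests across bins, per-quartile regression slopes
with the slope-equivalence test, bin-2..4 quartile t-tests, and the
new-chord report — every table tidy and tab-separated, with a manifest
recording the configuration hash and library versions for reproducibility.

The surprise baseline is always the distribution of the *first* time bin
(the method measures inflation against a fixed early reference); per-bin
re-estimation is available behind a flag for exploration only.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohorts import (
    TimeBin,
    HISTORIC_BINS,
    MODERN_BINS,
    assign_time_bins,
    bins_from_config,
    classify_quartiles_global,
    classify_quartiles_grouped,
)
from .corpus_io import Corpus, apply_fixed_windows, read_corpus_table
from .stats import (
    compare_slopes,
    fit_trend,
    jonckheere_terpstra,
    new_chord_report,
    two_sample_t,
)
from .surprise import build_distribution, corpus_surprise_profiles

__all__ = ["RunConfig", "AnalysisReport", "run_analysis", "write_report"]

MEASURES = ("absolute", "contrastive")


@dataclass
class RunConfig:
    """Configuration for one analysis run."""

    corpus: Union[str, Path, Corpus]
    bins: Union[str, Sequence[TimeBin]] = "auto"  # 'auto'|'historic'|'modern'|list
    baseline_window: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None
    quartile_rule: str = "global"           # 'global' | 'grouped'
    oov_policy: str = "exclude"
    section_mode: str = "annotation"        # 'annotation' | 'window:<W>'
    rebaseline_per_bin: bool = False        # exploration only
    new_chord_quartile_mode: str = "per_chord"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "bins" in raw and isinstance(raw["bins"], list):
            raw["bins"] = bins_from_config(raw["bins"])
        if "baseline_window" in raw and raw["baseline_window"] is not None:
            s, e = raw["baseline_window"]
            raw["baseline_window"] = (tuple(s), tuple(e))
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Bundle of tidy result tables plus the run manifest."""

    profiles: pd.DataFrame
    bin_summary: pd.DataFrame
    jt_tests: pd.DataFrame
    trends: pd.DataFrame
    slope_tests: pd.DataFrame
    t_tests: pd.DataFrame
    new_chords: pd.DataFrame
    new_chords_by_year: pd.DataFrame
    manifest: Dict = field(default_factory=dict)

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "profiles": self.profiles,
            "bin_summary": self.bin_summary,
            "jt_tests": self.jt_tests,
            "trends": self.trends,
            "slope_tests": self.slope_tests,
            "t_tests": self.t_tests,
            "new_chords": self.new_chords,
            "new_chords_by_year": self.new_chords_by_year,
        }


def _resolve_bins(config: RunConfig, corpus: Corpus) -> List[TimeBin]:
    if isinstance(config.bins, str):
        if config.bins == "historic":
            return list(HISTORIC_BINS)
        if config.bins == "modern":
            return list(MODERN_BINS)
        if config.bins == "auto":
            earliest = min(s.release_year for s in corpus.songs)
            return list(HISTORIC_BINS) if earliest < 2000 else list(MODERN_BINS)
        raise ValueError(f"unknown bin set {config.bins!r}")
    return list(config.bins)


def _config_hash(config: RunConfig) -> str:
    payload = {
        k: v
        for k, v in vars(config).items()
        if k != "corpus" and not isinstance(v, Corpus)
    }
    payload["bins"] = (
        config.bins
        if isinstance(config.bins, str)
        else [(b.name, b.start, b.end) for b in config.bins]
    )
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Run the full analysis; deterministic given (corpus, config)."""
    corpus = (
        config.corpus
        if isinstance(config.corpus, Corpus)
        else read_corpus_table(config.corpus)
    )
    if config.section_mode.startswith("window:"):
        w = int(config.section_mode.split(":", 1)[1])
        corpus = Corpus(
            songs=[apply_fixed_windows(s, w) for s in corpus.songs],
            encoding=corpus.encoding,
            provenance=corpus.provenance,
        )
    elif config.section_mode != "annotation":
        raise ValueError(f"unknown section mode {config.section_mode!r}")

    bins = _resolve_bins(config, corpus)
    bin_of = assign_time_bins(corpus, bins)
    if config.quartile_rule == "global":
        quartiles = classify_quartiles_global(corpus)
    elif config.quartile_rule == "grouped":
        quartiles = classify_quartiles_grouped(corpus)
    else:
        raise ValueError(f"unknown quartile rule {config.quartile_rule!r}")

    window = config.baseline_window or (bins[0].start, bins[0].end)
    baseline = build_distribution(corpus, window)

    if config.rebaseline_per_bin:
        frames = []
        for b in bins:
            members = [s.id for s in corpus.songs if bin_of[s.id] is b]
            sub = Corpus(
                songs=[s for s in corpus.songs if s.id in set(members)],
                encoding=corpus.encoding,
            )
            dist_b = build_distribution(sub, (b.start, b.end))
            frames.append(corpus_surprise_profiles(sub, dist_b, config.oov_policy))
        profiles = pd.concat(frames, ignore_index=True)
    else:
        profiles = corpus_surprise_profiles(corpus, baseline, config.oov_policy)

    profiles = profiles.copy()
    profiles["bin"] = profiles["song_id"].map(lambda i: bin_of[i].name)
    profiles["quartile"] = profiles["song_id"].map(quartiles)
    profiles["frac_year"] = (
        profiles["release_year"] + (profiles["release_month"] - 1) / 12.0
    )

    bin_order = [b.name for b in bins]
    bin_rows, jt_rows, trend_rows, slope_rows, t_rows = [], [], [], [], []
    trend_by: Dict[Tuple[str, str], object] = {}
    for measure in MEASURES:
        for q in ("Q1", "MID", "Q4"):
            sub = profiles[(profiles["quartile"] == q)].dropna(subset=[measure])
            for b in bin_order:
                vals = sub.loc[sub["bin"] == b, measure].to_numpy()
                bin_rows.append(
                    (
                        measure,
                        q,
                        b,
                        len(vals),
                        float(np.mean(vals)) if len(vals) else np.nan,
                        float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1
                        else np.nan,
                    )
                )
            if q == "MID":
                continue
            groups = [
                sub.loc[sub["bin"] == b, measure].to_numpy() for b in bin_order
            ]
            if sum(len(g) > 0 for g in groups) >= 2:
                jt = jonckheere_terpstra(groups, alternative="increasing")
                jt_rows.append(
                    (measure, q, jt.J, jt.z, jt.p, jt.method, jt.n_total)
                )
            if len(sub) >= 3 and sub["frac_year"].nunique() >= 2:
                tr = fit_trend(sub["frac_year"], sub[measure])
                trend_by[(measure, q)] = tr
                trend_rows.append(
                    (measure, q, tr.slope, tr.intercept, tr.slope_se, tr.n)
                )
        if (measure, "Q1") in trend_by and (measure, "Q4") in trend_by:
            st = compare_slopes(trend_by[(measure, "Q1")], trend_by[(measure, "Q4")])
            slope_rows.append((measure, st.t, st.df, st.p, st.degenerate))
        # Q1-vs-Q4 t-test pooled over the post-baseline bins (2..4)
        later = profiles[profiles["bin"].isin(bin_order[1:])]
        x = later.loc[later["quartile"] == "Q1", measure].dropna().to_numpy()
        y = later.loc[later["quartile"] == "Q4", measure].dropna().to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            t, p = two_sample_t(x, y)
            t_rows.append(
                (measure, "bins2-4", len(x), len(y),
                 float(np.mean(x)), float(np.mean(y)), t, p)
            )

    report_new = new_chord_report(
        corpus, quartiles, mode=config.new_chord_quartile_mode
    )
    new_chords = pd.DataFrame(
        [
            (
                report_new.total_new,
                report_new.count_Q1,
                report_new.count_Q4,
                report_new.pct_Q1,
                report_new.pct_Q4,
                report_new.pct_Q1_yearly_mean,
                report_new.pct_Q4_yearly_mean,
                report_new.chi2,
                report_new.df,
                report_new.p,
            )
        ],
        columns=[
            "total_new", "count_q1", "count_q4", "pct_q1", "pct_q4",
            "pct_q1_yearly_mean", "pct_q4_yearly_mean", "chi2", "df", "p",
        ],
    )
    new_by_year = pd.DataFrame(
        [
            (y, len(chords), ";".join(sorted(chords)))
            for y, chords in sorted(report_new.new_by_year.items())
        ],
        columns=["year", "n_new_chords", "chords"],
    )

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_songs": len(corpus.songs),
        "encoding": corpus.encoding,
        "baseline_window": list(window),
        "baseline_unique_chords": baseline.N,
        "baseline_total_chords": baseline.total,
        "bins": [(b.name, list(b.start), list(b.end)) for b in bins],
        "quartile_rule": config.quartile_rule,
        "oov_policy": config.oov_policy,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    return AnalysisReport(
        profiles=profiles,
        bin_summary=pd.DataFrame(
            bin_rows, columns=["measure", "quartile", "bin", "n", "mean", "se"]
        ),
        jt_tests=pd.DataFrame(
            jt_rows, columns=["measure", "quartile", "J", "z", "p", "method", "n"]
        ),
        trends=pd.DataFrame(
            trend_rows,
            columns=["measure", "quartile", "slope", "intercept", "slope_se", "n"],
        ),
        slope_tests=pd.DataFrame(
            slope_rows, columns=["measure", "t", "df", "p", "degenerate"]
        ),
        t_tests=pd.DataFrame(
            t_rows,
            columns=["measure", "bins", "n_q1", "n_q4",
                     "mean_q1", "mean_q4", "t", "p"],
        ),
        new_chords=new_chords,
        new_chords_by_year=new_by_year,
        manifest=manifest,
    )


def write_report(report: AnalysisReport, outdir) -> None:
    """Write every table as a TSV plus the manifest as YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in report.tables().items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(report.manifest, fh, sort_keys=True)
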