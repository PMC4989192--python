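"""End-to-end orchestration: simulate -> analyze -> report -> recover.

The per-subject path is: classify trial contexts, summarize behavior,
epoch and reject, average per condition, smooth, baseline, measure
components.  The cohort path applies the inclusion rule (at least 20
artifact-free false-alarm epochs), then runs the inferential layer and
assembles one structured report.  :func:`recover` re-simulates replicate
cohorts and tabulates injected vs recovered parameters;
:func:`null_calibration` estimates the false-positive rate of the
condition contrast under a condition-blind generator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior as beh
from . import components as comp
from . import erp, stats
from .config import GroundTruth, PipelineConfig
from .simulate import iter_cohort

__all__ = ["SubjectResult", "analyze_subject", "analyze_cohort",
           "run_cohort", "recover", "null_calibration"]


@dataclass
class SubjectResult:
    subject: int
    summary: beh.BehavioralSummary
    sdt: beh.SDTResult
    n_fa_total: int
    n_fa_clean: int
    measures: pd.DataFrame
    evokeds: dict[str, erp.Evoked]
    truth: GroundTruth | None = None


def analyze_subject(recording: erp.ContinuousRecording,
                    events: pd.DataFrame, cfg: PipelineConfig,
                    subject: int = 0,
                    truth: GroundTruth | None = None) -> SubjectResult:
    """Run the full single-subject analysis."""
    labels = beh.classify_trials(events)
    summary = beh.behavioral_summary(events, labels)
    sdt = beh.sdt_metrics(summary.n_hits, summary.n_misses,
                          summary.n_fa, summary.n_cr)
    evokeds, err_epochs = erp.build_condition_evokeds(
        recording, events, labels,
        window=(cfg.epoch_start_ms, cfg.epoch_end_ms),
        threshold_uv=cfg.rejection_threshold_uv,
        cutoff_hz=cfg.smoothing_cutoff_hz,
        baseline_scheme=cfg.baseline_scheme)
    measures = comp.measure_components(evokeds, cfg.windows, subject)
    return SubjectResult(
        subject=subject, summary=summary, sdt=sdt,
        n_fa_total=summary.n_fa,
        n_fa_clean=int(err_epochs.retained.sum()),
        measures=measures, evokeds=evokeds, truth=truth)


def _discovered_windows(results: list[SubjectResult],
                        cfg: PipelineConfig) -> list:
    """Data-driven analysis windows: per component, the intersection of
    the longest consistently significant runs across its channels; the
    fixed default is kept wherever discovery fails."""
    out = []
    evs = [r.evokeds for r in results]
    for spec in cfg.windows:
        if spec.measure != "mean":
            out.append(spec)
            continue
        try:
            mask = comp.samplewise_paired_ttest(
                evs, "post_error", "post_correct", spec.channels, cfg.alpha)
        except ValueError:
            out.append(spec)
            continue
        wins = [comp.select_window(mask, ch, (cfg.epoch_start_ms, 0.0),
                                   cfg.min_run_ms, spec.component)
                for ch in spec.channels]
        if any(w is None for w in wins):
            out.append(spec)
            continue
        start = max(w.start_ms for w in wins)
        end = min(w.end_ms for w in wins)
        if start >= end:
            out.append(spec)
            continue
        out.append(type(spec)(spec.component, spec.channels, start, end,
                              spec.measure, spec.polarity))
    return out


def analyze_cohort(results: list[SubjectResult],
                   cfg: PipelineConfig) -> dict:
    """Inclusion, inferential statistics and the cohort report."""
    decisions = beh.select_subjects(
        [(r.subject, r.n_fa_total, r.n_fa_clean) for r in results],
        min_clean_fa=cfg.min_clean_fa)
    included = [r for r, d in zip(results, decisions) if d.included]

    if not included:
        return stats.build_report(decisions, [], [], pd.DataFrame(
            columns=["subject", "condition", "component", "channel",
                     "value_uv", "latency_ms"]), cfg.alpha)

    if cfg.discover_windows and len(included) >= 3:
        windows = _discovered_windows(included, cfg)
        measures = pd.concat(
            [comp.measure_components(r.evokeds, windows, r.subject)
             for r in included], ignore_index=True)
    else:
        measures = pd.concat([r.measures for r in included],
                             ignore_index=True)

    # amplitude-RT correlations in the post-error condition
    correlations = []
    rts = np.array([r.summary.median_rt_post_error_hits for r in included],
                   dtype=float)
    if np.isfinite(rts).all() and len(included) >= 3 and rts.std() > 0:
        pe = measures[measures["condition"] == "post_error"]
        for component in ("BP", "pN"):
            cm = pe[pe["component"] == component]
            for ch in sorted(cm["channel"].unique().tolist()):
                amps = (cm[cm["channel"] == ch]
                        .set_index("subject")["value_uv"]
                        .reindex([r.subject for r in included]).to_numpy())
                if np.isfinite(amps).all() and amps.std() > 0:
                    correlations.append(stats.pearson_r(
                        amps, rts,
                        pair=(f"{component}_{ch}_uv", "median_rt_post_error_ms")))

    return stats.build_report(
        decisions,
        [r.summary for r in included],
        [r.sdt for r in included],
        measures, cfg.alpha, correlations=correlations)


def run_cohort(cfg: PipelineConfig, seed: int | None = None,
               n_subjects: int | None = None, keep_evokeds: bool = False,
               ) -> tuple[dict, list[SubjectResult]]:
    """Simulate and analyze one cohort, streaming subject by subject."""
    results = []
    for i, (rec, events, truth) in enumerate(
            iter_cohort(cfg, seed=seed, n_subjects=n_subjects)):
        r = analyze_subject(rec, events, cfg, subject=i, truth=truth)
        if not keep_evokeds and not cfg.discover_windows:
            r.evokeds = {k: v for k, v in r.evokeds.items()
                         if k in ("post_error", "post_correct")}
        results.append(r)
    report = analyze_cohort(results, cfg)
    return report, results


def _cohort_recovery_row(results: list[SubjectResult],
                         report: dict, cfg: PipelineConfig) -> dict:
    """Injected vs recovered quantities for one simulated cohort."""
    included = [r for r in results
                if any(d["subject"] == r.subject and d["included"]
                       for d in report["inclusion"]["decisions"])]
    row: dict = {"n_included": len(included)}
    if not included:
        return row

    # pooled false-alarm counts by context vs the per-subject truths
    for ctx, p_attr in (("post_correct", "p_fa_after_correct"),
                        ("post_error", "p_fa_after_error")):
        n = sum(getattr(r.summary, f"n_nogo_{ctx}") for r in included)
        k = sum(getattr(r.summary, f"n_fa_{ctx}") for r in included)
        expected = sum(
            getattr(r.truth.profile, p_attr)
            * getattr(r.summary, f"n_nogo_{ctx}") for r in included)
        row[f"n_nogo_{ctx}"] = n
        row[f"n_fa_{ctx}"] = k
        row[f"fa_rate_{ctx}"] = k / n if n else math.nan
        row[f"true_fa_rate_{ctx}"] = expected / n if n else math.nan

    pes = [r.summary.pes_ms for r in included if r.summary.pes_ms is not None]
    row["pes_ms"] = float(np.mean(pes)) if pes else math.nan
    row["true_pes_ms"] = float(np.mean(
        [r.truth.true_pes_ms for r in included]))

    beh = report.get("behavior", {})
    if "sdt" in beh:
        row["d_prime_mean"] = beh["sdt"]["d_prime"]["mean"]
        row["criterion_c_mean"] = beh["sdt"]["criterion_c"]["mean"]
    if "pia_test" in beh:
        row["pia_t"] = beh["pia_test"]["t"]
        row["pia_p"] = beh["pia_test"]["p"]
    if "pes_test" in beh:
        row["pes_t"] = beh["pes_test"]["t"]
        row["pes_p"] = beh["pes_test"]["p"]

    comps = report.get("components", {})
    for name, truth_attr in (("pN", "pn_gain_post_error"),
                             ("BP", "bp_gain_post_error")):
        entry = comps.get(name, {})
        means = entry.get("condition_means_uv")
        if means and means.get("post_correct"):
            row[f"{name}_post_error_uv"] = means["post_error"]
            row[f"{name}_post_correct_uv"] = means["post_correct"]
            row[f"{name}_ratio"] = (means["post_error"]
                                    / means["post_correct"])
        row[f"true_{name}_ratio"] = float(np.mean(
            [getattr(r.truth, truth_attr) for r in included]))
        anova = entry.get("anova")
        if anova:
            row[f"{name}_condition_F"] = anova["effects"]["condition"]["F"]
            row[f"{name}_condition_p"] = anova["effects"]["condition"]["p"]
    return row


def recover(cfg: PipelineConfig, n_replicates: int = 20,
            seed: int = 0) -> pd.DataFrame:
    """Parameter-recovery table across replicate simulated cohorts.

    One row per replicate with injected and recovered post-error slowing,
    context-conditioned false-alarm rates, and pN/BP condition amplitude
    ratios, plus the p-value of the pN condition effect.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=n_replicates)
    rows = []
    for k, s in enumerate(rep_seeds):
        report, results = run_cohort(cfg, seed=int(s))
        row = _cohort_recovery_row(results, report, cfg)
        row["replicate"] = k
        row["seed"] = int(s)
        rows.append(row)
    return pd.DataFrame(rows)


def null_calibration(n_replicates: int = 200, seed: int = 0,
                     n_subjects: int = 12,
                     montage=("Fp1", "Fp2"), alpha: float = 0.05) -> dict:
    """False-positive rate of the pN Condition effect under a
    condition-blind generator (all gains equal, no error complex)."""
    cfg = PipelineConfig.null(n_subjects=n_subjects, montage=montage)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=n_replicates)
    n_valid = n_reject = 0
    for s in rep_seeds:
        report, _ = run_cohort(cfg, seed=int(s))
        anova = report.get("components", {}).get("pN", {}).get("anova")
        if not anova:
            continue
        n_valid += 1
        if anova["effects"]["condition"]["p"] < alpha:
            n_reject += 1
    return {"n_replicates": n_valid, "n_rejections": n_reject,
            "rejection_rate": n_reject / n_valid if n_valid else math.nan,
            "alpha": alpha}
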