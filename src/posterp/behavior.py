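"""Sequential trial context and behavioral statistics.

Each trial is labelled by its outcome (hit, miss, correct rejection,
false alarm) and by its context relative to its neighbours within the
same block: *post-error* (the previous trial was a false alarm),
*post-correct* (the previous trial was a hit or a correct rejection) and
*pre-error* (the next trial is a false alarm).  From these the module
computes false-alarm rates by context, median RTs, post-error slowing
(PES), post-error improvement of accuracy (PIA), and signal-detection
sensitivity d' and criterion C with the standard extreme-rate correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import RESPONSE_WINDOW_MS

__all__ = [
    "classify_trials", "behavioral_summary", "sdt_metrics",
    "select_subjects", "BehavioralSummary", "SDTResult", "InclusionDecision",
]


def classify_trials(events: pd.DataFrame) -> pd.DataFrame:
    """Label every trial's outcome and sequential context.

    Context never crosses block boundaries (blocks are separated by rest
    periods), so the first trial of each block carries no post-context
    flag.  Trials whose predecessor is a miss carry neither post flag: a
    miss is neither a correctly responded trial nor a false alarm.

    Returns a DataFrame aligned with ``events`` with columns ``outcome``,
    ``post_error``, ``post_correct``, ``pre_error`` and ``eligible`` (has
    a post-context flag).
    """
    for block, grp in events.groupby("block"):
        on = grp["onset_ms"].to_numpy()
        if np.any(np.diff(on) <= 0):
            raise ValueError(f"block {block}: onsets not strictly increasing")
        if grp["trial"].duplicated().any():
            raise ValueError(f"block {block}: duplicated trial indices")

    lo, hi = RESPONSE_WINDOW_MS
    rt = events["rt_ms"].to_numpy(dtype=float)
    responded = ((events["response"].to_numpy() == 1)
                 & np.isfinite(rt) & (rt >= lo) & (rt < hi))
    is_go = events["category"].to_numpy() == "go"
    outcome = np.where(is_go,
                       np.where(responded, "hit", "miss"),
                       np.where(responded, "false_alarm",
                                "correct_rejection")).astype(object)

    out = pd.DataFrame(index=events.index)
    out["outcome"] = outcome
    prev = pd.Series(outcome, index=events.index).groupby(
        events["block"]).shift(1)
    nxt = pd.Series(outcome, index=events.index).groupby(
        events["block"]).shift(-1)
    out["post_error"] = (prev == "false_alarm").to_numpy()
    out["post_correct"] = prev.isin(["hit", "correct_rejection"]).to_numpy()
    out["pre_error"] = (nxt == "false_alarm").to_numpy()
    out["eligible"] = out["post_error"] | out["post_correct"]
    return out


@dataclass
class BehavioralSummary:
    """Per-subject behavioral statistics; a field is None when its trial
    set is empty (never a fabricated zero)."""

    fa_rate_post_correct: float | None
    fa_rate_post_error: float | None
    median_rt_pre_error_hits: float | None
    median_rt_post_error_hits: float | None
    median_rt_fa: float | None
    pes_ms: float | None
    pia: float | None
    n_fa: int
    n_hits: int
    n_misses: int
    n_cr: int
    # context denominators (No-go trials per context, FAs per context)
    n_nogo_post_correct: int = 0
    n_fa_post_correct: int = 0
    n_nogo_post_error: int = 0
    n_fa_post_error: int = 0


def _median_or_none(values: np.ndarray) -> float | None:
    return float(np.median(values)) if len(values) else None


def behavioral_summary(events: pd.DataFrame,
                       labels: pd.DataFrame | None = None) -> BehavioralSummary:
    """False-alarm rates by context, median RTs, PES and PIA.

    PES = median RT of post-error hits minus median RT of pre-error hits
    (positive = slowing); PIA = FA rate after correct trials minus FA
    rate after errors (positive = improvement).
    """
    if labels is None:
        labels = classify_trials(events)
    outcome = labels["outcome"].to_numpy()
    is_nogo = events["category"].to_numpy() == "nogo"
    rt = events["rt_ms"].to_numpy(dtype=float)

    def fa_counts(flag: np.ndarray) -> tuple[int, int]:
        sel = is_nogo & flag
        return int(sel.sum()), int(np.sum(outcome[sel] == "false_alarm"))

    n_pc, k_pc = fa_counts(labels["post_correct"].to_numpy())
    n_pe, k_pe = fa_counts(labels["post_error"].to_numpy())
    fa_pc = k_pc / n_pc if n_pc else None
    fa_pe = k_pe / n_pe if n_pe else None

    hits = outcome == "hit"
    med_pre = _median_or_none(rt[hits & labels["pre_error"].to_numpy()])
    med_post = _median_or_none(rt[hits & labels["post_error"].to_numpy()])
    med_fa = _median_or_none(rt[outcome == "false_alarm"])

    pes = (med_post - med_pre
           if med_post is not None and med_pre is not None else None)
    pia = fa_pc - fa_pe if fa_pc is not None and fa_pe is not None else None
    return BehavioralSummary(
        fa_rate_post_correct=fa_pc, fa_rate_post_error=fa_pe,
        median_rt_pre_error_hits=med_pre, median_rt_post_error_hits=med_post,
        median_rt_fa=med_fa, pes_ms=pes, pia=pia,
        n_fa=int(np.sum(outcome == "false_alarm")),
        n_hits=int(hits.sum()),
        n_misses=int(np.sum(outcome == "miss")),
        n_cr=int(np.sum(outcome == "correct_rejection")),
        n_nogo_post_correct=n_pc, n_fa_post_correct=k_pc,
        n_nogo_post_error=n_pe, n_fa_post_error=k_pe,
    )


@dataclass
class SDTResult:
    hit_rate_corrected: float
    fa_rate_corrected: float
    d_prime: float
    criterion_c: float


def _correct_rate(k: int, n: int) -> float:
    """Proportion with the extreme-rate floor/ceiling correction: 1 is
    replaced by 1 - 1/(2N) and 0 by 1/(2N), on the rate's own N."""
    p = k / n
    if p >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    if p <= 0.0:
        return 1.0 / (2 * n)
    return p


def sdt_metrics(n_hits: int, n_misses: int, n_fa: int, n_cr: int) -> SDTResult:
    """Signal-detection sensitivity and bias from raw trial counts.

    d' = z(H) - z(FA) and C = -(z(H) + z(FA)) / 2, where z is the
    standard-normal quantile function, H the (corrected) hit rate over Go
    trials and FA the (corrected) false-alarm rate over No-go trials.
    """
    n_go = n_hits + n_misses
    n_nogo = n_fa + n_cr
    if n_go < 1 or n_nogo < 1:
        raise ValueError("need at least one Go and one No-go trial")
    h = _correct_rate(n_hits, n_go)
    f = _correct_rate(n_fa, n_nogo)
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return SDTResult(hit_rate_corrected=h, fa_rate_corrected=f,
                     d_prime=float(zh - zf),
                     criterion_c=float(-(zh + zf) / 2.0))


@dataclass
class InclusionDecision:
    subject: object
    n_fa_total: int
    n_fa_artifact_free: int
    included: bool
    exclusion_reason: str | None


def select_subjects(counts: Iterable[tuple[object, int, int]],
                    min_clean_fa: int = 20) -> list[InclusionDecision]:
    """Apply the inclusion rule: a subject enters the group analysis iff
    they produced at least one false alarm and at least ``min_clean_fa``
    artifact-free false-alarm epochs survive rejection.

    ``counts`` yields (subject id, total FA count, artifact-free FA
    epoch count) triples — i.e. artifact rejection must already have run.
    """
    decisions = []
    for subject, n_total, n_clean in counts:
        if n_total < 1:
            dec = InclusionDecision(subject, n_total, n_clean, False, "no_fa")
        elif n_clean < min_clean_fa:
            dec = InclusionDecision(subject, n_total, n_clean, False,
                                    f"lt{min_clean_fa}_clean_fa")
        else:
            dec = InclusionDecision(subject, n_total, n_clean, True, None)
        decisions.append(dec)
    return decisions
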