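"""Inferential statistics: repeated-measures ANOVA, Bonferroni post-hocs,
paired t-tests, Pearson correlations, percent-change effects, and the
cohort report.

The two-way within-subject ANOVA uses the classical sum-of-squares
partition in which each effect is tested against its own
effect-by-subject interaction mean square, with no sphericity correction,
so the degrees of freedom are the integer design dfs (Condition over two
levels: 1 and n-1; Site over three levels: 2 and 2(n-1)).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTable", "PairwiseComparison", "CorrelationResult",
    "rm_anova_2way", "rm_anova_1way", "bonferroni_pairwise", "paired_t",
    "pearson_r", "effect_percent_change", "build_report", "report_to_json",
]


@dataclass
class AnovaTable:
    """F, dfs and p per effect, plus per-cell descriptives."""

    effects: dict[str, dict[str, float]]   # name -> {F, df1, df2, p}
    cell_means: dict[str, float]
    cell_sds: dict[str, float]
    n_subjects: int


def _f_and_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int,
             tol: float = 0.0) -> tuple[float, float]:
    # sums of squares below tol are rounding residue of a constant table
    if ss_eff <= max(tol, 1e-300):
        return 0.0, 1.0
    if ss_err <= max(tol, 1e-300):
        return math.inf, 0.0
    f = (ss_eff / df_eff) / (ss_err / df_err)
    return float(f), float(sps.f.sf(f, df_eff, df_err))


def _to_cube(table: pd.DataFrame, factors: tuple[str, str]
             ) -> tuple[np.ndarray, list, list, list]:
    """Pivot a tidy (subject, A, B, value) table into an (n, a, b) cube,
    erroring on missing or duplicated cells."""
    fa, fb = factors
    subjects = sorted(table["subject"].unique().tolist())
    la = sorted(table[fa].unique().tolist())
    lb = sorted(table[fb].unique().tolist())
    piv = table.pivot_table(index="subject", columns=[fa, fb],
                            values="value", aggfunc="count")
    if piv.isna().any().any() or (piv != 1).any().any() \
            or piv.shape != (len(subjects), len(la) * len(lb)):
        raise ValueError("design is not complete and balanced: every subject "
                         "must contribute exactly one value per cell")
    cube = np.empty((len(subjects), len(la), len(lb)))
    for i, s in enumerate(subjects):
        sub = table[table["subject"] == s]
        for j, a in enumerate(la):
            for k, b in enumerate(lb):
                cube[i, j, k] = sub[(sub[fa] == a) & (sub[fb] == b)][
                    "value"].iloc[0]
    return cube, subjects, la, lb


def rm_anova_2way(table: pd.DataFrame | np.ndarray,
                  factors: tuple[str, str] = ("condition", "site"),
                  ) -> AnovaTable:
    """Two-way fully within-subject ANOVA.

    ``table`` is either a tidy DataFrame with columns ``subject``, the
    two factor columns and ``value``, or an already-pivoted
    (subjects x levels_A x levels_B) array.  Each effect's F statistic is
    its mean square over its subject-interaction error mean square.
    """
    if isinstance(table, pd.DataFrame):
        cube, _, la, lb = _to_cube(table, factors)
    else:
        cube = np.asarray(table, dtype=float)
        if cube.ndim != 3:
            raise ValueError("array input must be subjects x A x B")
        la = list(range(cube.shape[1]))
        lb = list(range(cube.shape[2]))
    n, a, b = cube.shape
    if n < 2:
        raise ValueError("need at least two subjects")

    g = cube.mean()
    m_s = cube.mean(axis=(1, 2))          # subject means
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_ab = cube.mean(axis=0)              # a x b
    m_as = cube.mean(axis=2)              # n x a
    m_bs = cube.mean(axis=1)              # n x b

    ss_a = n * b * np.sum((m_a - g) ** 2)
    ss_b = n * a * np.sum((m_b - g) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_s = a * b * np.sum((m_s - g) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + g) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + g) ** 2)
    ss_tot = np.sum((cube - g) ** 2)
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    fa, fb = (factors if isinstance(table, pd.DataFrame)
              else ("A", "B"))
    tol = (1e-9 * max(1.0, abs(g))) ** 2 * cube.size
    effects = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
            (fa, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
            (fb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
            (f"{fa} x {fb}", ss_ab, (a - 1) * (b - 1),
             ss_abs, (a - 1) * (b - 1) * (n - 1))):
        f, p = _f_and_p(ss_eff, df_eff, max(ss_err, 0.0), df_err, tol)
        effects[name] = {"F": f, "df1": df_eff, "df2": df_err, "p": p}

    cell_means = {f"{ai}|{bi}": float(m_ab[j, k])
                  for j, ai in enumerate(la) for k, bi in enumerate(lb)}
    cell_sds = {f"{ai}|{bi}": float(cube[:, j, k].std(ddof=1))
                for j, ai in enumerate(la) for k, bi in enumerate(lb)}
    return AnovaTable(effects=effects, cell_means=cell_means,
                      cell_sds=cell_sds, n_subjects=n)


def rm_anova_1way(data: np.ndarray | pd.DataFrame,
                  factor: str = "condition") -> AnovaTable:
    """One-way within-subject ANOVA (subjects x levels array or tidy
    DataFrame with columns subject, <factor>, value)."""
    if isinstance(data, pd.DataFrame):
        levels = sorted(data[factor].unique().tolist())
        piv = data.pivot(index="subject", columns=factor, values="value")
        if piv.isna().any().any():
            raise ValueError("design is not complete and balanced")
        cube = piv[levels].to_numpy()
    else:
        cube = np.asarray(data, dtype=float)
        levels = list(range(cube.shape[1]))
    n, a = cube.shape
    if n < 2:
        raise ValueError("need at least two subjects")
    g = cube.mean()
    m_a = cube.mean(axis=0)
    m_s = cube.mean(axis=1)
    ss_a = n * np.sum((m_a - g) ** 2)
    ss_as = np.sum((cube - m_a[None, :] - m_s[:, None] + g) ** 2)
    tol = (1e-9 * max(1.0, abs(g))) ** 2 * cube.size
    f, p = _f_and_p(ss_a, a - 1, ss_as, (a - 1) * (n - 1), tol)
    return AnovaTable(
        effects={factor: {"F": f, "df1": a - 1, "df2": (a - 1) * (n - 1),
                          "p": p}},
        cell_means={str(l): float(m_a[j]) for j, l in enumerate(levels)},
        cell_sds={str(l): float(cube[:, j].std(ddof=1))
                  for j, l in enumerate(levels)},
        n_subjects=n)


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    mean_difference: float
    p_raw: float
    p_adjusted: float
    significant: bool


def paired_t(a: Sequence[float], b: Sequence[float]
             ) -> tuple[float, int, float]:
    """Two-tailed paired t-test; returns (t, df, p).

    Zero variance of the differences yields a signed infinite t with
    p = 0 (or t = 0, p = 1 when the sequences are identical).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length sequences of length >= 2")
    d = a - b
    df = len(d) - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, d.mean()), df, 0.0
    t = d.mean() / (sd / math.sqrt(len(d)))
    return float(t), df, float(2.0 * sps.t.sf(abs(t), df))


def bonferroni_pairwise(table: pd.DataFrame, factor: str = "site",
                        alpha: float = 0.05) -> list[PairwiseComparison]:
    """All unordered level pairs of ``factor``, paired t within subject,
    with the multiplied-p Bonferroni adjustment (capped at 1)."""
    levels = sorted(table[factor].unique().tolist())
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    piv = table.pivot(index="subject", columns=factor, values="value")
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    out = []
    for la, lb in pairs:
        t, df, p = paired_t(piv[la].to_numpy(), piv[lb].to_numpy())
        p_adj = min(1.0, p * m)
        out.append(PairwiseComparison(
            pair=(str(la), str(lb)),
            mean_difference=float(piv[la].mean() - piv[lb].mean()),
            p_raw=p, p_adjusted=p_adj, significant=p_adj < alpha))
    return out


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    n: int
    p: float


def pearson_r(x: Sequence[float], y: Sequence[float],
              pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Product-moment correlation with two-tailed p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length sequences of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return CorrelationResult(pair=pair, r=float(res.statistic), n=len(x),
                             p=float(res.pvalue))


def effect_percent_change(reference_uv: float, test_uv: float) -> float:
    """Percent amplitude change between two like-signed amplitudes.

    Works on magnitudes, so the phrasing matches components of either
    polarity: 100 * (|test| - |reference|) / |reference|; negative values
    are reductions, positive enhancements.
    """
    if reference_uv == 0:
        raise ValueError("reference amplitude must be nonzero")
    if reference_uv * test_uv < 0:
        raise ValueError("amplitudes must be of like sign")
    return float(100.0 * (abs(test_uv) - abs(reference_uv))
                 / abs(reference_uv))


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

def _descr(values: Sequence[float]) -> dict[str, float]:
    v = np.asarray([x for x in values if x is not None], dtype=float)
    return {"mean": float(v.mean()), "sd": float(v.std(ddof=1))
            if len(v) > 1 else 0.0, "n": int(len(v))}


def build_report(inclusion, behavior_summaries, sdt_results, measures,
                 alpha: float = 0.05, correlations=None) -> dict:
    """Assemble the cohort-level report.

    Parameters
    ----------
    inclusion : list of InclusionDecision for every simulated/loaded subject
    behavior_summaries : list of BehavioralSummary, included subjects only
    sdt_results : list of SDTResult, included subjects only
    measures : tidy component DataFrame (subject, condition, component,
        channel, value_uv, latency_ms), included subjects only
    """
    report: dict = {
        "inclusion": {
            "n_total": len(inclusion),
            "n_included": sum(d.included for d in inclusion),
            "decisions": [asdict(d) for d in inclusion],
        },
    }
    n = report["inclusion"]["n_included"]
    if n == 0:
        report["status"] = "no analyzable subjects"
        return report
    report["status"] = "ok"

    # -- behavior ----------------------------------------------------------
    beh: dict = {}
    for name in ("fa_rate_post_correct", "fa_rate_post_error",
                 "median_rt_pre_error_hits", "median_rt_post_error_hits",
                 "median_rt_fa", "pes_ms", "pia"):
        vals = [getattr(s, name) for s in behavior_summaries]
        beh[name] = _descr(vals)
    pairs = [(s.fa_rate_post_correct, s.fa_rate_post_error)
             for s in behavior_summaries
             if s.fa_rate_post_correct is not None
             and s.fa_rate_post_error is not None]
    if len(pairs) >= 2:
        t, df, p = paired_t([a for a, _ in pairs], [b for _, b in pairs])
        beh["pia_test"] = {"t": t, "df": df, "p": p}
    pairs = [(s.median_rt_post_error_hits, s.median_rt_pre_error_hits)
             for s in behavior_summaries
             if s.median_rt_post_error_hits is not None
             and s.median_rt_pre_error_hits is not None]
    if len(pairs) >= 2:
        t, df, p = paired_t([a for a, _ in pairs], [b for _, b in pairs])
        beh["pes_test"] = {"t": t, "df": df, "p": p}
    beh["sdt"] = {
        "d_prime": _descr([r.d_prime for r in sdt_results]),
        "criterion_c": _descr([r.criterion_c for r in sdt_results]),
    }
    report["behavior"] = beh

    # -- component ANOVAs --------------------------------------------------
    comps: dict = {}
    for comp in sorted(measures["component"].unique().tolist()):
        sub = measures[measures["component"] == comp]
        entry: dict = {}
        n_sites = sub["channel"].nunique()
        tidy = sub.rename(columns={"channel": "site",
                                   "value_uv": "value"})[
            ["subject", "condition", "site", "value"]]
        if n < 2:
            entry["anova"] = None
            entry["reason"] = "insufficient n"
            comps[comp] = entry
            continue
        try:
            if n_sites > 1:
                tab = rm_anova_2way(tidy, ("condition", "site"))
            else:
                tab = rm_anova_1way(tidy[["subject", "condition", "value"]])
        except ValueError as exc:
            entry["anova"] = None
            entry["reason"] = str(exc)
            comps[comp] = entry
            continue
        entry["anova"] = {"effects": tab.effects,
                          "cell_means": tab.cell_means,
                          "cell_sds": tab.cell_sds,
                          "n_subjects": tab.n_subjects}
        cond_means = tidy.groupby("condition")["value"].mean()
        entry["condition_means_uv"] = {k: float(v)
                                       for k, v in cond_means.items()}
        if {"post_correct", "post_error"} <= set(cond_means.index):
            ref = float(cond_means["post_correct"])
            test = float(cond_means["post_error"])
            if ref != 0 and ref * test > 0:
                pc = effect_percent_change(ref, test)
                entry["percent_change"] = {"value": pc,
                                           "rounded": int(round(pc))}
        if n_sites > 1 and n >= 2:
            entry["posthoc_site_by_condition"] = {
                cond: [asdict(c) for c in bonferroni_pairwise(
                    tidy[tidy["condition"] == cond], "site", alpha)]
                for cond in sorted(tidy["condition"].unique().tolist())
            }
        # peak latency ANOVA where latencies exist
        if sub["latency_ms"].notna().all() and n >= 2:
            lat = sub.rename(columns={"latency_ms": "value"})[
                ["subject", "condition", "value"]]
            try:
                ltab = rm_anova_1way(lat)
                entry["latency_anova"] = {"effects": ltab.effects,
                                          "cell_means": ltab.cell_means}
            except ValueError:
                pass
        comps[comp] = entry
    report["components"] = comps
    if correlations is not None:
        report["correlations"] = {
            f"{c.pair[0]}~{c.pair[1]}": {"r": c.r, "n": c.n, "p": c.p}
            for c in correlations}
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    return json.dumps(report, sort_keys=True, indent=1, default=_default)
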