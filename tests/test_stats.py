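"""Inferential layer: ANOVA partition, post-hocs, t, r, percent change."""
import math

import numpy as np
import pandas as pd
import pytest

from posterp import (bonferroni_pairwise, build_report,
                     effect_percent_change, paired_t, pearson_r,
                     report_to_json, rm_anova_1way, rm_anova_2way)

# 3-subject toy table (2 conditions x 3 sites); the expected F values are
# frozen from an independent textbook sum-of-squares decomposition
# (cross-checked in R's aov with an Error(S/(A*B)) stratum).
TOY = np.array([[[1, 2, 3], [2, 4, 5]],
                [[2, 1, 4], [3, 5, 4]],
                [[3, 3, 2], [6, 4, 5]]], dtype=float)


def test_toy_table_matches_hand_computed_partition():
    tab = rm_anova_2way(TOY)
    assert tab.effects["A"]["F"] == pytest.approx(72.25, abs=1e-10)
    assert tab.effects["A"]["p"] == pytest.approx(0.0135599, abs=1e-6)
    assert (tab.effects["A"]["df1"], tab.effects["A"]["df2"]) == (1, 2)
    assert tab.effects["B"]["F"] == pytest.approx(0.9032258, abs=1e-6)
    assert (tab.effects["B"]["df1"], tab.effects["B"]["df2"]) == (2, 4)
    assert tab.effects["B"]["p"] == pytest.approx(0.4745679, abs=1e-6)
    assert tab.effects["A x B"]["F"] == pytest.approx(0.16, abs=1e-10)
    assert tab.effects["A x B"]["p"] == pytest.approx(0.8573388, abs=1e-6)


def test_toy_table_matches_independent_package():
    pg = pytest.importorskip("pingouin")
    rows = [(s, a, b, TOY[s, a, b])
            for s in range(3) for a in range(2) for b in range(3)]
    df = pd.DataFrame(rows, columns=["subject", "A", "B", "value"])
    ref = pg.rm_anova(dv="value", within=["A", "B"], subject="subject",
                      data=df)
    tab = rm_anova_2way(TOY)
    for src, name in (("A", "A"), ("B", "B"), ("A * B", "A x B")):
        want = float(ref.loc[ref["Source"] == src, "F"].iloc[0])
        assert tab.effects[name]["F"] == pytest.approx(want, rel=1e-9)


def test_identical_cells_give_zero_f():
    tab = rm_anova_2way(np.full((4, 2, 3), 1.7))
    for eff in tab.effects.values():
        assert eff["F"] == 0.0 and eff["p"] == 1.0


def test_dfs_match_the_design():
    rng = np.random.default_rng(0)
    tab = rm_anova_2way(rng.normal(size=(36, 2, 3)))
    assert (tab.effects["A"]["df1"], tab.effects["A"]["df2"]) == (1, 35)
    assert (tab.effects["B"]["df1"], tab.effects["B"]["df2"]) == (2, 70)
    assert (tab.effects["A x B"]["df1"], tab.effects["A x B"]["df2"]) == (2, 70)


def test_condition_f_equals_squared_paired_t():
    """For a 2-level within factor, F equals the square of the paired t
    on the per-subject level means."""
    rng = np.random.default_rng(3)
    cube = rng.normal(size=(10, 2, 3))
    tab = rm_anova_2way(cube)
    t, df, p = paired_t(cube[:, 0, :].mean(axis=1),
                        cube[:, 1, :].mean(axis=1))
    assert tab.effects["A"]["F"] == pytest.approx(t ** 2, rel=1e-9)
    assert tab.effects["A"]["p"] == pytest.approx(p, rel=1e-9)
    # same identity for the one-way ANOVA
    one = rm_anova_1way(cube.mean(axis=2))
    assert one.effects["condition"]["F"] == pytest.approx(t ** 2, rel=1e-9)


def test_missing_cell_is_an_explicit_error():
    rows = [(s, a, b, 1.0) for s in range(3) for a in range(2)
            for b in range(3)][:-1]
    df = pd.DataFrame(rows, columns=["subject", "condition", "site",
                                     "value"])
    with pytest.raises(ValueError):
        rm_anova_2way(df)


# ---------------------------------------------------------------------------
# post-hocs and t-tests
# ---------------------------------------------------------------------------

def _tidy(values):
    """values: subjects x levels."""
    rows = [(s, f"l{j}", v) for s, row in enumerate(values)
            for j, v in enumerate(row)]
    return pd.DataFrame(rows, columns=["subject", "site", "value"])


def test_bonferroni_three_levels_multiplier():
    rng = np.random.default_rng(7)
    table = _tidy(rng.normal(size=(8, 3)))
    comps = bonferroni_pairwise(table)
    assert len(comps) == 3
    for c in comps:
        assert c.p_adjusted == pytest.approx(min(1.0, 3.0 * c.p_raw))
        assert c.p_adjusted >= c.p_raw


def test_bonferroni_identical_levels():
    table = _tidy(np.tile([[1.0, 1.0]], (5, 1)))
    (c,) = bonferroni_pairwise(table)
    assert c.mean_difference == 0.0
    assert c.p_adjusted == 1.0 and not c.significant


def test_paired_t_hand_computed_example():
    """Differences (1, 2, 3): mean 2, SD 1, t = 2 * sqrt(3)."""
    t, df, p = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(2.0 * math.sqrt(3.0), abs=1e-12)
    assert df == 2
    assert 0.0 < p < 0.1


def test_paired_t_degenerate_cases():
    t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, p) == (0.0, 1.0)
    t, df, p = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
    assert math.isinf(t) and t > 0 and p == 0.0


# ---------------------------------------------------------------------------
# correlations and effect sizes
# ---------------------------------------------------------------------------

def test_pearson_r_perfect_and_affine_invariance():
    x = np.arange(10.0)
    assert pearson_r(x, x).r == pytest.approx(1.0)
    assert pearson_r(x, -x).r == pytest.approx(-1.0)
    rng = np.random.default_rng(4)
    y = rng.normal(size=10)
    a = pearson_r(x, y)
    b = pearson_r(2.5 * x + 7.0, y)
    assert a.r == pytest.approx(b.r, abs=1e-12)
    assert a.p == pytest.approx(b.p, rel=1e-9)


def test_pearson_r_zero_variance_raises():
    with pytest.raises(ValueError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_percent_change_reduction_and_enhancement():
    """-1.8 -> -0.8 uV is a 56% reduction; -1.4 -> -3.0 uV is a more
    than 100% enhancement (the printed condition means)."""
    red = effect_percent_change(-1.8, -0.8)
    assert round(red) == -56
    enh = effect_percent_change(-1.4, -3.0)
    assert enh > 100.0
    assert enh == pytest.approx(114.29, abs=0.01)
    assert effect_percent_change(-2.0, -2.0) == 0.0


def test_percent_change_rejects_sign_discordant_inputs():
    with pytest.raises(ValueError):
        effect_percent_change(-1.0, 2.0)
    with pytest.raises(ValueError):
        effect_percent_change(0.0, 1.0)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _fake_cohort(n=4):
    from posterp import BehavioralSummary, InclusionDecision, SDTResult
    rng = np.random.default_rng(0)
    inc = [InclusionDecision(i, 30, 25, True, None) for i in range(n)]
    beh = [BehavioralSummary(0.11, 0.04, 408.0, 445.0 + rng.normal(0, 5),
                             395.0, 37.0, 0.07, 30, 390, 10, 370)
           for _ in range(n)]
    sdt = [SDTResult(0.99, 0.11, 3.8, -0.6) for _ in range(n)]
    rows = []
    for i in range(n):
        for cond, gain in (("post_correct", 1.0), ("post_error", 2.14)):
            for ch in ("Fp1", "Fp2"):
                rows.append((i, cond, "pN", ch,
                             -1.4 * gain + rng.normal(0, 0.2), np.nan))
    measures = pd.DataFrame(rows, columns=["subject", "condition",
                                           "component", "channel",
                                           "value_uv", "latency_ms"])
    return inc, beh, sdt, measures


def test_report_contains_every_statistic_family():
    inc, beh, sdt, measures = _fake_cohort()
    report = build_report(inc, beh, sdt, measures)
    assert report["status"] == "ok"
    assert "pes_test" in report["behavior"]
    assert "pia_test" in report["behavior"]
    assert report["components"]["pN"]["anova"]["effects"]["condition"]["F"] > 0
    assert "percent_change" in report["components"]["pN"]
    assert "posthoc_site_by_condition" in report["components"]["pN"]
    assert report["behavior"]["sdt"]["d_prime"]["mean"] == pytest.approx(3.8)


def test_single_subject_report_skips_anova_with_reason():
    inc, beh, sdt, measures = _fake_cohort(n=1)
    report = build_report(inc, beh, sdt, measures)
    assert report["components"]["pN"]["anova"] is None
    assert report["components"]["pN"]["reason"] == "insufficient n"


def test_report_serialization_is_deterministic():
    inc, beh, sdt, measures = _fake_cohort()
    a = report_to_json(build_report(inc, beh, sdt, measures))
    b = report_to_json(build_report(inc, beh, sdt, measures))
    assert a == b
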