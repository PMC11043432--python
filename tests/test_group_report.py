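"""Questionnaire scoring and group-level inference."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from gridclock import group_report as gr


def _items(**overrides):
    base = {k: 3 for k in ("q3", "q4", "q5s", "q10", "q11", "q13",
                           "q5r", "q6r", "q6s", "q9_sp", "q9_verb")}
    base.update(overrides)
    return base


def test_qos_scores_worked_example():
    scores = gr.qos_scores(_items(q5r=4, q6r=5, q5s=2, q6s=2, q9_sp=3, q9_verb=1))
    assert scores["route"] == 9
    assert scores["survey"] == 6
    assert scores["dRS"] == 3
    equal = gr.qos_scores(_items(q5r=4, q6r=4, q5s=3, q6s=3, q9_sp=3, q9_verb=1))
    assert equal["dRS"] == equal["route"] - equal["survey"]


def test_qos_missing_item_raises():
    items = _items()
    del items["q6r"]
    with pytest.raises(KeyError):
        gr.qos_scores(items)


def test_qos_scoring_is_linear():
    items = _items(q5r=4, q6r=5, q5s=2, q6s=2, q9_sp=3, q9_verb=1)
    scaled = {k: 3 * v for k, v in items.items()}
    assert gr.qos_scores(scaled)["dRS"] == 3 * gr.qos_scores(items)["dRS"]


@pytest.mark.parametrize("base, n, alpha", [(0.05, 3, 0.05 / 3), (0.05, 5, 0.01),
                                            (0.05, 1, 0.05)])
def test_bonferroni_alpha(base, n, alpha):
    assert gr.bonferroni_alpha(base, n) == pytest.approx(alpha)


def test_bonferroni_rejects_bad_count():
    with pytest.raises(ValueError):
        gr.bonferroni_alpha(0.05, 0)


def test_normality_gate_selects_t_or_wilcoxon():
    rng = np.random.default_rng(0)
    gauss = rng.normal(0.5, 1.0, 30)
    res = gr.normality_gated_test(gauss)
    assert res.test_name == "one-sample t"
    heavy = rng.lognormal(0.0, 1.2, 30) - 1.0
    res = gr.normality_gated_test(heavy)
    assert res.test_name == "wilcoxon signed-rank"
    with pytest.raises(ValueError):
        gr.normality_gated_test(np.zeros(10))


def test_one_tailed_p_orientation():
    rng = np.random.default_rng(1)
    pos = rng.normal(1.0, 1.0, 25)
    res = gr.normality_gated_test(pos, tails="greater")
    assert res.p < 0.01
    res_wrong = gr.normality_gated_test(pos, tails="less")
    assert res_wrong.p > 0.9


def test_t_tests_match_pingouin_oracle():
    """One-sample and two-sample t p-values agree with an independent
    implementation to 1e-6 on random fixtures."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        x = rng.normal(rng.normal(), 1.0, size=rng.integers(8, 30))
        res = gr.normality_gated_test(x)
        if res.test_name != "one-sample t":
            continue
        ref = pg.ttest(x, 0.0)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)
        assert res.statistic == pytest.approx(float(ref["T"].iloc[0]), abs=1e-6)
        assert res.effect_size == pytest.approx(
            float(pg.compute_effsize(x, 0.0, eftype="cohen")), abs=1e-6
        )
    for _ in range(20):
        a = rng.normal(0.0, 1.0, 19)
        b = rng.normal(0.3, 1.0, 19)
        res = gr.group_compare(a, b)
        if res.test_name != "two-sample t":
            continue
        ref = pg.ttest(a, b, correction=False)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)


def test_group_compare_identical_and_shifted():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 19)
    same = gr.group_compare(x, x.copy())
    assert same.p == pytest.approx(1.0)
    assert same.effect_size == pytest.approx(0.0)
    detected = 0
    for seed in range(30):
        r = np.random.default_rng(seed)
        a = r.normal(0.0, 1.0, 19)
        b = r.normal(2.0, 1.0, 19)  # two pooled SDs apart
        if gr.group_compare(a, b).p < 0.01:
            detected += 1
    assert detected >= 29


def test_levene_flags_variance_heterogeneity():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 0.2, 19)
    b = rng.normal(1.0, 2.0, 19)
    res = gr.group_compare(a, b)
    assert res.extra["levene_p"] < 0.01


def test_correlate_basics_and_calibration():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 19)
    res = gr.correlate(x, 2 * x + 1)
    assert res.statistic == pytest.approx(1.0)
    with pytest.raises(ValueError):
        gr.correlate(x, np.zeros(19))
    rej = 0
    reps = 2000
    for _ in range(reps):
        a = rng.normal(0, 1, 19)
        b = rng.normal(0, 1, 19)
        rej += gr.correlate(a, b).p < 0.05
    assert rej / reps == pytest.approx(0.05, abs=0.015)


def test_partial_correlation_matches_residualization_and_pingouin():
    rng = np.random.default_rng(5)
    z = rng.normal(0, 1, 40)
    x = rng.normal(0, 1, 40)
    y = x + z + rng.normal(0, 0.5, 40)
    res = gr.correlate(x, y, covariate=z)
    df = pd.DataFrame({"x": x, "y": y, "z": z})
    ref = pg.partial_corr(df, x="x", y="y", covar="z")
    assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
    assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


def test_interaction_model_detects_slope_difference():
    rng = np.random.default_rng(6)
    cov = rng.normal(0, 1, 38)
    group = np.array(["a"] * 19 + ["b"] * 19)
    y_null = 0.5 * cov + rng.normal(0, 0.1, 38)
    res = gr.interaction_model(y_null, cov, group)
    assert abs(res.extra["coef"]) < 0.15
    slopes = np.where(group == "a", 0.5, 0.0)
    detected = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        c = r.normal(0, 1, 38)
        y = slopes * c + r.normal(0, 0.3, 38)
        if gr.interaction_model(y, c, group).p < 0.05:
            detected += 1
    assert detected >= 14
    with pytest.raises(ValueError):
        gr.interaction_model(y_null, cov, np.array(["a"] * 38))


def _null_records(rng, n=10):
    rows = []
    for g in ("groupA", "groupB"):
        for i in range(n):
            row = {"subject": f"{g}{i}", "group": g,
                   "roi_activity_beta": rng.normal(), "accuracy": rng.uniform(0.8, 1),
                   "pi_performance": rng.uniform(0.5, 2), "nav_confidence": 20,
                   "route": 8, "survey": 8, "dRS": rng.normal()}
            for f in (4, 5, 6, 7, 8):
                row[f"beta_f{f}"] = rng.normal(0, 1)
                row[f"phi_f{f}"] = rng.uniform(0, 360 / f)
            rows.append(row)
    return pd.DataFrame(rows)


def test_build_report_null_groups_rarely_flag():
    clean = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        report = gr.build_report(_null_records(rng))
        if not any(report["flags"].values()):
            clean += 1
    assert clean >= 8


def test_build_report_deterministic_and_writable(tmp_path):
    rng = np.random.default_rng(11)
    records = _null_records(rng)
    r1 = gr.build_report(records)
    r2 = gr.build_report(records.copy())
    assert r1["summary_md"] == r2["summary_md"]
    gr.write_report(r1, tmp_path)
    assert (tmp_path / "summary.md").read_text() == r1["summary_md"]
    assert (tmp_path / "one_sample.tsv").exists()
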