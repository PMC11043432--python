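"""Questionnaire scoring and group-level inference.

Implements the analysis battery applied to the per-subject scalars:
normality-gated one- and two-sample tests (Shapiro-Wilk at alpha = 0.05
deciding between t tests and rank tests), Bonferroni-corrected alpha
levels, Levene's variance-homogeneity check, Pearson and partial
correlations, a group x covariate interaction model, Rayleigh clustering
of grid orientations, and a report builder that runs the whole battery on
a table of subject records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .circular_stats import CircularSample, rayleigh_test

SHAPIRO_ALPHA = 0.05
REPORT_FOLDS = (4, 5, 6, 7, 8)


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p: float
    effect_size: float
    effect_size_name: str
    ci: tuple[float, float] | None
    alpha_used: float
    tails: str
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_used


# ---------------------------------------------------------------------------
# questionnaire scoring
# ---------------------------------------------------------------------------

NAV_CONFIDENCE_ITEMS = ("q3", "q4", "q5s", "q10", "q11", "q13")
ROUTE_ITEMS = ("q5r", "q6r")
SURVEY_PLUS = ("q5s", "q6s", "q9_sp")
SURVEY_MINUS = ("q9_verb",)


def qos_scores(items: dict) -> dict:
    """Everyday-navigation questionnaire scores.

    Navigation Confidence sums six items; Route knowledge = q5r + q6r;
    Survey knowledge = q5s + q6s + q9_sp - q9_verb; dRS = Route - Survey
    (positive values flag a preference for egocentric route strategies).
    """
    required = set(NAV_CONFIDENCE_ITEMS) | set(ROUTE_ITEMS) | set(SURVEY_PLUS) | set(SURVEY_MINUS)
    missing = required - set(items)
    if missing:
        raise KeyError(f"missing questionnaire items: {sorted(missing)}")
    nav = sum(items[k] for k in NAV_CONFIDENCE_ITEMS)
    route = sum(items[k] for k in ROUTE_ITEMS)
    survey = sum(items[k] for k in SURVEY_PLUS) - sum(items[k] for k in SURVEY_MINUS)
    return {
        "nav_confidence": nav,
        "route": route,
        "survey": survey,
        "dRS": route - survey,
    }


# ---------------------------------------------------------------------------
# inference primitives
# ---------------------------------------------------------------------------

def bonferroni_alpha(base_alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return base_alpha / n_tests


def _one_tailed(p_two: float, statistic: float, tails: str) -> float:
    if tails == "two":
        return p_two
    favored = statistic > 0 if tails == "greater" else statistic < 0
    return p_two / 2.0 if favored else 1.0 - p_two / 2.0


def normality_gated_test(
    sample, mu0: float = 0.0, tails: str = "two", alpha: float = 0.05
) -> TestResult:
    """One-sample location test, t or Wilcoxon depending on normality.

    Shapiro-Wilk at alpha 0.05 gates the choice; the Wilcoxon signed-rank
    uses Pratt handling of zeros and reports r = |z| / sqrt(n).
    """
    x = np.asarray(sample, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: location test degenerate")
    sw_stat, sw_p = stats.shapiro(x)
    d = x - mu0
    if sw_p >= SHAPIRO_ALPHA:
        t_stat, p_two = stats.ttest_1samp(x, mu0)
        p = _one_tailed(float(p_two), float(t_stat), tails)
        cohen_d = float(d.mean() / d.std(ddof=1))
        se = d.std(ddof=1) / math.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        return TestResult(
            test_name="one-sample t",
            statistic=float(t_stat),
            p=p,
            effect_size=cohen_d,
            effect_size_name="cohen_d",
            ci=(float(d.mean() - tcrit * se), float(d.mean() + tcrit * se)),
            alpha_used=alpha,
            tails=tails,
            extra={"shapiro_W": float(sw_stat), "shapiro_p": float(sw_p), "dof": n - 1},
        )
    res = stats.wilcoxon(d, zero_method="pratt", method="approx", correction=False)
    z = float(res.zstatistic)
    p = _one_tailed(float(res.pvalue), -z if tails != "two" else z, tails)
    # sign convention: positive z favors d > 0 under the scipy statistic; use the
    # median sign of d to orient the one-tailed p instead
    if tails != "two":
        favored = np.median(d) > 0 if tails == "greater" else np.median(d) < 0
        p = float(res.pvalue) / 2.0 if favored else 1.0 - float(res.pvalue) / 2.0
    return TestResult(
        test_name="wilcoxon signed-rank",
        statistic=float(res.statistic),
        p=p,
        effect_size=abs(z) / math.sqrt(n),
        effect_size_name="r",
        ci=None,
        alpha_used=alpha,
        tails=tails,
        extra={"z": z, "shapiro_W": float(sw_stat), "shapiro_p": float(sw_p)},
    )


def group_compare(a, b, tails: str = "two", alpha: float = 0.05) -> TestResult:
    """Two-sample comparison with a normality gate and a Levene check.

    Uses the two-sample t test when both groups pass Shapiro-Wilk, the
    Wilcoxon rank-sum (Mann-Whitney) otherwise.  Levene's test for
    homogeneity of variance is reported alongside either way.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    lev_stat, lev_p = stats.levene(a, b, center="median")
    normal = (
        np.ptp(a) > 0
        and np.ptp(b) > 0
        and stats.shapiro(a).pvalue >= SHAPIRO_ALPHA
        and stats.shapiro(b).pvalue >= SHAPIRO_ALPHA
    )
    pooled_sd = math.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    cohen_d = (a.mean() - b.mean()) / pooled_sd if pooled_sd > 0 else 0.0
    if normal:
        t_stat, p_two = stats.ttest_ind(a, b)
        p = _one_tailed(float(p_two), float(t_stat), tails)
        return TestResult(
            test_name="two-sample t",
            statistic=float(t_stat),
            p=p,
            effect_size=float(cohen_d),
            effect_size_name="cohen_d",
            ci=None,
            alpha_used=alpha,
            tails=tails,
            extra={"levene_F": float(lev_stat), "levene_p": float(lev_p),
                   "dof": len(a) + len(b) - 2},
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    n = len(a) + len(b)
    mu = len(a) * len(b) / 2.0
    sd = math.sqrt(len(a) * len(b) * (n + 1) / 12.0)
    z = (float(res.statistic) - mu) / sd
    p = _one_tailed(float(res.pvalue), z, tails)
    if tails != "two":
        favored = np.median(a) > np.median(b) if tails == "greater" else np.median(a) < np.median(b)
        p = float(res.pvalue) / 2.0 if favored else 1.0 - float(res.pvalue) / 2.0
    return TestResult(
        test_name="wilcoxon rank-sum",
        statistic=float(res.statistic),
        p=p,
        effect_size=abs(z) / math.sqrt(n),
        effect_size_name="r",
        ci=None,
        alpha_used=alpha,
        tails=tails,
        extra={"z": z, "levene_F": float(lev_stat), "levene_p": float(lev_p)},
    )


def correlate(x, y, covariate=None, alpha: float = 0.05) -> TestResult:
    """Pearson correlation; partial correlation when a covariate is given.

    The partial correlation residualizes both variables on the covariate
    (with intercept) and correlates the residuals, with dof n - 3.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    if covariate is None:
        r, p = stats.pearsonr(x, y)
        extra = {"r2": float(r**2), "dof": len(x) - 2}
        name = "pearson"
    else:
        z = np.column_stack([np.ones(len(x)), np.asarray(covariate, float)])
        rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
        ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
        r, _ = stats.pearsonr(rx, ry)
        dof = len(x) - 3
        t = r * math.sqrt(dof / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), dof)
        extra = {"r2": float(r**2), "dof": dof}
        name = "partial pearson"
    return TestResult(
        test_name=name,
        statistic=float(r),
        p=float(p),
        effect_size=float(r),
        effect_size_name="r",
        ci=None,
        alpha_used=alpha,
        tails="two",
        extra=extra,
    )


def interaction_model(y, covariate, group, alpha: float = 0.05) -> TestResult:
    """OLS y ~ covariate + group + covariate x group; tests the interaction."""
    y = np.asarray(y, float)
    cov = np.asarray(covariate, float)
    g = pd.Categorical(group)
    if len(g.categories) < 2:
        raise ValueError("interaction model needs at least two groups")
    gi = g.codes.astype(float)
    X = sm.add_constant(np.column_stack([cov, gi, cov * gi]))
    fit = sm.OLS(y, X).fit()
    return TestResult(
        test_name="ols interaction",
        statistic=float(fit.tvalues[3]),
        p=float(fit.pvalues[3]),
        effect_size=float(fit.rsquared),
        effect_size_name="r2",
        ci=tuple(np.asarray(fit.conf_int())[3]),
        alpha_used=alpha,
        tails="two",
        extra={"coef": float(fit.params[3]), "dof": int(fit.df_resid)},
    )


# ---------------------------------------------------------------------------
# report builder
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "subject",
    "group",
    "roi_activity_beta",
    "accuracy",
    "pi_performance",
    "nav_confidence",
    "route",
    "survey",
    "dRS",
]


def build_report(records: pd.DataFrame, folds=REPORT_FOLDS, base_alpha: float = 0.05) -> dict:
    """Run the full group-level battery on a subject-record table.

    ``records`` needs one row per subject with a ``group`` label and, per
    tested fold n, columns ``beta_f{n}`` (cross-validated symmetry
    magnitude) and ``phi_f{n}`` (estimated orientation, degrees).  Returns
    a dict with tidy result tables, a markdown summary, and the
    qualitative pattern flags (which group expresses which symmetry,
    group difference, orientation clustering).
    """
    groups = sorted(records["group"].unique())
    if len(groups) != 2 or records.groupby("group").size().min() < 2:
        raise ValueError("report requires two groups with >= 2 subjects each")
    alpha_folds = bonferroni_alpha(base_alpha, len(folds))

    rows_one = []
    for grp in groups:
        sub = records[records["group"] == grp]
        for n in folds:
            res = normality_gated_test(
                sub[f"beta_f{n}"], mu0=0.0, tails="greater", alpha=alpha_folds
            )
            rows_one.append(
                {
                    "group": grp,
                    "fold": n,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p": res.p,
                    "effect_size": res.effect_size,
                    "alpha": res.alpha_used,
                    "significant": res.significant,
                }
            )
    one_sample = pd.DataFrame(rows_one)

    rows_two = []
    ga, gb = groups
    a_rec = records[records["group"] == ga]
    b_rec = records[records["group"] == gb]
    for n in folds:
        res = group_compare(a_rec[f"beta_f{n}"], b_rec[f"beta_f{n}"], tails="two")
        rows_two.append(
            {
                "fold": n,
                "test": res.test_name,
                "statistic": res.statistic,
                "p": res.p,
                "effect_size": res.effect_size,
                "levene_p": res.extra["levene_p"],
                "mean_diff": a_rec[f"beta_f{n}"].mean() - b_rec[f"beta_f{n}"].mean(),
                "significant": res.significant,
            }
        )
    group_diff = pd.DataFrame(rows_two)

    rows_ray = []
    for grp in groups:
        sub = records[records["group"] == grp]
        for n in folds:
            Z, p = rayleigh_test(
                CircularSample(tuple(sub[f"phi_f{n}"].astype(float)), fold=n)
            )
            rows_ray.append(
                {"group": grp, "fold": n, "Z": Z, "p": p, "significant": p < base_alpha}
            )
    rayleigh = pd.DataFrame(rows_ray)

    rows_corr = []
    for grp in groups:
        sub = records[records["group"] == grp]
        for n in folds:
            res = correlate(sub["roi_activity_beta"], sub[f"beta_f{n}"])
            rows_corr.append(
                {"group": grp, "fold": n, "r": res.statistic, "p": res.p,
                 "significant": res.significant}
            )
    correlations = pd.DataFrame(rows_corr)

    inter = {}
    for n in folds:
        res = interaction_model(
            records[f"beta_f{n}"], records["roi_activity_beta"], records["group"]
        )
        inter[n] = res
    interactions = pd.DataFrame(
        [
            {"fold": n, "t": r.statistic, "p": r.p, "coef": r.extra["coef"],
             "significant": r.significant}
            for n, r in inter.items()
        ]
    )

    rows_beh = []
    for col in ("accuracy", "pi_performance", "dRS", "nav_confidence"):
        if col not in records:
            continue
        res = group_compare(a_rec[col], b_rec[col], tails="two")
        rows_beh.append(
            {"measure": col, "test": res.test_name, "statistic": res.statistic,
             "p": res.p, "effect_size": res.effect_size, "significant": res.significant}
        )
    behavior = pd.DataFrame(rows_beh)

    def sig(table, **mask):
        sel = table
        for k, v in mask.items():
            sel = sel[sel[k] == v]
        return bool(sel["significant"].iloc[0])

    diff4 = group_diff[group_diff["fold"] == 4]
    flags = {
        "fold6_sig_a": sig(one_sample, group=ga, fold=6),
        "fold6_sig_b": sig(one_sample, group=gb, fold=6),
        "fold4_sig_a": sig(one_sample, group=ga, fold=4),
        "fold4_sig_b": sig(one_sample, group=gb, fold=4),
        "fold4_b_gt_a": bool(
            diff4["significant"].iloc[0] and diff4["mean_diff"].iloc[0] < 0
        ),
        "rayleigh_sig_a_f6": sig(rayleigh, group=ga, fold=6),
        "rayleigh_sig_b_f4": sig(rayleigh, group=gb, fold=4),
    }

    summary = _markdown_summary(groups, one_sample, group_diff, rayleigh, behavior, flags)
    return {
        "one_sample": one_sample,
        "group_diff": group_diff,
        "rayleigh": rayleigh,
        "correlations": correlations,
        "interactions": interactions,
        "behavior": behavior,
        "flags": flags,
        "summary_md": summary,
    }


def _markdown_summary(groups, one_sample, group_diff, rayleigh, behavior, flags) -> str:
    lines = ["# Group report", ""]
    lines.append("## n-fold symmetry, one-sample tests (one-tailed, Bonferroni-corrected)")
    lines.append(one_sample.to_string(index=False))
    lines.append("")
    lines.append("## Group differences per fold (two-tailed)")
    lines.append(group_diff.to_string(index=False))
    lines.append("")
    lines.append("## Rayleigh clustering of grid orientations")
    lines.append(rayleigh.to_string(index=False))
    lines.append("")
    if len(behavior):
        lines.append("## Behavioral and questionnaire comparisons")
        lines.append(behavior.to_string(index=False))
        lines.append("")
    lines.append("## Pattern flags")
    for k, v in flags.items():
        lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    for key in ("one_sample", "group_diff", "rayleigh", "correlations",
                "interactions", "behavior"):
        report[key].to_csv(os.path.join(out_dir, f"{key}.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "summary.md"), "w") as fh:
        fh.write(report["summary_md"])
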