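"""Group-level inference: factorial ANOVA, t-tests, FDR, FD/sex matching.

The two-way ANOVA treats every group x target observation as independent (the
factorial form whose error df is N - g*t, matching the reported df structure of
the design it reproduces); a true repeated-measures variant is available via
``repeated=True``.  Effect sizes are partial eta-squared (ANOVA, with a
noncentral-F pivot CI) and Cohen's d (t-tests: sd of differences for paired,
pooled sd for independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .errors import MatchingError, ValidationError


@dataclass
class StatResult:
    name: str
    statistic: float
    df: tuple
    p_raw: float
    effect_name: str
    effect: float
    p_adjusted: float | None = None
    effect_ci: tuple | None = None
    mean_diff_ci: tuple | None = None

    def row(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df1": self.df[0],
            "df2": self.df[1] if len(self.df) > 1 else np.nan,
            "p_raw": self.p_raw,
            "p_adj": self.p_adjusted,
            "effect_name": self.effect_name,
            "effect": self.effect,
            "effect_ci_low": self.effect_ci[0] if self.effect_ci else np.nan,
            "effect_ci_high": self.effect_ci[1] if self.effect_ci else np.nan,
            "ci_low": self.mean_diff_ci[0] if self.mean_diff_ci else np.nan,
            "ci_high": self.mean_diff_ci[1] if self.mean_diff_ci else np.nan,
        }


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results])


# ---------------------------------------------------------------------------
# ANOVA


def partial_eta_sq_ci(f_value: float, df1: int, df2: int,
                      confidence: float = 0.95) -> tuple[float, float, float]:
    """Partial eta^2 with a CI from inverting the noncentral-F distribution.

    eta^2 = df1*F / (df1*F + df2); the CI bounds come from the noncentrality
    parameters lambda solving P(F >= F_obs | lambda_lo) = alpha/2 and
    P(F <= F_obs | lambda_hi) = alpha/2, mapped via eta^2 = lambda/(lambda+df1+df2+1).
    """
    if df1 <= 0 or df2 <= 0:
        raise ValidationError("degrees of freedom must be positive")
    if f_value < 0:
        raise ValidationError("F must be non-negative")
    eta = df1 * f_value / (df1 * f_value + df2)
    alpha = 1.0 - confidence
    n_total = df1 + df2 + 1

    def to_eta(lam: float) -> float:
        return lam / (lam + n_total)

    # sf is increasing and cdf decreasing in the noncentrality; scipy's ncf
    # returns NaN far in the tails, mapped here to the limiting values
    def sf_safe(lam: float) -> float:
        v = sps.ncf.sf(f_value, df1, df2, lam)
        return 1.0 if np.isnan(v) else float(v)

    def cdf_safe(lam: float) -> float:
        v = sps.ncf.cdf(f_value, df1, df2, lam)
        return 0.0 if np.isnan(v) else float(v)

    def bisect(func, target: float, increasing: bool) -> float:
        ub = max(4.0 * (df1 * f_value + 10.0), 10.0)
        for _ in range(60):
            done = func(ub) > target if increasing else func(ub) < target
            if done:
                break
            ub *= 2.0
        lo_b, hi_b = 0.0, ub
        for _ in range(200):
            mid = 0.5 * (lo_b + hi_b)
            if (func(mid) < target) == increasing:
                lo_b = mid
            else:
                hi_b = mid
        return 0.5 * (lo_b + hi_b)

    lo = 0.0 if sf_safe(0.0) >= alpha / 2 else bisect(sf_safe, alpha / 2, increasing=True)
    hi = 0.0 if cdf_safe(0.0) <= alpha / 2 else bisect(cdf_safe, alpha / 2, increasing=False)
    # report an interval that always covers the point estimate
    return eta, min(to_eta(lo), eta), max(to_eta(hi), eta)


def factorial_anova(table: pd.DataFrame, repeated: bool = False,
                    confidence: float = 0.95) -> dict:
    """Two-way ANOVA of ``value ~ group * target`` on a long table.

    Columns required: subject, group, target, value.  The default factorial
    form treats all observations as independent (error df N - g*t); with
    ``repeated=True`` a mixed/repeated-measures model is fit instead (the
    between-group effect then comes from a separate test on subject means).
    """
    required = {"subject", "group", "target", "value"}
    if not required.issubset(table.columns):
        raise ValidationError(f"long table must have columns {sorted(required)}")
    counts = table.groupby(["group", "target"], sort=False).size()
    if counts.nunique() != 1:
        raise ValidationError("design must be balanced (equal cell counts)")
    if table["group"].nunique() != 2:
        raise ValidationError("exactly two groups required")
    if table["target"].nunique() < 2:
        raise ValidationError("at least two targets required")

    if repeated:
        return _mixed_anova(table, confidence)

    model = ols("value ~ C(group) * C(target)", data=table).fit()
    aov = anova_lm(model, typ=2)
    df_err = int(aov.loc["Residual", "df"])
    results = {}
    for effect, label in [("C(group)", "group"), ("C(target)", "target"),
                          ("C(group):C(target)", "interaction")]:
        df1 = int(aov.loc[effect, "df"])
        if aov.loc[effect, "sum_sq"] < 1e-12:   # degenerate (e.g. constant) data
            f_value, p = 0.0, 1.0
        else:
            f_value = float(aov.loc[effect, "F"])
            p = float(aov.loc[effect, "PR(>F)"])
        eta, lo, hi = partial_eta_sq_ci(f_value, df1, df_err, confidence)
        results[label] = StatResult(
            name=f"anova_{label}", statistic=f_value, df=(df1, df_err),
            p_raw=p, effect_name="partial_eta_sq",
            effect=eta, effect_ci=(lo, hi))
    return results


def _mixed_anova(table: pd.DataFrame, confidence: float) -> dict:
    """True mixed-design decomposition: group tested against subjects-within-
    groups, target and interaction against the within-subject error."""
    grand = table["value"].mean()
    groups = table["group"].unique()
    targets = table["target"].unique()
    g, t = len(groups), len(targets)
    n = table["subject"].nunique() // g

    subj_means = table.groupby("subject")["value"].mean()
    group_means = table.groupby("group")["value"].mean()
    target_means = table.groupby("target")["value"].mean()
    cell_means = table.groupby(["group", "target"])["value"].mean()

    ss_group = n * t * ((group_means - grand) ** 2).sum()
    ss_between_subj = t * ((subj_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_target = g * n * ((target_means - grand) ** 2).sum()
    ss_inter = n * sum(
        (cell_means[(gr, ta)] - group_means[gr] - target_means[ta] + grand) ** 2
        for gr in groups for ta in targets)
    ss_total = ((table["value"] - grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_target - ss_inter

    df_subj = g * (n - 1)
    df_err = g * (n - 1) * (t - 1)
    out = {}
    for label, ss, df1, ss_denom, df_denom in [
            ("group", ss_group, g - 1, ss_subj_within, df_subj),
            ("target", ss_target, t - 1, ss_err, df_err),
            ("interaction", ss_inter, (g - 1) * (t - 1), ss_err, df_err)]:
        if ss < 1e-12:
            out[label] = StatResult(name=f"anova_{label}", statistic=0.0,
                                    df=(df1, df_denom), p_raw=1.0,
                                    effect_name="partial_eta_sq", effect=0.0,
                                    effect_ci=(0.0, 0.0))
            continue
        f_value = (ss / df1) / (ss_denom / df_denom)
        eta = ss / (ss + ss_denom)
        _, lo, hi = partial_eta_sq_ci(f_value, df1, df_denom, confidence)
        out[label] = StatResult(
            name=f"anova_{label}", statistic=float(f_value), df=(df1, df_denom),
            p_raw=float(sps.f.sf(f_value, df1, df_denom)),
            effect_name="partial_eta_sq", effect=float(eta), effect_ci=(lo, hi))
    return out


# ---------------------------------------------------------------------------
# t-tests


def paired_ttest(a, b, name: str = "paired", confidence: float = 0.95) -> StatResult:
    """Paired t-test; Cohen's d = mean(diff)/sd(diff); CI of the mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("paired samples must be equal-length 1-D arrays, n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd <= 1e-12 * (abs(diff.mean()) + 1.0):
        raise ValidationError("zero-variance differences: t undefined")
    n = len(diff)
    se = sd / np.sqrt(n)
    t_value = diff.mean() / se
    df = n - 1
    p = 2 * sps.t.sf(abs(t_value), df)
    tcrit = sps.t.ppf(0.5 + confidence / 2, df)
    return StatResult(name=name, statistic=float(t_value), df=(df,), p_raw=float(p),
                      effect_name="cohen_d", effect=float(diff.mean() / sd),
                      mean_diff_ci=(float(diff.mean() - tcrit * se),
                                    float(diff.mean() + tcrit * se)))


def independent_ttest(x, y, name: str = "independent",
                      confidence: float = 0.95) -> StatResult:
    """Pooled-variance two-sample t-test; Cohen's d with pooled sd."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 observations")
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if pooled_var == 0:
        raise ValidationError("zero pooled variance: t undefined")
    se = np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    mean_diff = x.mean() - y.mean()
    t_value = mean_diff / se
    p = 2 * sps.t.sf(abs(t_value), df)
    tcrit = sps.t.ppf(0.5 + confidence / 2, df)
    return StatResult(name=name, statistic=float(t_value), df=(df,), p_raw=float(p),
                      effect_name="cohen_d",
                      effect=float(mean_diff / np.sqrt(pooled_var)),
                      mean_diff_ci=(float(mean_diff - tcrit * se),
                                    float(mean_diff + tcrit * se)))


# ---------------------------------------------------------------------------
# Multiple comparisons


def fdr_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Step-up FDR-adjusted p-values (BH) or the Yekutieli variant (BY)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method.lower())
    if key is None:
        raise ValidationError(f"unknown FDR method {method!r}")
    return multipletests(p, method=key)[1]


def attach_fdr(results, method: str = "bh"):
    """Fill ``p_adjusted`` across a family of StatResults; returns the list."""
    adjusted = fdr_adjust([r.p_raw for r in results], method)
    for r, p in zip(results, adjusted):
        r.p_adjusted = float(p)
    return results


# ---------------------------------------------------------------------------
# Cohort matching


@dataclass
class MatchResult:
    pairs: dict            # neonate_id -> adult_id (injective)
    fd_differences: dict   # neonate_id -> |FD_neonate - FD_adult| (mm)


def match_groups(neonates: pd.DataFrame, adult_pool: pd.DataFrame) -> MatchResult:
    """Greedy same-sex 1-NN matching on mean FD, without replacement.

    Both tables need columns subject_id, sex, fd_mean.  Neonates are processed
    in ascending subject_id; ties on |dFD| go to the lowest adult id.
    """
    for table, label in [(neonates, "neonates"), (adult_pool, "adult pool")]:
        if not {"subject_id", "sex", "fd_mean"}.issubset(table.columns):
            raise ValidationError(f"{label} table needs subject_id, sex, fd_mean")
    for sex in neonates["sex"].unique():
        need = int((neonates["sex"] == sex).sum())
        have = int((adult_pool["sex"] == sex).sum())
        if have < need:
            raise MatchingError(
                f"need {need} adults of sex {sex!r} but pool has only {have}")
    available = adult_pool.sort_values("subject_id").copy()
    pairs, diffs = {}, {}
    for _, neo in neonates.sort_values("subject_id").iterrows():
        candidates = available[available["sex"] == neo["sex"]]
        delta = (candidates["fd_mean"] - neo["fd_mean"]).abs()
        best = candidates.loc[delta.idxmin()]  # idxmin: first (lowest id) on ties
        pairs[neo["subject_id"]] = best["subject_id"]
        diffs[neo["subject_id"]] = float(abs(best["fd_mean"] - neo["fd_mean"]))
        available = available[available["subject_id"] != best["subject_id"]]
    return MatchResult(pairs=pairs, fd_differences=diffs)
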