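"""Condition-comparison statistics, effect sizes and confidence intervals.

Implements the full statistical toolkit used for comparing rhythm outcomes
across incubation conditions: odds and odds ratios of rhythm occurrence per
200-s segment, cascading basic-method bootstrap confidence intervals on
mean differences, unbiased (Hedges-corrected) Cohen's d, rank-biserial
correlation for Wilcoxon designs, Friedman tests with Kendall's W,
chi-square distribution tests with Cramer's V, repeated-measures
correlation, and an equal-slopes ANCOVA with Holm-Sidak-adjusted pairwise
comparisons plus a literal identity-line (slope 1, intercept 0) null test.

Effect-size magnitude bands follow the conventional cutoffs: d 0.2/0.5/0.8,
Kendall's W 0.2/0.4, Cramer's V 0.07/0.21/0.35, rank-biserial 0.1/0.3/0.5,
odds ratio 1.5/2/3, r_rm 0.2/0.5/0.8.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

logger = logging.getLogger(__name__)

BOOTSTRAP_LEVELS = (0.95, 0.99, 0.999, 0.9999, 0.99999)


@dataclass
class EffectSize:
    kind: str
    value: float
    band: str  # "none" | "small" | "medium" | "large"


def _band(value: float, cuts: tuple[float, float, float]) -> str:
    v = abs(value)
    if v < cuts[0]:
        return "none"
    if v < cuts[1]:
        return "small"
    if v < cuts[2]:
        return "medium"
    return "large"


def band_cohens_d(d: float) -> str:
    return _band(d, (0.2, 0.5, 0.8))


def band_rank_biserial(r: float) -> str:
    return _band(r, (0.1, 0.3, 0.5))


def band_kendalls_w(w: float) -> str:
    # W in [0, 1]: small < 0.2, medium 0.2-0.39, large >= 0.4
    if w < 0.2:
        return "small"
    if w < 0.4:
        return "medium"
    return "large"


def band_cramers_v(v: float) -> str:
    return _band(v, (0.07, 0.21, 0.35))


def band_odds_ratio(orr: float) -> str:
    # symmetric in direction: OR and 1/OR have the same magnitude
    v = max(orr, 1.0 / orr) if orr > 0 else math.inf
    return _band(v, (1.5, 2.0, 3.0))


def band_r_rm(r: float) -> str:
    return _band(r, (0.2, 0.5, 0.8))


# ---------------------------------------------------------------------------
# Odds and odds ratios

@dataclass
class OddsResult:
    """GMR odds per condition and their ratio with a confidence interval."""

    n_gmr_a: int
    n_non_a: int
    n_gmr_b: int
    n_non_b: int
    odds_a: float
    odds_b: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    confidence_level: float
    method: str
    effect: EffectSize = field(init=False)

    def __post_init__(self) -> None:
        self.effect = EffectSize("odds_ratio", self.odds_ratio,
                                 band_odds_ratio(self.odds_ratio))


def odds_and_or(counts_a: tuple[int, int], counts_b: tuple[int, int],
                level: float = 0.95, method: str = "woolf",
                continuity: bool = False) -> OddsResult:
    """Odds of rhythm occurrence per condition and their ratio.

    ``counts_*`` are ``(n_gmr, n_non)`` segment counts, the non-rhythm count
    combining irregular and absent rhythms.  The default CI is the Woolf
    log-normal interval; ``continuity=True`` adds 0.5 to every cell (needed
    when a cell is zero).
    """
    a1, a0 = counts_a
    b1, b0 = counts_b
    if min(a1, a0, b1, b0) < 0:
        raise ValueError("counts must be non-negative")
    if continuity:
        a1, a0, b1, b0 = (x + 0.5 for x in (a1, a0, b1, b0))
    if min(a0, b0, a1, b1) == 0:
        raise ZeroDivisionError(
            "zero cell in odds computation; enable continuity correction")
    odds_a, odds_b = a1 / a0, b1 / b0
    orr = odds_a / odds_b
    if method != "woolf":
        raise ValueError(f"unknown CI method {method!r}")
    z = sps.norm.ppf(0.5 + level / 2)
    se = math.sqrt(1 / a1 + 1 / a0 + 1 / b1 + 1 / b0)
    lo, hi = math.exp(math.log(orr) - z * se), math.exp(math.log(orr) + z * se)
    return OddsResult(counts_a[0], counts_a[1], counts_b[0], counts_b[1],
                      odds_a, odds_b, orr, lo, hi, level, method)


def odds_ratio_table(counts: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """All pairwise odds ratios from a per-condition (gmr, non_gmr) table."""
    rows = []
    for a in counts.index:
        for b in counts.index:
            if a == b:
                continue
            res = odds_and_or((int(counts.loc[a, "gmr"]), int(counts.loc[a, "non_gmr"])),
                              (int(counts.loc[b, "gmr"]), int(counts.loc[b, "non_gmr"])),
                              level=level)
            rows.append({"condition_a": a, "condition_b": b,
                         "odds_a": res.odds_a, "odds_b": res.odds_b,
                         "odds_ratio": res.odds_ratio,
                         "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "band": res.effect.band})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals

@dataclass
class BootstrapCI:
    """A basic-method (reverse percentile) bootstrap CI at one level.

    The basic method does not guarantee ``low <= point <= high`` for very
    skewed resampling distributions; intervals are reported as computed.
    """

    statistic: str
    point: float
    level: float
    low: float
    high: float
    n_iterations: int

    @property
    def excludes_zero(self) -> bool:
        return self.low > 0 or self.high < 0


def bootstrap_mean_diff_ci(samples_a, samples_b,
                           n_iterations: int = 10_000,
                           rng: np.random.Generator | int | None = None,
                           levels: Sequence[float] = BOOTSTRAP_LEVELS,
                           ) -> list[BootstrapCI]:
    """Cascading basic-method bootstrap CIs on ``mean(a) - mean(b)``.

    Resamples each group with replacement at its own size, 10,000 iterations
    by default.  The 95% interval is always reported; while an interval
    excludes zero, the next level in (99%, 99.9%, 99.99%, 99.999%) is added,
    stopping at the first interval that crosses zero.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    rng = np.random.default_rng(rng)
    est = float(a.mean() - b.mean())
    boot = (a[rng.integers(0, a.size, (n_iterations, a.size))].mean(axis=1)
            - b[rng.integers(0, b.size, (n_iterations, b.size))].mean(axis=1))
    out: list[BootstrapCI] = []
    for level in levels:
        alpha = 1.0 - level
        q_lo, q_hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
        ci = BootstrapCI("mean_difference", est, level,
                         2 * est - float(q_hi), 2 * est - float(q_lo),
                         n_iterations)
        out.append(ci)
        if not ci.excludes_zero:
            break
    return out


# ---------------------------------------------------------------------------
# Effect sizes

def cohens_d_unbiased(samples_a, samples_b) -> EffectSize:
    """Hedges-corrected standardized mean difference (unbiased Cohen's d).

    d = (mean_a - mean_b) / pooled SD, multiplied by the small-sample
    correction J = 1 - 3 / (4 (n_a + n_b - 2) - 1).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least two observations per sample")
    df = na + nb - 2
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df)
    if pooled == 0:
        if a.mean() == b.mean():
            return EffectSize("cohens_d_unbiased", 0.0, "none")
        raise ValueError("zero pooled SD with unequal means")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = j * (a.mean() - b.mean()) / pooled
    return EffectSize("cohens_d_unbiased", float(d), band_cohens_d(d))


def rank_biserial_wilcoxon(paired_diffs) -> EffectSize:
    """Rank-biserial correlation for a Wilcoxon signed-rank design.

    (Sum of positive ranks - sum of negative ranks) / total rank sum over
    the nonzero differences; +1 when every difference is positive, -1 when
    every one is negative.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    r_pos = ranks[d > 0].sum()
    r_neg = ranks[d < 0].sum()
    r = (r_pos - r_neg) / ranks.sum()
    return EffectSize("rank_biserial", float(r), band_rank_biserial(r))


def kendalls_w(rank_input) -> EffectSize:
    """Kendall's coefficient of concordance with tie correction.

    ``rank_input`` is a subjects x conditions value matrix; values are
    midranked within each subject.  W is in [0, 1], 1 meaning every subject
    orders the conditions identically.
    """
    X = np.asarray(rank_input, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 subjects and >=2 conditions")
    n, k = X.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, X)
    col_sums = ranks.sum(axis=0)
    s = float(((col_sums - col_sums.mean()) ** 2).sum())
    tie_term = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts ** 3 - counts).sum())
    denom = n ** 2 * (k ** 3 - k) - n * tie_term
    if denom <= 0:
        return EffectSize("kendalls_w", 0.0, band_kendalls_w(0.0))
    w = 12.0 * s / denom
    return EffectSize("kendalls_w", float(w), band_kendalls_w(w))


def cramers_v(table) -> EffectSize:
    """Cramer's V association for a contingency table: sqrt(chi2 / (n (m-1)))."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2 or obs.sum() == 0:
        raise ValueError("need a non-empty table of at least 2x2")
    chi2 = sps.chi2_contingency(obs, correction=False)[0]
    n = obs.sum()
    m = min(obs.shape) - 1
    v = math.sqrt(chi2 / (n * m))
    return EffectSize("cramers_v", float(v), band_cramers_v(v))


# ---------------------------------------------------------------------------
# Tests

@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    effect: EffectSize
    n_subjects: int
    n_conditions: int


def friedman_with_w(values) -> FriedmanResult:
    """Friedman chi-square over within-subject ranks, with Kendall's W.

    Uses the tie-corrected statistic ``chi2 = n (k - 1) W``; supports the
    paired (k = 2) design, where the test reduces to a sign-test-like
    statistic.  Missing cells are an error (complete blocks required).
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be subjects x conditions")
    if np.isnan(X).any():
        raise ValueError("missing cells; Friedman needs complete blocks")
    n, k = X.shape
    w = kendalls_w(X)
    chi2 = n * (k - 1) * w.value
    p = float(sps.chi2.sf(chi2, df=k - 1))
    return FriedmanResult(float(chi2), p, w, n, k)


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float
    dof: int
    effect: EffectSize


def chi_square_distribution_test(table) -> ChiSquareResult:
    """Pearson chi-square on a category x condition count table + Cramer's V."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    if (expected == 0).any():
        raise ValueError("zero expected count; test undefined for this table")
    return ChiSquareResult(float(chi2), float(p), int(dof), cramers_v(obs))


# ---------------------------------------------------------------------------
# Repeated-measures correlation

@dataclass
class RmCorrResult:
    r_rm: float
    r2_rm: float
    ci: tuple[float, float]
    p_value: float
    dof: int
    n_subjects: int
    effect: EffectSize


def repeated_measures_correlation(data: pd.DataFrame,
                                  subject: str = "subject", x: str = "x",
                                  y: str = "y") -> RmCorrResult:
    """Common within-subject correlation (rm_corr).

    Estimates the association shared across subjects by removing
    between-subject offsets (subject-demeaning both variables, the ANCOVA
    with subject as a factor).  ``r_rm`` carries the sign of the common
    slope; dof = N - n_subjects - 1; the 95% CI uses the Fisher z
    transform.  Subjects with fewer than two points are dropped with a
    warning; two subjects suffice.
    """
    df = data[[subject, x, y]].dropna().copy()
    sizes = df.groupby(subject).size()
    small = sizes[sizes < 2].index
    if len(small):
        logger.warning("dropping %d subject(s) with fewer than two points",
                       len(small))
        df = df[~df[subject].isin(small)]
    if df[subject].nunique() < 2:
        raise ValueError("need at least two subjects with >=2 points each")

    xd = df[x] - df.groupby(subject)[x].transform("mean")
    yd = df[y] - df.groupby(subject)[y].transform("mean")
    ss_x, ss_y = float((xd ** 2).sum()), float((yd ** 2).sum())
    if ss_x == 0 or ss_y == 0:
        raise ValueError("no within-subject variance in x or y")
    r = float((xd * yd).sum() / math.sqrt(ss_x * ss_y))
    n_subs = int(df[subject].nunique())
    dof = len(df) - n_subs - 1
    if dof < 1:
        raise ValueError("not enough points for the repeated-measures fit")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(dof / (1.0 - r * r))
        p = float(2 * sps.t.sf(abs(t), dof))
    if dof > 2 and abs(r) < 1.0:
        z = math.atanh(r)
        half = sps.norm.ppf(0.975) / math.sqrt(dof - 1)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (float("nan"), float("nan"))
    return RmCorrResult(r, r * r, ci, p, dof, n_subs,
                        EffectSize("r_rm", r, band_r_rm(r)))


# ---------------------------------------------------------------------------
# Equal-slopes ANCOVA

@dataclass
class AncovaResult:
    """Equal-slopes ANCOVA with Holm-Sidak pairwise adjusted-mean contrasts."""

    interaction_p: float
    slopes_homogeneous: bool
    common_slope: float | None
    adjusted_means: dict[str, float] | None
    pairwise: pd.DataFrame | None      # group_a, group_b, diff, p_raw, p_holm_sidak
    identity_line_tests: dict[str, float] | None   # group -> p vs y = x


def ancova_equal_slopes(data: pd.DataFrame, group: str = "group",
                        x: str = "x", y: str = "y",
                        alpha: float = 0.05) -> AncovaResult:
    """Compare group responses adjusted for a baseline covariate.

    First tests the group x covariate interaction; when slopes are
    homogeneous (p >= alpha), fits the common-slope model, reports
    covariate-adjusted group means at the grand-mean covariate and all
    pairwise adjusted-mean differences with Holm-Sidak correction, plus a
    per-group test of the fitted predictions against the identity line
    (slope 1, intercept 0, i.e. no effect of incubation) via an
    independent-samples t test, following the source procedure literally.
    When slopes differ, adjusted means are withheld.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multitest import multipletests

    df = data[[group, x, y]].dropna().copy()
    df.columns = ["g", "xv", "yv"]
    groups = sorted(df["g"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if (df.groupby("g").size() < 3).any():
        raise ValueError("need at least three points per group")

    full = smf.ols("yv ~ xv * C(g)", data=df).fit()
    reduced = smf.ols("yv ~ xv + C(g)", data=df).fit()
    inter_p = float(anova_lm(reduced, full).iloc[1]["Pr(>F)"])
    if not math.isfinite(inter_p):
        raise ValueError("degenerate design: interaction test undefined")
    if inter_p < alpha:
        return AncovaResult(inter_p, False, None, None, None, None)

    slope = float(reduced.params["xv"])
    grand_x = float(df["xv"].mean())
    grid = pd.DataFrame({"g": groups, "xv": grand_x})
    adj = dict(zip(groups, reduced.predict(grid).astype(float)))

    # pairwise contrasts on the group coefficients (adjusted means share the
    # covariate term, so their differences are coefficient contrasts)
    names = list(reduced.params.index)
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            contrast = np.zeros(len(names))
            for g_label, sign in ((ga, 1.0), (gb, -1.0)):
                term = f"C(g)[T.{g_label}]"
                if term in names:
                    contrast[names.index(term)] += sign
            tt = reduced.t_test(contrast)
            rows.append({"group_a": ga, "group_b": gb,
                         "diff": adj[ga] - adj[gb],
                         "p_raw": float(tt.pvalue)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm_sidak"] = multipletests(pairwise["p_raw"],
                                             method="holm-sidak")[1]

    identity = {}
    for g_label in groups:
        sub = df[df["g"] == g_label]
        pred = reduced.predict(pd.DataFrame({"g": g_label, "xv": sub["xv"]}))
        if np.allclose(pred, sub["xv"]):
            identity[g_label] = 1.0
        else:
            identity[g_label] = float(
                sps.ttest_ind(pred, sub["xv"]).pvalue)
    return AncovaResult(inter_p, True, slope, adj, pairwise, identity)
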