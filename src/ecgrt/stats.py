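"""Cohort statistics over RT index values.

Reproduces the published analysis layer: per-group summaries (n, mean, SD,
SE, t-based 95% CI — the row shape of the cohort tables), three comparison
models against the exercise-ECG-negative reference with Bonferroni
correction, the negative threshold, and ROC/AUC.

Grouping models (reference group is always "negative"):

* model 1 — all exercise-ECG-positive subjects pooled (1 comparison);
* model 2 — stenosis < 50% (normal imaging included) vs >= 50% (2 comparisons);
* model 3 — normal imaging, < 50%, >= 50% separately (3 comparisons).

A repeated-measures design is impossible here (one window per subject,
between-subject groups), so the omnibus test is a one-way ANOVA and the
pairwise tests are two-sample t-tests (Welch by default) computed from
summary statistics, which also makes the published tables' internal
arithmetic directly checkable from their printed rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .records import InvalidParameterError

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "ROCResult",
    "summarize_group",
    "summary_from_stats",
    "se_from_sd",
    "t_test_from_summary",
    "run_model",
    "ModelResult",
    "weighted_subgroup_mean",
    "negative_threshold",
    "roc_auc",
]

#: Model number -> (subgroup label -> cohort groups pooled into it).
MODEL_GROUPS = {
    1: {"positive": ("normal", "lt50", "ge50")},
    2: {"lt50": ("normal", "lt50"), "ge50": ("ge50",)},
    3: {"normal": ("normal",), "lt50": ("lt50",), "ge50": ("ge50",)},
}


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / SD / SE / t-based CI for one group (one table row)."""

    group: str
    n: int
    mean: float
    sd: float | None
    se: float | None
    ci_lower: float | None
    ci_upper: float | None
    ci_level: float = 0.95


@dataclass(frozen=True)
class ComparisonResult:
    model: int
    group_a: str
    group_b: str
    t_statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool
    variance_policy: str = "welch"


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    p_value: float
    positive_class: str = "exercise-ECG positive"


@dataclass(frozen=True)
class ModelResult:
    model: int
    summaries: list
    comparisons: list
    anova_f: float | None
    anova_p: float | None
    skipped: list = field(default_factory=list)


def se_from_sd(sd: float, n: int) -> float:
    """Standard error of the mean, sd / sqrt(n)."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if sd < 0:
        raise InvalidParameterError("sd must be >= 0")
    return sd / math.sqrt(n)


def _ci(mean: float, se: float, n: int, ci_level: float):
    tcrit = sstats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    half = tcrit * se
    return mean - half, mean + half


def summarize_group(values, ci_level: float = 0.95,
                    group: str = "") -> GroupSummary:
    """Summary row from raw values: sample SD (n-1), SE = SD/sqrt(n),
    CI = mean +/- t_{1-(1-level)/2, n-1} * SE.

    With n == 1 the dispersion and CI fields are None (flagged absent).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 1:
        raise InvalidParameterError("need at least one value")
    if not np.all(np.isfinite(v)):
        raise InvalidParameterError("values must be finite")
    n = int(v.size)
    mean = float(v.mean())
    if n < 2:
        return GroupSummary(group, n, mean, None, None, None, None, ci_level)
    sd = float(v.std(ddof=1))
    se = se_from_sd(sd, n)
    lo, hi = _ci(mean, se, n, ci_level)
    return GroupSummary(group, n, mean, sd, se, lo, hi, ci_level)


def summary_from_stats(n: int, mean: float, sd: float | None = None,
                       se: float | None = None, ci_level: float = 0.95,
                       group: str = "") -> GroupSummary:
    """Summary row rebuilt from printed (n, mean, SD-or-SE) numbers.

    This is how published table rows are re-derived without per-subject
    data: give it the printed n, mean and either SD or SE and it recomputes
    the other plus the CI bounds.
    """
    if n < 2:
        raise InvalidParameterError("summary-input mode needs n >= 2")
    if sd is None and se is None:
        raise InvalidParameterError("give sd or se")
    if sd is None:
        sd = se * math.sqrt(n)
    if se is None:
        se = se_from_sd(sd, n)
    lo, hi = _ci(mean, se, n, ci_level)
    return GroupSummary(group, int(n), float(mean), float(sd), float(se),
                        lo, hi, ci_level)


def t_test_from_summary(summary_a: GroupSummary, summary_b: GroupSummary,
                        variance_policy: str = "welch",
                        model: int = 0) -> ComparisonResult:
    """Two-sided two-sample t-test from (n, mean, sd) pairs.

    ``variance_policy``: "welch" (default; the printed groups have unequal
    n and SD) or "pooled".  Two zero-variance groups with equal means give
    p = 1 by convention.
    """
    if variance_policy not in ("welch", "pooled"):
        raise InvalidParameterError("variance_policy must be 'welch' or 'pooled'")
    a, b = summary_a, summary_b
    if a.n < 2 or b.n < 2 or a.sd is None or b.sd is None:
        raise InvalidParameterError("both groups need n >= 2 and an SD")
    if a.sd == 0 and b.sd == 0:
        t_stat = 0.0 if a.mean == b.mean else math.inf * np.sign(a.mean - b.mean)
        p = 1.0 if a.mean == b.mean else 0.0
        df = a.n + b.n - 2
    else:
        res = sstats.ttest_ind_from_stats(
            a.mean, a.sd, a.n, b.mean, b.sd, b.n,
            equal_var=(variance_policy == "pooled"))
        t_stat, p = float(res.statistic), float(res.pvalue)
        if variance_policy == "pooled":
            df = a.n + b.n - 2
        else:
            va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
            df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return ComparisonResult(model=model, group_a=a.group, group_b=b.group,
                            t_statistic=t_stat, df=float(df), p_raw=p,
                            p_adjusted=p, significant=p < 0.05,
                            variance_policy=variance_policy)


def _bonferroni(comp: ComparisonResult, k: int) -> ComparisonResult:
    p_adj = min(1.0, comp.p_raw * k)
    return ComparisonResult(model=comp.model, group_a=comp.group_a,
                            group_b=comp.group_b, t_statistic=comp.t_statistic,
                            df=comp.df, p_raw=comp.p_raw, p_adjusted=p_adj,
                            significant=p_adj < 0.05,
                            variance_policy=comp.variance_policy)


def run_model(results, model: int, ci_level: float = 0.95,
              variance_policy: str = "welch",
              alpha: float = 0.05) -> ModelResult:
    """One grouping model: summaries, pairwise-vs-negative tests, omnibus ANOVA.

    ``results`` is a list of RTResult (or any objects with ``group`` and
    ``rt_pct``).  Each model subgroup is compared against the negative
    reference with a two-sample t-test; Bonferroni factor = number of
    comparisons actually run in the model.  Empty subgroups are skipped and
    reported in ``skipped``.  Values are analyzed on the percent scale.
    """
    if model not in MODEL_GROUPS:
        raise InvalidParameterError("model must be 1, 2 or 3")
    by_group: dict[str, list] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r.rt_pct)
    neg = by_group.get("negative", [])
    if len(neg) < 2:
        raise InvalidParameterError("negative reference group needs n >= 2")
    neg_summary = summarize_group(neg, ci_level, group="negative")

    summaries = [neg_summary]
    comparisons: list[ComparisonResult] = []
    skipped: list[str] = []
    pooled_values = [np.asarray(neg)]
    for label, sources in MODEL_GROUPS[model].items():
        vals = [v for g in sources for v in by_group.get(g, [])]
        if len(vals) < 2:
            skipped.append(label)
            continue
        s = summarize_group(vals, ci_level, group=label)
        summaries.append(s)
        comparisons.append(t_test_from_summary(s, neg_summary,
                                               variance_policy, model=model))
        pooled_values.append(np.asarray(vals))

    k = len(comparisons)
    comparisons = [_bonferroni(c, k) for c in comparisons]
    anova_f = anova_p = None
    if len(pooled_values) >= 2:
        f, p = sstats.f_oneway(*pooled_values)
        anova_f, anova_p = float(f), float(p)
    return ModelResult(model=model, summaries=summaries,
                       comparisons=comparisons,
                       anova_f=anova_f, anova_p=anova_p, skipped=skipped)


def weighted_subgroup_mean(summaries) -> float:
    """Count-weighted mean of subgroup means: sum(n_i * mean_i) / sum(n_i)."""
    summaries = list(summaries)
    if not summaries:
        raise InvalidParameterError("need at least one summary")
    n_total = sum(s.n for s in summaries)
    if n_total <= 0:
        raise InvalidParameterError("total n must be positive")
    return sum(s.n * s.mean for s in summaries) / n_total


def negative_threshold(values=None, summary: GroupSummary | None = None,
                       ci_level: float = 0.95, method: str = "ci_upper",
                       quantile: float = 0.95) -> float:
    """Positivity threshold from the negative reference group.

    The published definition is verbal ("the negative group's RT index"),
    operationalized as the upper CI bound of the negative mean (default) or,
    alternatively, an empirical quantile.  Scores strictly above the
    threshold are flagged positive.
    """
    if method not in ("ci_upper", "quantile"):
        raise InvalidParameterError("method must be 'ci_upper' or 'quantile'")
    if summary is None:
        if values is None:
            raise InvalidParameterError("give values or a summary")
        v = np.asarray(list(values), dtype=float)
        if v.size < 2:
            raise InvalidParameterError("need n >= 2 negative values")
        if method == "quantile":
            return float(np.quantile(v, quantile))
        summary = summarize_group(v, ci_level, group="negative")
    if method == "quantile":
        raise InvalidParameterError("quantile method needs raw values")
    if summary.ci_upper is None:
        raise InvalidParameterError("summary lacks a CI (n < 2?)")
    return float(summary.ci_upper)


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC for separating positives from negatives.

    AUC uses the rank (Mann-Whitney) formulation with midrank tie handling;
    its p-value is the normal approximation to the Mann-Whitney statistic
    with tie correction, two-sided against AUC = 0.5.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if s.size != y.size or s.size == 0:
        raise InvalidParameterError("scores and labels must be equal-length, non-empty")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InvalidParameterError("both classes must be present")

    ranks = sstats.rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # Normal approximation with tie correction for the MWU null variance.
    n = n_pos + n_neg
    _, counts = np.unique(s, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n_pos * n_neg / 12.0 * ((n + 1) - tie_term)
    u = auc * n_pos * n_neg
    if var_u <= 0:
        p = 1.0
    else:
        z = (u - n_pos * n_neg / 2.0) / math.sqrt(var_u)
        p = 2.0 * sstats.norm.sf(abs(z))

    # Step-function ROC: sweep unique scores as strict ">" thresholds.
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    sens = np.array([(s[y == 1] > t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] <= t).mean() for t in thresholds])
    return ROCResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=float(auc), p_value=float(p))
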