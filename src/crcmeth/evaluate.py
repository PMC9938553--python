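"""Cohort-level diagnostic reporting.

Sensitivity/specificity with exact binomial confidence intervals per
clinical group, interfering-disease negative rates (pooled by count, never
by averaging subgroup rates), paired tumor/normal tissue comparisons on
delta-Ct, pairwise group-level rank-sum comparisons, participant-flow
accounting, and clinicopathological association testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal display rounding (half away from zero), matching how
    percentages are conventionally printed in clinical reports."""
    factor = 10.0 ** ndigits
    return float(np.floor(abs(x) * factor + 0.5) / factor * np.sign(x))


@dataclass
class PerformanceResult:
    """A binomial performance estimate with its exact 95% CI (percent)."""

    group: str
    kind: str  # 'sensitivity' or 'specificity' or 'negative_rate'
    n: int
    numerator: int
    estimate: float
    ci_low: float
    ci_high: float
    ci_method: str

    def display(self) -> str:
        return (
            f"{self.kind} [{self.group}]: {round_half_up(self.estimate)}% "
            f"({self.numerator}/{self.n}, 95% CI {round_half_up(self.ci_low)}–"
            f"{round_half_up(self.ci_high)}%)"
        )


def binomial_performance(
    numerator: int,
    n: int,
    group: str = "",
    kind: str = "sensitivity",
    ci_method: str = "clopper-pearson",
    alpha: float = 0.05,
) -> PerformanceResult:
    """Point estimate and two-sided exact CI for a k-of-n proportion.

    Clopper–Pearson (beta-quantile inversion of the binomial tails) by
    default; Wilson score interval available via ``ci_method='wilson'``.
    """
    if n <= 0:
        raise InputError("zero denominator")
    if not 0 <= numerator <= n:
        raise InputError("numerator must lie in [0, n]")
    method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(ci_method)
    if method is None:
        raise InputError(f"unknown ci_method {ci_method!r}")
    lo, hi = proportion_confint(numerator, n, alpha=alpha, method=method)
    return PerformanceResult(
        group=group,
        kind=kind,
        n=n,
        numerator=numerator,
        estimate=100.0 * numerator / n,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        ci_method=ci_method,
    )


def performance(
    calls: Sequence[bool],
    labels: Sequence[int],
    group: str = "",
    ci_method: str = "clopper-pearson",
) -> tuple[PerformanceResult, PerformanceResult]:
    """Sensitivity and specificity of positive/negative calls.

    Sensitivity = positive calls among diseased (label 1); specificity =
    negative calls among controls (label 0). The two use disjoint
    denominators that sum to the group size.
    """
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(labels, dtype=int)
    if calls.size == 0:
        raise InputError("empty group")
    n_dis, n_ctl = int((labels == 1).sum()), int((labels == 0).sum())
    if n_dis == 0 or n_ctl == 0:
        raise InputError("both diseased and control samples are required")
    tp = int((calls & (labels == 1)).sum())
    tn = int((~calls & (labels == 0)).sum())
    sens = binomial_performance(tp, n_dis, group, "sensitivity", ci_method)
    spec = binomial_performance(tn, n_ctl, group, "specificity", ci_method)
    return sens, spec


def negative_rate(
    calls: Sequence[bool], subgroups: Sequence[str], ci_method: str = "clopper-pearson"
) -> pd.DataFrame:
    """Per-subgroup and pooled negative rates for interfering-disease samples.

    The pooled rate is total negatives over total n (the count-weighted
    mean of the subgroup rates, never their unweighted average).
    """
    calls = np.asarray(calls, dtype=bool)
    subgroups = np.asarray(subgroups, dtype=object)
    if calls.size == 0:
        raise InputError("no interfering-disease samples")
    rows = []
    for sg in sorted(set(subgroups)):
        mask = subgroups == sg
        neg, n = int((~calls[mask]).sum()), int(mask.sum())
        r = binomial_performance(neg, n, str(sg), "negative_rate", ci_method)
        rows.append((sg, n, neg, r.estimate, r.ci_low, r.ci_high))
    pooled = binomial_performance(int((~calls).sum()), calls.size, "pooled", "negative_rate", ci_method)
    rows.append(("pooled", pooled.n, pooled.numerator, pooled.estimate, pooled.ci_low, pooled.ci_high))
    return pd.DataFrame(rows, columns=["subgroup", "n", "n_negative", "rate_pct", "ci_low", "ci_high"])


def paired_tissue_comparison(
    tumor_delta_ct: Sequence[float], normal_delta_ct: Sequence[float]
) -> dict:
    """Paired tumor-vs-normal delta-Ct comparison for one marker.

    Counts pairs where the tumor delta-Ct is lower than its paired normal
    (lower delta-Ct = higher methylation) and tests the paired differences
    with the Wilcoxon signed-rank test.
    """
    t = np.asarray(tumor_delta_ct, dtype=float)
    n = np.asarray(normal_delta_ct, dtype=float)
    if t.shape != n.shape or t.size == 0:
        raise InputError("paired comparison requires equal-length, non-empty arrays")
    if not (np.isfinite(t).all() and np.isfinite(n).all()):
        raise InputError("incomplete pair: non-finite delta-Ct")
    higher = int((t < n).sum())
    diff = t - n
    if np.allclose(diff, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(t, n).pvalue)
    return {
        "n_higher": higher,
        "n_total": int(t.size),
        "percent": 100.0 * higher / t.size,
        "p_value": p,
    }


def significance_stars(p: float) -> str:
    """Presentation-only star convention (*P<0.05, **P<0.01, ***P<0.001)."""
    for stars, bound in (("***", 0.001), ("**", 0.01), ("*", 0.05)):
        if p < bound:
            return stars
    return "ns"


def group_level_comparison(
    values: Sequence[float],
    groups: Sequence[str],
    pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum comparisons of methylation level by group.

    Typical groups are NED / AA / CRC I–II / CRC III–IV with mean marker Ct
    as the value. Empty groups are skipped with a notice row.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    present = sorted(set(groups))
    if len(present) < 2 and pairs is None:
        return pd.DataFrame(columns=["group_a", "group_b", "n_a", "n_b", "p_value", "stars", "note"])
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1 :]]
    rows = []
    for a, b in pairs:
        va, vb = values[groups == a], values[groups == b]
        if va.size == 0 or vb.size == 0:
            rows.append((a, b, va.size, vb.size, np.nan, "", "empty group skipped"))
            continue
        p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        rows.append((a, b, va.size, vb.size, p, significance_stars(p), ""))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "p_value", "stars", "note"])


def account_samples(roster: pd.DataFrame) -> dict:
    """Participant-flow summary from a roster with exclusion flags.

    Every participant lands in exactly one arm: ``excluded`` (any exclusion
    flag), ``interfering``, or ``main``. Returns total enrollment, per-arm
    counts and per-reason exclusion counts; raises if flags contradict the
    recorded ``analysis_arm``.
    """
    flag_cols = [
        c
        for c in roster.columns
        if c not in ("participant_id", "group", "interfering", "analysis_arm")
        and roster[c].dtype == bool
    ]
    excluded = roster[flag_cols].any(axis=1) if flag_cols else pd.Series(False, index=roster.index)
    interfering = roster["interfering"] if "interfering" in roster else pd.Series(False, index=roster.index)
    derived = np.where(excluded, "excluded", np.where(interfering, "interfering", "main"))
    if "analysis_arm" in roster.columns:
        clash = roster.loc[roster["analysis_arm"] != derived, "participant_id"]
        if len(clash):
            raise InputError(f"contradictory flags for participants: {list(clash[:5])}")
    arms = pd.Series(derived).value_counts()
    return {
        "enrolled": int(len(roster)),
        "main": int(arms.get("main", 0)),
        "interfering": int(arms.get("interfering", 0)),
        "excluded": int(arms.get("excluded", 0)),
        "excluded_by_reason": {c: int(roster[c].sum()) for c in flag_cols},
    }


def sample_type_total(analyzed_counts: Mapping[str, int], n_interfering: int) -> int:
    """Total samples of one matrix type: analyzed groups plus interfering."""
    return int(sum(analyzed_counts.values()) + n_interfering)


def association_tests(
    outcomes: Sequence[bool], covariates: pd.DataFrame, method: str = "auto"
) -> pd.DataFrame:
    """Association of a binary call/sensitivity indicator with categorical
    clinicopathological covariates.

    With ``method='auto'`` (default): chi-square when every expected cell
    count is >= 5, otherwise Fisher's exact test (2x2 tables; larger sparse
    tables fall back to chi-square with a notice). ``method='fisher'`` or
    ``'chi-square'`` forces one test. Single-level covariates are skipped.
    """
    if method not in ("auto", "fisher", "chi-square"):
        raise InputError(f"unknown method {method!r}")
    outcomes = np.asarray(outcomes, dtype=bool)
    rows = []
    for cov in covariates.columns:
        levels = covariates[cov]
        table = pd.crosstab(levels, outcomes)
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows.append((cov, "skipped", np.nan, "single level"))
            continue
        obs = table.to_numpy()
        expected = stats.contingency.expected_freq(obs)
        use_fisher = (
            method == "fisher"
            or (method == "auto" and not (expected >= 5).all() and obs.shape == (2, 2))
        )
        if use_fisher:
            if obs.shape != (2, 2):
                raise InputError("Fisher's exact test requires a 2x2 table")
            p = float(stats.fisher_exact(obs).pvalue)
            rows.append((cov, "fisher", p, ""))
        elif method == "auto" and not (expected >= 5).all():
            p = float(stats.chi2_contingency(obs).pvalue)
            rows.append((cov, "chi-square", p, "sparse r x c table; exact test unavailable"))
        else:
            p = float(stats.chi2_contingency(obs).pvalue)
            rows.append((cov, "chi-square", p, ""))
    return pd.DataFrame(rows, columns=["covariate", "test", "p_value", "note"])
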