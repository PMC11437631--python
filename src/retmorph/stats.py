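"""Group comparison statistics for cohort morphometry tables.

Implements the statistical layer applied to per-image metric values
grouped by refractive status: per-group descriptives (mean, sample SD,
95% CI of the mean), one-way ANOVA across groups, and pairwise mean
differences with confidence intervals and p-values. The default post hoc
procedure is Fisher's LSD (unadjusted pairwise t tests on the pooled
within-group mean square of the full ANOVA), matching the common
SPSS-style workflow of reporting unadjusted pairwise p-values next to a
one-way ANOVA; Bonferroni adjustment and Welch (unpooled) comparisons
are available via configuration.

Images are treated as independent observations — both eyes of a subject
enter separately. That mirrors the unit of analysis of the reference
cohort but ignores within-subject correlation; see the methods note.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig
from .morphometry import METRICS

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "ComparisonResult",
    "describe",
    "one_way_anova",
    "pairwise_comparison",
    "build_report",
    "PAIR_ORDER",
]

GROUP_ORDER = ("normal", "low", "moderate", "high")
PAIR_ORDER = (
    ("normal", "low"), ("normal", "moderate"), ("normal", "high"),
    ("low", "moderate"), ("low", "high"), ("moderate", "high"),
)


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float
    ss_total: float
    ms_within: float


@dataclass(frozen=True)
class ComparisonResult:
    group_pair: tuple[str, str]
    MD: float
    ci95: tuple[float, float]
    p: float


def describe(values, ci_level: float = 0.95) -> GroupSummary:
    """Mean, sample SD (n−1) and t-based CI of the mean."""
    x = np.asarray(values, float)
    n = len(x)
    if n < 2:
        raise ValueError("describe needs at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(sps.t.ppf((1 + ci_level) / 2, n - 1) * sd / math.sqrt(n))
    return GroupSummary(n=n, mean=mean, sd=sd, ci95=(mean - half, mean + half))


def one_way_anova(groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA over a list of value arrays.

    F = MS_between / MS_within with the standard sum-of-squares
    decomposition; the p-value comes from the F(df_between, df_within)
    distribution.
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    ns = np.array([len(g) for g in gs])
    means = np.array([g.mean() for g in gs])
    grand = float(np.concatenate(gs).mean())
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df_b = len(gs) - 1
    df_w = int(ns.sum()) - len(gs)
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        F = math.inf if ss_b > 0 else 0.0
        p = 0.0 if ss_b > 0 else 1.0
    else:
        F = ms_b / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p,
                       ss_between=ss_b, ss_within=ss_w, ss_total=ss_b + ss_w, ms_within=ms_w)


def pairwise_comparison(
    groups: dict[str, np.ndarray],
    i: str,
    j: str,
    *,
    method: str = "lsd",
    ci_level: float = 0.95,
) -> ComparisonResult:
    """Mean difference ``mean_i − mean_j`` with CI and p-value.

    ``lsd`` (default) uses Fisher's LSD: pooled MSE and residual df from
    the one-way ANOVA over *all* supplied groups. ``bonferroni`` is LSD
    with the p-value multiplied by the number of pairs (capped at 1) and
    a correspondingly wider CI. ``welch`` ignores the pooled MSE and
    uses an unpooled two-sample comparison with Satterthwaite df.
    """
    for k in (i, j):
        if k not in groups:
            raise ValueError(f"unknown group label {k!r}")
    xi = np.asarray(groups[i], float)
    xj = np.asarray(groups[j], float)
    md = float(xi.mean() - xj.mean())
    if i == j:
        return ComparisonResult((i, j), 0.0, (0.0, 0.0), 1.0)
    m = len(groups)
    n_pairs = m * (m - 1) // 2
    alpha = 1 - ci_level
    if method in ("lsd", "bonferroni"):
        anova = one_way_anova(list(groups.values()))
        se = math.sqrt(anova.ms_within * (1 / len(xi) + 1 / len(xj))) if anova.ms_within > 0 else 0.0
        df = anova.df_within
        if method == "bonferroni":
            alpha = alpha / n_pairs
    elif method == "welch":
        vi, vj = xi.var(ddof=1) / len(xi), xj.var(ddof=1) / len(xj)
        se = math.sqrt(vi + vj)
        df = (vi + vj) ** 2 / (
            vi**2 / (len(xi) - 1) + vj**2 / (len(xj) - 1)
        ) if se > 0 else 1.0
    else:
        raise ValueError(f"unknown post hoc method {method!r}")
    if se == 0.0:
        p = 0.0 if md != 0 else 1.0
        return ComparisonResult((i, j), md, (md, md), p)
    t = md / se
    p = float(2 * sps.t.sf(abs(t), df))
    if method == "bonferroni":
        p = min(1.0, p * n_pairs)
    half = float(sps.t.ppf(1 - alpha / 2, df) * se)
    return ComparisonResult((i, j), md, (md - half, md + half), p)


def build_report(cohort: pd.DataFrame, config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """Descriptives, ANOVA and pairwise tables from a cohort CSV frame.

    Expects columns image_id, group, vessel_class plus the five metric
    columns; rows with NaN metric values are dropped per metric. Returns
    {"descriptives": ..., "anova": ..., "pairwise": ...}.
    """
    cfg = config or RunConfig()
    _validate_cohort(cohort)
    desc_rows, anova_rows, pair_rows = [], [], []
    for vessel_class in sorted(cohort["vessel_class"].unique()):
        sub = cohort[cohort["vessel_class"] == vessel_class]
        labels = [g for g in GROUP_ORDER if g in set(sub["group"])]
        for metric in METRICS:
            if metric not in sub.columns:
                continue
            groups = {
                g: sub.loc[sub["group"] == g, metric].dropna().to_numpy() for g in labels
            }
            groups = {g: v for g, v in groups.items() if len(v) >= 2}
            for g, vals in groups.items():
                s = describe(vals, cfg.ci_level)
                desc_rows.append(
                    {"vessel_class": vessel_class, "metric": metric, "group": g,
                     "n": s.n, "mean": s.mean, "sd": s.sd,
                     "ci_low": s.ci95[0], "ci_high": s.ci95[1]}
                )
            if len(groups) < 2:
                warnings.warn(
                    f"{vessel_class}/{metric}: fewer than 2 groups, comparisons skipped",
                    stacklevel=2,
                )
                continue
            a = one_way_anova(list(groups.values()))
            anova_rows.append(
                {"vessel_class": vessel_class, "metric": metric, "F": a.F,
                 "df_between": a.df_between, "df_within": a.df_within, "p": a.p}
            )
            pairs = [p for p in PAIR_ORDER if p[0] in groups and p[1] in groups]
            pairs += [
                p for p in itertools.combinations(groups, 2)
                if p not in pairs and (p[1], p[0]) not in pairs
            ]
            for gi, gj in pairs:
                c = pairwise_comparison(groups, gi, gj, method=cfg.posthoc,
                                        ci_level=cfg.ci_level)
                pair_rows.append(
                    {"vessel_class": vessel_class, "metric": metric,
                     "group_i": gi, "group_j": gj, "MD": c.MD,
                     "ci_low": c.ci95[0], "ci_high": c.ci95[1], "p": c.p}
                )
    return {
        "descriptives": pd.DataFrame(desc_rows),
        "anova": pd.DataFrame(anova_rows),
        "pairwise": pd.DataFrame(pair_rows),
    }


def _validate_cohort(cohort: pd.DataFrame) -> None:
    required = {"image_id", "group", "vessel_class"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    bad = ~cohort["group"].isin(GROUP_ORDER)
    if bad.any():
        rows = cohort.index[bad].tolist()[:10]
        raise ValueError(
            f"invalid group labels at rows {rows}: "
            f"{sorted(set(cohort.loc[bad, 'group']))} (expected {list(GROUP_ORDER)})"
        )
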