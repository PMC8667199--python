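"""Module-level association between differential promoter scores and
expression-trajectory membership.

One-way fixed-effects ANOVA of the signed promoter score on group
membership (modules i-viii plus the non-DE reference "NS"), linear-model
contrasts against NS, and Tukey-Kramer adjusted p-values for each
module-vs-NS comparison via the studentized range distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory import MODULES

NS_LABEL = "NS"


class IntegrationError(ValueError):
    pass


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class ModuleAssociationResult:
    table: pd.DataFrame  # per group: n_genes, mean_score, contrast_vs_ns, tukey_p_vs_ns, stars
    anova_F: float
    anova_p: float
    df_between: int
    df_within: int
    ms_within: float


def _group_scores(
    scores: pd.Series, assignments: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Split scores by trajectory module, pooling non-DE genes into NS."""
    modules = assignments["module"].reindex(scores.index).fillna("unassigned")
    groups: dict[str, np.ndarray] = {}
    ns_mask = modules == "unassigned"
    groups[NS_LABEL] = scores[ns_mask].dropna().to_numpy(dtype=float)
    for mod in MODULES:
        groups[mod] = scores[modules == mod].dropna().to_numpy(dtype=float)
    return {g: v for g, v in groups.items() if len(v) > 0}


def module_anova(
    scores: pd.Series,
    assignments: pd.DataFrame,
    min_group: int = 2,
) -> ModuleAssociationResult:
    """ANOVA + Tukey-Kramer contrasts of promoter scores by module.

    Groups with fewer than ``min_group`` genes are dropped with a
    warning.  The NS (not differentially expressed) group is the
    reference: its contrast is 0 by construction, and each module's
    Tukey p is the family-wise adjusted p for the module-vs-NS mean
    difference, q = |diff| / sqrt(MSW/2 * (1/ni + 1/nj)) referred to the
    studentized range with k groups and the within df.
    """
    groups = _group_scores(scores, assignments)
    small = [g for g, v in groups.items() if len(v) < min_group]
    for g in small:
        warnings.warn(f"group {g!r} has < {min_group} genes; dropped", stacklevel=2)
        del groups[g]
    if len(groups) < 2:
        raise IntegrationError("need at least 2 groups with enough genes")
    if NS_LABEL not in groups:
        raise IntegrationError("NS reference group is empty")

    labels = [NS_LABEL] + [m for m in MODULES if m in groups]
    ns = groups[NS_LABEL]
    k = len(labels)
    sizes = {g: len(groups[g]) for g in labels}
    n_total = sum(sizes.values())
    grand = np.concatenate([groups[g] for g in labels]).mean()

    ssb = sum(sizes[g] * (groups[g].mean() - grand) ** 2 for g in labels)
    ssw = sum(((groups[g] - groups[g].mean()) ** 2).sum() for g in labels)
    df_b, df_w = k - 1, n_total - k
    if df_w <= 0:
        raise IntegrationError("no within-group degrees of freedom")
    msb, msw = ssb / df_b, ssw / df_w
    F = msb / msw if msw > 0 else (np.inf if msb > 0 else 0.0)
    anova_p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0

    rows = []
    for g in labels:
        vals = groups[g]
        if g == NS_LABEL:
            contrast, tukey_p = 0.0, np.nan
        else:
            contrast = float(vals.mean() - ns.mean())
            se = np.sqrt(msw / 2.0 * (1.0 / len(vals) + 1.0 / len(ns)))
            q = abs(contrast) / se if se > 0 else np.inf
            tukey_p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append(
            {
                "group": g,
                "n_genes": sizes[g],
                "mean_score": float(vals.mean()),
                "contrast_vs_ns": contrast,
                "tukey_p_vs_ns": tukey_p,
                "stars": "" if np.isnan(tukey_p) else _stars(tukey_p),
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    return ModuleAssociationResult(
        table=table,
        anova_F=float(F),
        anova_p=anova_p,
        df_between=df_b,
        df_within=df_w,
        ms_within=float(msw),
    )


def tukey_all_pairs(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey-Kramer adjusted p for every group pair (calibration surface).

    Shares the machinery of :func:`module_anova`: pooled within-group
    variance, q = |diff| / sqrt(MSW/2 * (1/ni + 1/nj)), studentized
    range with k groups and within df.
    """
    labels = sorted(groups)
    k = len(labels)
    if k < 2:
        raise IntegrationError("need >= 2 groups")
    n_total = sum(len(groups[g]) for g in labels)
    df_w = n_total - k
    ssw = sum(((groups[g] - groups[g].mean()) ** 2).sum() for g in labels)
    msw = ssw / df_w
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            diff = groups[a].mean() - groups[b].mean()
            se = np.sqrt(msw / 2.0 * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            q = abs(diff) / se if se > 0 else np.inf
            rows.append((a, b, diff, float(stats.studentized_range.sf(q, k, df_w))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "tukey_p"])


def summarize_boxplot(
    scores: pd.Series,
    assignments: pd.DataFrame,
    result: ModuleAssociationResult | None = None,
) -> pd.DataFrame:
    """Box-plot summary per group: quartiles, 1.5*IQR whiskers, stars."""
    groups = _group_scores(scores, assignments)
    rows = []
    for g in [NS_LABEL] + [m for m in MODULES if m in groups]:
        if g not in groups:
            continue
        vals = groups[g]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        whisk_lo = float(inside.min()) if len(inside) else float(q1)
        whisk_hi = float(inside.max()) if len(inside) else float(q3)
        stars = ""
        if result is not None and g in result.table.index and g != NS_LABEL:
            p = result.table.loc[g, "tukey_p_vs_ns"]
            stars = _stars(float(p)) if not np.isnan(p) else ""
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "whisker_low": whisk_lo,
                "whisker_high": whisk_hi,
                "stars": stars,
            }
        )
    return pd.DataFrame(rows).set_index("group")
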