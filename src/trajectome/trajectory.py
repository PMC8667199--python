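"""Eight-way expression-trajectory module assignment.

Each gene that is differentially expressed at either timepoint is placed
in exactly one module based on its (day-1 status, day-14 status) pair
and, for genes significant at both days in the same direction, on
whether the absolute model fold change grew or shrank between days:

====== ========= ========== =======================================
module status d1 status d14 magnitude rule
====== ========= ========== =======================================
i      up        up         |fc14| > |fc1|   (keeps increasing)
ii     up        up         |fc14| <= |fc1|  (partial recovery)
iii    ns        up         delayed upregulation
iv     up        ns         full recovery from acute upregulation
v      down      ns         full recovery from acute downregulation
vi     ns        down       delayed downregulation
vii    down      down       |fc14| < |fc1|   (partial recovery)
viii   down      down       |fc14| >= |fc1|  (keeps decreasing)
====== ========= ========== =======================================

Sign-flipping genes (up then down, or down then up) are labelled
``discordant``; genes not significant at either day are ``unassigned``.
The ten labels partition the gene universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dge import DgeTable, rpkm
from .io import CountMatrix

MODULES = ("i", "ii", "iii", "iv", "v", "vi", "vii", "viii")
ALL_LABELS = MODULES + ("discordant", "unassigned")


def classify_trajectory(status_d1: str, status_d14: str,
                        log2fc_d1: float, log2fc_d14: float) -> str:
    """Decision table mapping the two statuses (+ magnitudes) to a label."""
    key = (status_d1, status_d14)
    if key == ("ns", "ns"):
        return "unassigned"
    if key == ("up", "up"):
        return "i" if abs(log2fc_d14) > abs(log2fc_d1) else "ii"
    if key == ("ns", "up"):
        return "iii"
    if key == ("up", "ns"):
        return "iv"
    if key == ("down", "ns"):
        return "v"
    if key == ("ns", "down"):
        return "vi"
    if key == ("down", "down"):
        return "vii" if abs(log2fc_d14) < abs(log2fc_d1) else "viii"
    if key in (("up", "down"), ("down", "up")):
        return "discordant"
    raise ValueError(f"invalid status pair {key!r}")


def assign_modules(
    dge_d1: DgeTable,
    dge_d14: DgeTable,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    cm: CountMatrix | None = None,
) -> pd.DataFrame:
    """Classify every gene; optionally attach baseline-anchored profiles.

    Returns a gene-indexed frame with status_d1, status_d14, module and,
    when ``cm`` is given, the (baseline, value_d1, value_d14) profile on
    the log2 RPKM scale.
    """
    from .dge import call_degs

    s1 = call_degs(dge_d1, alpha=alpha, use_adjusted=use_adjusted)
    s14 = call_degs(dge_d14, alpha=alpha, use_adjusted=use_adjusted)
    genes = dge_d1.table.index
    fc1 = dge_d1.table["log2fc"].fillna(0.0)
    fc14 = dge_d14.table["log2fc"].reindex(genes).fillna(0.0)
    s14 = s14.reindex(genes).fillna("ns")

    labels = [
        classify_trajectory(a, b, f1, f14)
        for a, b, f1, f14 in zip(s1, s14, fc1, fc14)
    ]
    out = pd.DataFrame(
        {"status_d1": s1.to_numpy(), "status_d14": s14.to_numpy(), "module": labels},
        index=genes,
    )
    if cm is not None:
        prof = trajectory_profiles(out, dge_d1, dge_d14, cm)
        out = out.join(prof)
    return out


def trajectory_profiles(
    assignments: pd.DataFrame,
    dge_d1: DgeTable,
    dge_d14: DgeTable,
    cm: CountMatrix,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Baseline-anchored log2 expression profiles.

    Baseline = mean log2 RPKM over sham day-14 samples (the recovered
    reference group); value at each day = baseline + model log2 fold
    change at that day.
    """
    if "length" not in cm.gene_meta.columns:
        raise ValueError("gene lengths required for RPKM profiles")
    sham14 = cm.samples_for(condition="sham", timepoint="day14")
    if not sham14:
        raise ValueError("no sham day-14 samples available for the baseline")
    rp = rpkm(cm)[sham14]
    baseline = np.log2(rp + pseudo).mean(axis=1)
    genes = assignments.index
    fc1 = dge_d1.table["log2fc"].reindex(genes).fillna(0.0)
    fc14 = dge_d14.table["log2fc"].reindex(genes).fillna(0.0)
    base = baseline.reindex(genes)
    return pd.DataFrame(
        {
            "baseline": base,
            "value_d1": base + fc1,
            "value_d14": base + fc14,
        },
        index=genes,
    )


def classify_de_table(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the DEG filter and classifier to a precomputed DE table.

    ``de`` is gene-indexed with columns ``log2fc_day1``, ``adj_p_day1``,
    ``log2fc_day14``, ``adj_p_day14`` (missing p treated as not
    significant).  Returns statuses plus the module label per gene —
    useful for re-deriving module counts from a published full DE table.
    """
    required = {"log2fc_day1", "adj_p_day1", "log2fc_day14", "adj_p_day14"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing column(s): {sorted(missing)}")

    def status(fc, p):
        sig = p.notna() & (p < alpha)
        return np.where(sig & (fc > 0), "up", np.where(sig & (fc < 0), "down", "ns"))

    s1 = status(de["log2fc_day1"], de["adj_p_day1"])
    s14 = status(de["log2fc_day14"], de["adj_p_day14"])
    fc1 = de["log2fc_day1"].fillna(0.0)
    fc14 = de["log2fc_day14"].fillna(0.0)
    labels = [
        classify_trajectory(a, b, f1, f14)
        for a, b, f1, f14 in zip(s1, s14, fc1, fc14)
    ]
    return pd.DataFrame(
        {"status_d1": s1, "status_d14": s14, "module": labels}, index=de.index
    )


def module_sizes(assignments: pd.DataFrame) -> pd.Series:
    sizes = assignments["module"].value_counts()
    return sizes.reindex(ALL_LABELS).fillna(0).astype(int)


def export_sankey(assignments: pd.DataFrame) -> pd.DataFrame:
    """Node/flow table for a two-column Sankey of status transitions.

    One row per populated module: source stratum at day 1, target
    stratum at day 14, module label and gene count.  Flow totals equal
    the number of assigned (non-``unassigned``) genes.
    """
    assigned = assignments[assignments["module"] != "unassigned"]
    flows = (
        assigned.groupby(["status_d1", "status_d14", "module"], observed=True)
        .size()
        .reset_index(name="n_genes")
    )
    flows["source"] = flows["status_d1"] + "@day1"
    flows["target"] = flows["status_d14"] + "@day14"
    return flows[["source", "target", "module", "n_genes"]].sort_values(
        "module", kind="mergesort"
    ).reset_index(drop=True)
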