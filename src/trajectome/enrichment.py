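"""Hypergeometric over-representation analysis against a GMT library."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dge import bh_adjust
from .io import GeneSetLibrary
from .trajectory import MODULES


class EnrichmentError(ValueError):
    pass


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def storey_q(pvalues: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed lambda (no smoother).

    pi0 = min(1, #{p > lambda} / (m * (1 - lambda))); q = pi0 * BH.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam)) if m else 1.0
    pi0 = max(pi0, 1.0 / m)  # guard against zero when all p are tiny
    return np.minimum(pi0 * bh_adjust(p), 1.0)


def hypergeom_ora(
    query: set[str],
    universe: set[str],
    lib: GeneSetLibrary,
    min_set: int = 10,
    max_set: int = 500,
) -> pd.DataFrame:
    """One-sided over-representation test of ``query`` against each term.

    Terms are restricted to the universe before the size filter; BH and
    Storey q are computed across the tested term family.  Rows sorted by
    ascending p (ties by term id for determinism).
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise EnrichmentError(
            f"query genes outside the universe: {sorted(stray)[:10]}"
        )
    if not len(lib):
        raise EnrichmentError("empty gene-set library")
    N, n = len(universe), len(query)
    rows = []
    for tid, (desc, genes) in lib.terms.items():
        in_universe = genes & universe
        K = len(in_universe)
        if not (min_set <= K <= max_set):
            continue
        k = len(in_universe & query)
        rows.append((tid, desc, k, K, n, N, hypergeom_pvalue(k, N, K, n)))
    df = pd.DataFrame(
        rows, columns=["term_id", "description", "k", "K", "n", "N", "p"]
    )
    if len(df):
        df["adj_p"] = bh_adjust(df["p"].to_numpy())
        df["q"] = storey_q(df["p"].to_numpy())
        df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["adj_p"] = pd.Series(dtype=float)
        df["q"] = pd.Series(dtype=float)
    return df


def enrich_modules(
    assignments: pd.DataFrame,
    lib: GeneSetLibrary,
    universe: set[str] | None = None,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
    min_set: int = 10,
    max_set: int = 500,
) -> dict[str, pd.DataFrame]:
    """Per-module ORA; rows retained iff adj_p <= p_cut and q <= q_cut.

    The universe defaults to every gene in the assignment table (i.e.
    all genes tested for DE).  Modules with no genes yield empty tables,
    as do modules with no passing terms.
    """
    if universe is None:
        universe = set(assignments.index)
    results: dict[str, pd.DataFrame] = {}
    for mod in MODULES:
        genes = set(assignments.index[assignments["module"] == mod]) & universe
        if not genes:
            results[mod] = pd.DataFrame(
                columns=["term_id", "description", "k", "K", "n", "N", "p", "adj_p", "q"]
            )
            continue
        tbl = hypergeom_ora(genes, universe, lib, min_set=min_set, max_set=max_set)
        results[mod] = tbl[(tbl["adj_p"] <= p_cut) & (tbl["q"] <= q_cut)].reset_index(
            drop=True
        )
    return results


def summary_matrix(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """term x module matrix of p-values for passing terms (dot-plot layout)."""
    cells = {}
    for mod, tbl in results.items():
        for r in tbl.itertuples(index=False):
            cells.setdefault(r.term_id, {})[mod] = r.p
    out = pd.DataFrame.from_dict(cells, orient="index")
    return out.reindex(columns=[m for m in MODULES if m in out.columns]).sort_index()
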