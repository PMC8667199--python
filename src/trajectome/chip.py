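"""Promoter H3K4me3 quantification and differential scoring from pileups.

Pipeline per timepoint: mean pileup coverage in a strand-agnostic
window centred on each TSS -> depth normalization to signal-per-million
-> within-sample fractional ranks (sensitivity compensation) -> signed
Poisson log10 likelihood-ratio score between the condition means ->
strong-enrichment flag and top-k selection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import PileupTrack

DEFAULT_FLANK = 1000
DEFAULT_PSEUDO = 1.0


class ChipError(ValueError):
    pass


def promoter_windows(gene_meta: pd.DataFrame, flank: int = DEFAULT_FLANK) -> pd.DataFrame:
    """[TSS - flank, TSS + flank) half-open windows, clipped at 0."""
    if flank <= 0:
        raise ChipError("flank must be positive")
    tss = gene_meta["tss"].astype(int)
    return pd.DataFrame(
        {
            "chrom": gene_meta["chrom"],
            "start": np.maximum(tss - flank, 0),
            "end": tss + flank,
        },
        index=gene_meta.index,
    )


def promoter_coverage(
    track: PileupTrack, gene_meta: pd.DataFrame, flank: int = DEFAULT_FLANK
) -> pd.Series:
    """Mean pileup coverage over each gene's promoter window.

    mean = sum(value * overlap_length) / window_length.  Genes on
    chromosomes absent from the track get 0 (counted in a warning).
    """
    windows = promoter_windows(gene_meta, flank)
    cov = pd.Series(0.0, index=gene_meta.index, name=track.label)
    iv = track.intervals
    missing_chrom = 0
    by_chrom = {c: g for c, g in iv.groupby("chrom", observed=True)} if len(iv) else {}
    for chrom, wgrp in windows.groupby("chrom", observed=True):
        sub = by_chrom.get(chrom)
        if sub is None:
            missing_chrom += len(wgrp)
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["value"].to_numpy()
        # cumulative signal up to each interval start lets one window be
        # resolved with two searchsorted lookups
        cum = np.concatenate([[0.0], np.cumsum((ends - starts) * vals)])
        for gene, w in zip(wgrp.index, wgrp.itertuples(index=False)):
            lo = np.searchsorted(ends, w.start, side="right")
            hi = np.searchsorted(starts, w.end, side="left")
            if lo >= hi:
                continue
            total = cum[hi] - cum[lo]
            # trim partial overlap at both edges
            total -= max(0, w.start - starts[lo]) * vals[lo]
            total -= max(0, ends[hi - 1] - w.end) * vals[hi - 1]
            cov[gene] = total / (w.end - w.start)
    if missing_chrom:
        warnings.warn(
            f"{missing_chrom} promoter(s) on chromosomes absent from "
            f"track {track.label!r}; coverage set to 0",
            stacklevel=2,
        )
    return cov


def depth_normalize(cov_table: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    """Scale each sample's coverages to signal-per-million total pileup."""
    totals = totals.reindex(cov_table.columns)
    if totals.isna().any() or (totals <= 0).any():
        bad = totals.index[(totals.isna() | (totals <= 0)).to_numpy()][0]
        raise ChipError(f"sample {bad!r} has missing or non-positive total signal")
    return cov_table * (1e6 / totals)


def rank_promoters(cov_table: pd.DataFrame) -> pd.DataFrame:
    """Ascending fractional ranks within each sample, ties averaged."""
    if len(cov_table) < 2:
        raise ChipError("need at least 2 promoters to rank")
    return cov_table.rank(axis=0, method="average")


def diff_loglr(c_tbi, c_sham, pseudo: float = DEFAULT_PSEUDO):
    """Signed log10 Poisson likelihood ratio of separate vs common mean.

    With x = c_tbi + pseudo, y = c_sham + pseudo and m = (x + y)/2:

        score = sign(x - y) * (x ln(x/m) + y ln(y/m)) / ln 10

    which is the log10 ratio of the likelihood of two distinct Poisson
    means against one common mean.  Antisymmetric in its arguments and
    zero at equality.
    """
    x = np.asarray(c_tbi, dtype=float)
    y = np.asarray(c_sham, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ChipError("coverages must be non-negative")
    x = x + pseudo
    y = y + pseudo
    m = (x + y) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / m), 0.0)
        ll = ll + np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / m), 0.0)
    score = np.sign(x - y) * ll / np.log(10.0)
    if np.isscalar(c_tbi) and np.isscalar(c_sham):
        return float(score)
    return score


def score_promoters(
    tracks: dict[str, PileupTrack],
    sample_meta: pd.DataFrame,
    gene_meta: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    pseudo: float = DEFAULT_PSEUDO,
    timepoint: str | None = None,
    input_tracks: dict[str, PileupTrack] | None = None,
    subtract_input: bool = False,
) -> pd.DataFrame:
    """Full promoter scoring table for one timepoint.

    ``tracks`` maps sample id -> ChIP pileup; ``sample_meta`` must carry
    a ``condition`` column (and ``timepoint`` if filtering is wanted).
    Per-condition coverages are averaged after depth normalization, then
    scored with :func:`diff_loglr`.  Optionally subtracts a matched
    input-control pileup (floored at 0) before normalization.
    """
    meta = sample_meta
    if timepoint is not None:
        meta = meta[meta["timepoint"] == timepoint]
    samples = [s for s in meta.index if s in tracks]
    if not samples:
        raise ChipError("no ChIP tracks match the sample sheet")
    meta = meta.loc[samples]

    cov = {}
    totals = {}
    for s in samples:
        track = tracks[s]
        c = promoter_coverage(track, gene_meta, flank)
        if subtract_input:
            if not input_tracks or s not in input_tracks:
                raise ChipError(f"input track missing for sample {s!r}")
            c = (c - promoter_coverage(input_tracks[s], gene_meta, flank)).clip(lower=0.0)
        cov[s] = c
        totals[s] = track.total_signal
    cov_table = pd.DataFrame(cov)
    norm = depth_normalize(cov_table, pd.Series(totals))
    ranks = rank_promoters(norm)

    tbi_samples = list(meta.index[meta["condition"] == "injury"])
    sham_samples = list(meta.index[meta["condition"] == "sham"])
    if not tbi_samples or not sham_samples:
        raise ChipError("both injury and sham ChIP samples are required")
    c_tbi = norm[tbi_samples].mean(axis=1)
    c_sham = norm[sham_samples].mean(axis=1)
    score = diff_loglr(c_tbi.to_numpy(), c_sham.to_numpy(), pseudo=pseudo)
    # mean fractional rank per condition, rescaled to [0, 1]
    nprom = len(norm)
    rank_tbi = ranks[tbi_samples].mean(axis=1) / nprom
    rank_sham = ranks[sham_samples].mean(axis=1) / nprom

    windows = promoter_windows(gene_meta, flank)
    out = pd.DataFrame(
        {
            "chrom": windows["chrom"],
            "start": windows["start"],
            "end": windows["end"],
            "cov_tbi": c_tbi,
            "cov_sham": c_sham,
            "rank_tbi": rank_tbi,
            "rank_sham": rank_sham,
            "score": score,
        },
        index=gene_meta.index,
    )
    for s in samples:
        out[f"cov_{s}"] = norm[s]
    return out


def flag_strong_enrichment(
    table: pd.DataFrame,
    sham_max_quantile: float = 0.2,
    tbi_min_quantile: float = 0.8,
) -> pd.Series:
    """Flag promoters low/undetectable in sham but high in injury.

    Flag iff sham rank <= ``sham_max_quantile`` and injury rank >=
    ``tbi_min_quantile`` (rank fractions of the scored promoters).
    """
    for q in (sham_max_quantile, tbi_min_quantile):
        if not (0.0 < q < 1.0):
            raise ChipError(f"quantile {q} outside (0, 1)")
    flag = (table["rank_sham"] <= sham_max_quantile) & (
        table["rank_tbi"] >= tbi_min_quantile
    )
    return flag.rename("strong_flag")


def select_top_k(table: pd.DataFrame, k: int = 100) -> tuple[list[str], list[str]]:
    """Top-k up and down gene lists ranked by |score|, ties by gene id."""
    if k < 0:
        raise ChipError("k must be non-negative")
    # pre-sort by gene id so the stable sort breaks score ties lexicographically
    pos = table[table["score"] > 0].sort_index().sort_values(
        "score", ascending=False, kind="mergesort"
    )
    neg = table[table["score"] < 0].sort_index().sort_values(
        "score", kind="mergesort"
    )
    if len(pos) < k or len(neg) < k:
        warnings.warn(
            f"fewer than k={k} genes of one sign "
            f"(up={len(pos)}, down={len(neg)}); returning all",
            stacklevel=2,
        )
    return list(pos.index[:k]), list(neg.index[:k])
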