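"""Readers and writers for the external formats the pipeline consumes.

All genomic coordinates are 0-based half-open internally (BED/bedGraph
convention).  GTF input (1-based closed) is converted at the reader
boundary: for a ``+`` gene the TSS is ``start - 1``; for a ``-`` gene it
is ``end - 1``.

Every reader validates strictly and raises :class:`FormatError` with the
offending location rather than coercing silently.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("injury", "sham")
TIMEPOINTS = ("day1", "day14")


class FormatError(ValueError):
    """Malformed external input (bad value, bad coordinates, bad schema)."""


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x sample counts with sample and gene metadata.

    Attributes
    ----------
    counts:
        DataFrame of non-negative integers, index = gene ids, columns =
        sample ids (same order as ``sample_meta``).
    sample_meta:
        DataFrame indexed by sample id with columns ``condition``
        (``injury``/``sham``), ``timepoint`` (``day1``/``day14``) and
        ``batch``.
    gene_meta:
        DataFrame indexed by gene id with columns ``chrom``, ``tss``
        (0-based), ``strand`` (``+``/``-``) and ``length`` (bp, >= 1).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        self.counts.index.name = "gene"
        self.counts.columns.name = None
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id in counts: {dup!r}")
        if list(self.counts.columns) != list(self.sample_meta.index):
            missing = set(self.counts.columns) - set(self.sample_meta.index)
            if missing:
                raise FormatError(
                    f"samples missing from metadata: {sorted(missing)}"
                )
            raise FormatError("sample order mismatch between counts and metadata")
        if list(self.counts.index) != list(self.gene_meta.index):
            missing = set(self.counts.index) - set(self.gene_meta.index)
            if missing:
                raise FormatError(f"genes missing from gene sheet: {sorted(missing)}")
            raise FormatError("gene order mismatch between counts and gene sheet")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # locate first non-integer cell for a useful message
            frac = arr.astype(float) != np.floor(arr.astype(float))
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise FormatError(
                    f"non-integer count {arr[i, j]!r} at gene "
                    f"{self.counts.index[i]!r}, sample {self.counts.columns[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        for col in ("condition", "timepoint"):
            if col not in self.sample_meta.columns:
                raise FormatError(f"sample sheet missing column {col!r}")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition label(s): {sorted(bad)}")
        bad = set(self.sample_meta["timepoint"]) - set(TIMEPOINTS)
        if bad:
            raise FormatError(f"unknown timepoint label(s): {sorted(bad)}")
        if "batch" not in self.sample_meta.columns:
            self.sample_meta = self.sample_meta.assign(batch="b0")
        if "length" in self.gene_meta.columns:
            lengths = pd.to_numeric(self.gene_meta["length"])
            if (lengths < 1).any():
                g = self.gene_meta.index[np.argmax(lengths.to_numpy() < 1)]
                raise FormatError(f"gene {g!r} has length < 1")

    # -- convenience --------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_for(self, condition: str | None = None, timepoint: str | None = None) -> list[str]:
        m = pd.Series(True, index=self.sample_meta.index)
        if condition is not None:
            m &= self.sample_meta["condition"] == condition
        if timepoint is not None:
            m &= self.sample_meta["timepoint"] == timepoint
        return list(self.sample_meta.index[m])

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[samples].copy(),
            sample_meta=self.sample_meta.loc[samples].copy(),
            gene_meta=self.gene_meta.copy(),
        )


def read_count_matrix(path_counts, path_samples, path_genes) -> CountMatrix:
    """Load counts TSV + sample sheet + gene sheet into a :class:`CountMatrix`.

    The counts file has genes as rows and samples as columns, first
    column = gene id (featureCounts-style export).
    """
    counts = pd.read_csv(path_counts, sep="\t", index_col=0, comment="#")
    # detect non-integer cells before casting
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        flt = arr.astype(float)
        frac = flt != np.floor(flt)
        if frac.any():
            i, j = np.argwhere(frac)[0]
            raise FormatError(
                f"non-integer count {arr[i, j]!r} at gene "
                f"{counts.index[i]!r}, sample {counts.columns[j]!r} in {path_counts}"
            )
        counts = counts.astype(np.int64)
    samples = pd.read_csv(path_samples, sep="\t", index_col=0, comment="#", dtype=str)
    genes = pd.read_csv(path_genes, sep="\t", index_col=0, comment="#")
    missing = set(counts.columns) - set(samples.index)
    if missing:
        raise FormatError(f"samples missing from {path_samples}: {sorted(missing)}")
    samples = samples.loc[list(counts.columns)]
    missing = set(counts.index) - set(genes.index)
    if missing:
        raise FormatError(f"genes missing from {path_genes}: {sorted(missing)[:5]}")
    genes = genes.loc[list(counts.index)]
    return CountMatrix(counts=counts, sample_meta=samples, gene_meta=genes)


def write_count_matrix(cm: CountMatrix, path_counts, path_samples, path_genes) -> None:
    cm.counts.to_csv(path_counts, sep="\t", index_label="gene")
    cm.sample_meta.to_csv(path_samples, sep="\t", index_label="sample")
    cm.gene_meta.to_csv(path_genes, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Pileup tracks (bedGraph)
# ---------------------------------------------------------------------------


@dataclass
class PileupTrack:
    """Interval-run-length genome coverage, 0-based half-open.

    ``intervals`` is a DataFrame with columns chrom/start/end/value,
    sorted by (chrom, start); intervals within one chrom never overlap.
    """

    intervals: pd.DataFrame
    label: str = ""
    assay: str = "chip"
    total_signal: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        iv = self.intervals.reset_index(drop=True)
        if len(iv):
            iv = iv.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
            bad = iv["start"] >= iv["end"]
            if bad.any():
                r = iv[bad].iloc[0]
                raise FormatError(
                    f"empty/inverted interval {r.chrom}:{r.start}-{r.end}"
                )
            if (iv["value"] < 0).any():
                r = iv[iv["value"] < 0].iloc[0]
                raise FormatError(
                    f"negative coverage {r.value} at {r.chrom}:{r.start}-{r.end}"
                )
            same = iv["chrom"].to_numpy()[1:] == iv["chrom"].to_numpy()[:-1]
            overlap = same & (iv["start"].to_numpy()[1:] < iv["end"].to_numpy()[:-1])
            if overlap.any():
                k = int(np.argmax(overlap)) + 1
                r = iv.iloc[k]
                raise FormatError(
                    f"overlapping intervals on {r.chrom} near position {r.start}"
                )
        self.intervals = iv
        recomputed = self.recompute_total()
        if self.total_signal is None:
            self.total_signal = recomputed
        elif not np.isclose(self.total_signal, recomputed, rtol=1e-6, atol=1e-9):
            raise FormatError(
                f"total_signal {self.total_signal} != recomputed {recomputed}"
            )

    def recompute_total(self) -> float:
        if not len(self.intervals):
            return 0.0
        iv = self.intervals
        return float(((iv["end"] - iv["start"]) * iv["value"]).sum())

    def scaled(self, factor: float) -> "PileupTrack":
        iv = self.intervals.copy()
        iv["value"] = iv["value"] * factor
        return PileupTrack(intervals=iv, label=self.label, assay=self.assay)


def read_bedgraph(path, label: str = "", assay: str = "chip") -> PileupTrack:
    """Parse a 4-column bedGraph; ``track``/``browser``/``#`` lines are skipped."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            values.append(value)
    iv = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "value": values})
    if not label:
        label = str(path)
    try:
        return PileupTrack(intervals=iv, label=label, assay=assay)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: PileupTrack, path) -> None:
    with open(path, "w") as fh:
        for r in track.intervals.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.value:g}\n")


# ---------------------------------------------------------------------------
# Gene-set library (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetLibrary:
    """Mapping term id -> (description, gene set); insertion-ordered."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise FormatError(f"gene set {tid!r} is empty")

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def description(self, term_id: str) -> str:
        return self.terms[term_id][0]


def read_gmt(path) -> GeneSetLibrary:
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            tid, desc = parts[0], parts[1]
            if tid in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term id {tid!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {tid!r} has no genes")
            terms[tid] = (desc, genes)
    return GeneSetLibrary(terms=terms)


def write_gmt(lib: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for tid, (desc, genes) in lib.terms.items():
            fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def read_gene_annotation(path) -> pd.DataFrame:
    """BED-like TSV gene sheet: gene, chrom, tss (0-based), strand, length."""
    genes = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    for col in ("chrom", "tss", "strand", "length"):
        if col not in genes.columns:
            raise FormatError(f"{path}: gene sheet missing column {col!r}")
    bad = set(genes["strand"]) - {"+", "-"}
    if bad:
        raise FormatError(f"{path}: bad strand value(s) {sorted(bad)}")
    if not genes.index.is_unique:
        dup = genes.index[genes.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return genes


def read_gtf_genes(path) -> pd.DataFrame:
    """Extract gene records from a GTF; converts 1-based closed to 0-based.

    TSS = start - 1 for ``+`` genes and end - 1 for ``-`` genes; length is
    the genomic span.  Requires a ``gene_id`` attribute.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: GTF line has < 9 fields")
            if parts[2] != "gene":
                continue
            chrom, start1, end1, strand, attrs = (
                parts[0], int(parts[3]), int(parts[4]), parts[6], parts[8],
            )
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene record lacks gene_id")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            start0 = start1 - 1  # 1-based closed -> 0-based half-open
            tss = start0 if strand == "+" else end1 - 1
            rows.append((gene_id, chrom, tss, strand, end1 - start0))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand", "length"])
    df = df.set_index("gene")
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    return df


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, params: dict | None = None, index_label="gene") -> None:
    """Write a TSV with a commented provenance header line."""
    from . import __version__

    items = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    buf = _stdio.StringIO()
    df.to_csv(buf, sep="\t", index_label=index_label)
    with open(path, "w") as fh:
        fh.write(f"# trajectome {__version__} {items}".rstrip() + "\n")
        fh.write(buf.getvalue())
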