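"""Synthetic count matrices and promoter pileups with known ground truth.

RNA counts are negative binomial with per-gene trajectory-module effects
(injury vs sham, per timepoint), an optional per-batch offset and
log-normal library-size factors.  Promoter pileup coverage is generated
proportional to an expression-correlated baseline times a per-timepoint
condition shift and a per-sample sensitivity factor, with Poisson noise.

Ground truth (:class:`SimTruth`) is returned alongside the data and is
never consumed by any analysis stage — only by test harnesses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, PileupTrack
from .trajectory import MODULES

# (day-1, day-14) effect multiples of effect_scale, per module; signs and
# magnitude orderings are consistent with the trajectory classifier
MODULE_EFFECT_PATTERN: dict[str, tuple[float, float]] = {
    "i": (1.0, 2.0),
    "ii": (2.0, 1.0),
    "iii": (0.0, 1.0),
    "iv": (1.0, 0.0),
    "v": (-1.0, 0.0),
    "vi": (0.0, -1.0),
    "vii": (-2.0, -1.0),
    "viii": (-1.0, -2.0),
}

DEFAULT_GROUP_SIZES = {
    ("sham", "day1"): 2,
    ("injury", "day1"): 4,
    ("sham", "day14"): 2,
    ("injury", "day14"): 4,
}


class SimulationError(ValueError):
    pass


@dataclass
class SimTruth:
    """Per-gene ground truth for a simulated dataset."""

    table: pd.DataFrame  # true_module, effect_day1, effect_day14, base_mean,
    #                      dispersion, chip_shift_day1, chip_shift_day14

    def genes_in_module(self, module: str) -> list[str]:
        return list(self.table.index[self.table["true_module"] == module])


def _make_gene_meta(n_genes: int, rng: np.random.Generator,
                    spacing: int = 5000) -> pd.DataFrame:
    ids = [f"g{i:05d}" for i in range(n_genes)]
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "tss": 10_000 + spacing * np.arange(n_genes),
            "strand": np.where(np.arange(n_genes) % 2 == 0, "+", "-"),
            "length": rng.integers(500, 5000, size=n_genes),
        },
        index=pd.Index(ids, name="gene"),
    )


def simulate_counts(
    n_genes: int,
    group_sizes: dict[tuple[str, str], int] | None = None,
    module_fractions: dict[str, float] | None = None,
    effect_scale: float = 2.0,
    batch_sd: float = 0.0,
    seed: int | None = None,
    base_mean_range: tuple[float, float] = (20.0, 2000.0),
    dispersion_range: tuple[float, float] = (0.02, 0.2),
    libsize_sd: float = 0.2,
    chip_shift: dict[str, tuple[float, float]] | None = None,
    batch_per_timepoint: bool = True,
) -> tuple[CountMatrix, SimTruth]:
    """Draw a two-condition, two-timepoint NB count matrix plus truth.

    Parameters
    ----------
    group_sizes:
        (condition, timepoint) -> replicate count; every cell needs >= 2.
        Defaults to the 2-sham/4-injury design per timepoint.
    module_fractions:
        trajectory module -> fraction of genes carrying that effect
        pattern; must sum to <= 1 (remainder are null genes).
    effect_scale:
        base |log2 fold change|; magnitude-split modules use 2x this.
    batch_sd:
        SD of per-gene, per-batch log2 offsets (0 disables).
    chip_shift:
        module -> (day-1, day-14) multiplicative promoter-coverage
        factors stored in the truth table for the pileup simulator.
    """
    if seed is None:
        raise SimulationError("an explicit seed is required")
    if n_genes < 1:
        raise SimulationError("n_genes must be positive")
    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    module_fractions = dict(module_fractions or {})
    bad = set(module_fractions) - set(MODULES)
    if bad:
        raise SimulationError(f"unknown module label(s): {sorted(bad)}")
    total_frac = sum(module_fractions.values())
    if total_frac > 1.0 + 1e-9:
        raise SimulationError(f"module fractions sum to {total_frac} > 1")
    for key, size in group_sizes.items():
        if size < 2:
            raise SimulationError(f"group {key} needs >= 2 samples, got {size}")

    rng = np.random.default_rng(seed)
    gene_meta = _make_gene_meta(n_genes, rng)
    genes = gene_meta.index

    # module labels: counts per module, then a seeded shuffle over genes
    labels = np.array(["null"] * n_genes, dtype=object)
    pos = 0
    for mod in MODULES:
        n_mod = int(round(module_fractions.get(mod, 0.0) * n_genes))
        labels[pos:pos + n_mod] = mod
        pos += n_mod
    rng.shuffle(labels)

    lo, hi = base_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    dlo, dhi = dispersion_range
    dispersion = rng.uniform(dlo, dhi, size=n_genes)

    eff1 = np.zeros(n_genes)
    eff14 = np.zeros(n_genes)
    shift1 = np.ones(n_genes)
    shift14 = np.ones(n_genes)
    for mod, (m1, m14) in MODULE_EFFECT_PATTERN.items():
        mask = labels == mod
        eff1[mask] = m1 * effect_scale
        eff14[mask] = m14 * effect_scale
        if chip_shift and mod in chip_shift:
            s1, s14 = chip_shift[mod]
            shift1[mask] = s1
            shift14[mask] = s14

    # sample sheet
    sample_rows = []
    for (cond, tp), size in sorted(group_sizes.items()):
        for r in range(size):
            sid = f"{'tbi' if cond == 'injury' else 'sham'}_{tp}_r{r + 1}"
            batch = f"batch_{tp}" if batch_per_timepoint else "batch_0"
            sample_rows.append((sid, cond, tp, batch))
    sample_meta = pd.DataFrame(
        sample_rows, columns=["sample", "condition", "timepoint", "batch"]
    ).set_index("sample")

    batches = sorted(sample_meta["batch"].unique())
    batch_offsets = {
        b: (rng.normal(0.0, batch_sd, size=n_genes) if batch_sd > 0 else np.zeros(n_genes))
        for b in batches
    }
    lib_factors = np.exp(rng.normal(0.0, libsize_sd, size=len(sample_meta)))

    counts = np.empty((n_genes, len(sample_meta)), dtype=np.int64)
    for j, (sid, row) in enumerate(sample_meta.iterrows()):
        eff = eff1 if row["timepoint"] == "day1" else eff14
        log2_effect = eff if row["condition"] == "injury" else 0.0
        mu = base_mean * 2.0 ** (log2_effect + batch_offsets[row["batch"]]) * lib_factors[j]
        nb_n = 1.0 / dispersion
        nb_p = nb_n / (nb_n + mu)
        counts[:, j] = rng.negative_binomial(nb_n, nb_p)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_meta.index),
        sample_meta=sample_meta,
        gene_meta=gene_meta,
    )
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "true_module": labels,
                "effect_day1": eff1,
                "effect_day14": eff14,
                "base_mean": base_mean,
                "dispersion": dispersion,
                "chip_shift_day1": shift1,
                "chip_shift_day14": shift14,
            },
            index=genes,
        )
    )
    return cm, truth


def simulate_pileups(
    truth: SimTruth,
    gene_meta: pd.DataFrame,
    chip_samples: pd.DataFrame,
    depth: float = 5.0,
    sensitivity: dict[str, float] | None = None,
    noise: float = 1.0,
    seed: int | None = None,
    flank_sim: int = 1500,
    bg_rate: float = 0.05,
) -> dict[str, PileupTrack]:
    """Generate one promoter-centred pileup track per ChIP sample.

    Each gene's promoter block [TSS - flank_sim, TSS + flank_sim) gets
    coverage depth * log2(1 + base_mean) * chip_shift(timepoint, if
    injury) * sensitivity, with Poisson noise at granularity ``noise``
    (0 = deterministic); the inter-promoter background is a constant
    low rate scaled by the same sensitivity.

    ``chip_samples`` is a frame indexed by sample id with ``condition``
    and ``timepoint`` columns.
    """
    if seed is None:
        raise SimulationError("an explicit seed is required")
    sensitivity = sensitivity or {}
    for s, f in sensitivity.items():
        if f <= 0:
            raise SimulationError(f"sensitivity for {s!r} must be > 0")
    if noise < 0:
        raise SimulationError("noise must be >= 0")

    rng = np.random.default_rng(seed)
    tt = truth.table.reindex(gene_meta.index)
    baseline = depth * np.log2(1.0 + tt["base_mean"].to_numpy())

    tracks: dict[str, PileupTrack] = {}
    for sid, row in chip_samples.iterrows():
        sens = float(sensitivity.get(sid, 1.0))
        shift_col = "chip_shift_day1" if row["timepoint"] == "day1" else "chip_shift_day14"
        shift = tt[shift_col].to_numpy() if row["condition"] == "injury" else 1.0
        mean_cov = baseline * shift * sens
        if noise > 0:
            cov = rng.poisson(mean_cov / noise) * noise
        else:
            cov = mean_cov.copy()
        bg = depth * bg_rate * sens

        chroms, starts, ends, values = [], [], [], []
        order = gene_meta.sort_values(["chrom", "tss"], kind="mergesort")
        cov_s = pd.Series(cov, index=gene_meta.index)
        for chrom, grp in order.groupby("chrom", observed=True):
            cursor = 0
            for gene, g in grp.iterrows():
                w_start = max(int(g["tss"]) - flank_sim, 0)
                w_end = int(g["tss"]) + flank_sim
                if w_start < cursor:
                    raise SimulationError(
                        f"promoter windows overlap near {chrom}:{w_start}; "
                        "increase gene spacing or reduce flank_sim"
                    )
                if bg > 0 and w_start > cursor:
                    chroms.append(chrom)
                    starts.append(cursor)
                    ends.append(w_start)
                    values.append(bg)
                v = float(cov_s[gene])
                if v > 0:
                    chroms.append(chrom)
                    starts.append(w_start)
                    ends.append(w_end)
                    values.append(v)
                cursor = w_end
            if bg > 0:
                chroms.append(chrom)
                starts.append(cursor)
                ends.append(cursor + 10_000)
                values.append(bg)
        iv = pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": ends, "value": values}
        )
        tracks[sid] = PileupTrack(intervals=iv, label=sid, assay="chip")
    return tracks


def default_chip_samples(timepoint: str = "day1") -> pd.DataFrame:
    """One pooled ChIP track per condition at the given timepoint."""
    rows = [
        (f"chip_tbi_{timepoint}", "injury", timepoint),
        (f"chip_sham_{timepoint}", "sham", timepoint),
    ]
    return pd.DataFrame(
        rows, columns=["sample", "condition", "timepoint"]
    ).set_index("sample")
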