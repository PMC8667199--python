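"""Per-timepoint moderated differential expression (injury vs sham).

The model is a precision-weighted gene-wise linear model on log2 CPM:

1. low-expression filter (CPM > ``cpm_threshold`` in at least the
   smallest group's worth of samples);
2. gene-wise ordinary least squares on log-CPM to estimate the
   mean-variance trend: lowess of sqrt(residual SD) against mean log
   count, inverted into per-observation precision weights;
3. weighted least squares per gene;
4. empirical-Bayes shrinkage of residual variances toward a fitted
   scaled inverse chi-square prior (moment matching on log variances);
5. moderated t statistics on the augmented degrees of freedom, BH
   adjustment across all unfiltered genes at the timepoint.

The stage is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix


class DgeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (composition bias).

    The reference sample is the one whose 75th count percentile is
    closest to the column mean of those percentiles.  Factors are scaled
    to have unit geometric mean; effective library size = libsize * factor.
    """
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        raise DgeError("zero library size")
    uq = np.array([
        np.percentile(arr[:, j][arr[:, j] > 0], 75) / lib[j] if (arr[:, j] > 0).any() else 0
        for j in range(arr.shape[1])
    ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    r, nr = arr[:, ref], lib[ref]
    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref:
            continue
        x, nx = arr[:, j], lib[j]
        ok = (x > 0) & (r > 0)
        if ok.sum() < 10:
            continue
        m = np.log2((x[ok] / nx) / (r[ok] / nr))
        a = 0.5 * np.log2((x[ok] / nx) * (r[ok] / nr))
        w = (nx - x[ok]) / (nx * x[ok]) + (nr - r[ok]) / (nr * r[ok])
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            factors[j] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_logcpm(
    cm: CountMatrix, prior_count: float = 0.5, lib_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    value = log2((count + prior) / (libsize + 2 * prior) * 1e6)

    ``lib_sizes`` overrides the raw column sums (e.g. TMM-effective
    library sizes).
    """
    if lib_sizes is None:
        lib = cm.library_sizes().to_numpy(dtype=float)
    else:
        lib = lib_sizes.reindex(cm.counts.columns).to_numpy(dtype=float)
    if (lib <= 0).any() or np.isnan(lib).any():
        bad = cm.counts.columns[np.argmax((lib <= 0) | np.isnan(lib))]
        raise DgeError(f"sample {bad!r} has zero library size")
    arr = cm.counts.to_numpy(dtype=float)
    vals = np.log2((arr + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads."""
    lib = cm.library_sizes().to_numpy(dtype=float)
    lengths = cm.gene_meta["length"].to_numpy(dtype=float)
    arr = cm.counts.to_numpy(dtype=float)
    vals = arr / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise DgeError("bh_adjust expects a 1-D vector")
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise DgeError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on trigamma(y) = x; standard initialization
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink sample variances toward a fitted global prior.

    Fits a scaled F/inverse-chi-square prior to the distribution of
    log variances via moment matching (mean and variance of
    ``log s2`` corrected by digamma/trigamma terms), then returns the
    posterior variances ``(d0*s0 + d*s2)/(d0 + d)`` along with the prior
    df and prior variance.  ``df`` is the residual df shared by genes.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = float(np.exp(
            emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        ))
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
    if np.isfinite(df_prior):
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
    else:
        s2_post = np.full_like(s2, s2_prior)
    return s2_post, df_prior, s2_prior


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


@dataclass
class DgeTable:
    """Per-gene DE results for one timepoint."""

    table: pd.DataFrame  # gene-indexed: log2fc, mean_logexpr, stat, p, adj_p, filtered
    timepoint: str
    params: dict

    def unfiltered(self) -> pd.DataFrame:
        return self.table[~self.table["filtered"]]


def _batched_lstsq(X: np.ndarray, Y: np.ndarray, W: np.ndarray | None):
    """Per-gene (weighted) least squares for a shared design matrix.

    X is (n, p); Y is (G, n); W is (G, n) weights or None.  Returns
    (beta (G, p), resid_var (G,), cov_unscaled (G, p, p) diagonal-needed).
    """
    n, p = X.shape
    if W is None:
        XtX = X.T @ X
        XtXinv = np.linalg.inv(XtX)
        beta = Y @ X @ XtXinv.T
        fitted = beta @ X.T
        resid = Y - fitted
        rss = np.einsum("gn,gn->g", resid, resid)
        cov_unscaled = np.broadcast_to(XtXinv, (Y.shape[0], p, p))
        return beta, rss / (n - p), cov_unscaled, fitted
    A = np.einsum("ni,gn,nj->gij", X, W, X)
    b = np.einsum("ni,gn,gn->gi", X, W, Y)
    beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    fitted = beta @ X.T
    resid = Y - fitted
    rss = np.einsum("gn,gn,gn->g", W, resid, resid)
    cov_unscaled = np.linalg.inv(A)
    return beta, rss / (n - p), cov_unscaled, fitted


def _build_design(meta: pd.DataFrame, include_batch: bool) -> tuple[np.ndarray, int]:
    cond = (meta["condition"] == "injury").to_numpy(dtype=float)
    cols = [np.ones(len(meta)), cond]
    if include_batch:
        batches = sorted(meta["batch"].unique())
        if len(batches) >= 2:
            for b in batches[1:]:
                cols.append((meta["batch"] == b).to_numpy(dtype=float))
        else:
            warnings.warn(
                "only one batch present within timepoint; batch covariate dropped",
                stacklevel=3,
            )
    X = np.column_stack(cols)
    return X, 1  # index of the condition coefficient


def expression_filter(
    cm: CountMatrix, cpm_threshold: float = 1.0, min_samples: int | None = None
) -> pd.Series:
    """Keep genes with CPM > threshold in at least ``min_samples`` samples.

    ``min_samples`` defaults to the smallest (condition, timepoint) group
    size in the matrix.
    """
    if min_samples is None:
        min_samples = int(
            cm.sample_meta.groupby(["condition", "timepoint"], observed=True).size().min()
        )
    lib = cm.library_sizes().to_numpy(dtype=float)
    cpm = cm.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    keep = (cpm > cpm_threshold).sum(axis=1) >= min_samples
    return pd.Series(keep, index=cm.counts.index, name="keep")


def fit_moderated_de(
    cm: CountMatrix,
    timepoint: str,
    include_batch: bool = True,
    prior_count: float = 0.5,
    cpm_threshold: float = 1.0,
    lowess_frac: float = 0.5,
    use_weights: bool = True,
    shrink: bool = True,
    keep: pd.Series | None = None,
    norm: str = "tmm",
) -> DgeTable:
    """Fit the moderated model for one timepoint and return a DgeTable.

    ``use_weights=False`` together with ``shrink=False`` reduces the fit
    to an ordinary per-gene two-group (plus batch) linear-model t-test,
    which is used as the oracle route in the test suite.

    ``keep`` overrides the expression filter (boolean per gene); by
    default the filter is computed on the full matrix so both timepoints
    test the same gene universe.
    """
    samples = cm.samples_for(timepoint=timepoint)
    if not samples:
        raise DgeError(f"no samples at timepoint {timepoint!r}")
    sub = cm.subset_samples(samples)
    sizes = sub.sample_meta.groupby("condition", observed=True).size()
    for cond in ("injury", "sham"):
        if sizes.get(cond, 0) < 2:
            raise DgeError(
                f"need >= 2 samples per condition at {timepoint}; "
                f"{cond} has {sizes.get(cond, 0)}"
            )

    if keep is None:
        keep = expression_filter(cm, cpm_threshold=cpm_threshold)
    keep = keep.reindex(cm.counts.index).fillna(False).astype(bool)

    X, cond_idx = _build_design(sub.sample_meta, include_batch)
    n, p = X.shape
    if n - p <= 0:
        raise DgeError(f"zero residual degrees of freedom at {timepoint}")

    if norm == "tmm":
        eff_lib = sub.library_sizes() * tmm_factors(sub.counts)
    elif norm == "none":
        eff_lib = sub.library_sizes().astype(float)
    else:
        raise DgeError(f"unknown normalization {norm!r}")
    logcpm_all = normalize_logcpm(sub, prior_count=prior_count, lib_sizes=eff_lib)
    logcpm = logcpm_all.loc[keep].to_numpy()
    genes_kept = logcpm_all.index[keep.to_numpy()]
    lib = eff_lib.to_numpy(dtype=float)

    # first pass: OLS for the mean-variance trend
    beta0, s2_0, _, fitted0 = _batched_lstsq(X, logcpm, None)
    weights = None
    if use_weights:
        # voom-style: sqrt residual SD vs average log count
        geo_lib = np.exp(np.mean(np.log(lib + 1.0)))
        sx = logcpm.mean(axis=1) + np.log2(geo_lib / 1e6)
        sy = np.sqrt(np.sqrt(np.maximum(s2_0, 0.0)))
        try:
            lo = lowess(sy, sx, frac=lowess_frac, return_sorted=True)
            lx, ly = lo[:, 0], lo[:, 1]
            if len(lx) < 2 or not np.all(np.isfinite(ly)):
                raise RuntimeError("degenerate lowess fit")
            # per-observation fitted log counts -> predicted sqrt-sd
            fitted_count = fitted0 + np.log2(lib / 1e6)[None, :]
            pred = np.interp(fitted_count, lx, ly)
            pred = np.clip(pred, 1e-4, None)
            weights = 1.0 / pred ** 4
        except Exception:  # trend failure: fall back to unweighted
            warnings.warn(
                "mean-variance trend fit failed; falling back to unweighted model",
                stacklevel=2,
            )
            weights = None

    beta, s2, cov_unscaled, _ = _batched_lstsq(X, logcpm, weights)
    df_resid = n - p
    if shrink:
        s2_post, df_prior, _ = squeeze_var(s2, df_resid)
    else:
        s2_post, df_prior = s2, 0.0
    se = np.sqrt(s2_post * cov_unscaled[:, cond_idx, cond_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[:, cond_idx] / se
    df_total = df_resid + (df_prior if np.isfinite(df_prior) else 1e6)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
    pvals = np.where(np.isfinite(tstat), pvals, 1.0)
    tstat = np.where(np.isfinite(tstat), tstat, 0.0)
    adj = bh_adjust(pvals)

    tbl = pd.DataFrame(
        {
            "log2fc": pd.Series(beta[:, cond_idx], index=genes_kept),
            "mean_logexpr": pd.Series(logcpm.mean(axis=1), index=genes_kept),
            "stat": pd.Series(tstat, index=genes_kept),
            "p": pd.Series(pvals, index=genes_kept),
            "adj_p": pd.Series(adj, index=genes_kept),
        }
    ).reindex(cm.counts.index)
    tbl["filtered"] = ~keep
    params = {
        "timepoint": timepoint,
        "prior_count": prior_count,
        "cpm_threshold": cpm_threshold,
        "lowess_frac": lowess_frac,
        "use_weights": use_weights,
        "shrink": shrink,
        "include_batch": include_batch,
        "df_resid": df_resid,
        "df_prior": float(df_prior),
    }
    return DgeTable(table=tbl, timepoint=timepoint, params=params)


def call_degs(tbl: DgeTable, alpha: float = 0.05, use_adjusted: bool = True) -> pd.Series:
    """Per-gene status in {up, down, ns} at the table's timepoint.

    up iff adj_p < alpha and log2fc > 0 (strict inequalities); filtered
    genes are ns.  ``use_adjusted=False`` thresholds the raw p instead.
    """
    if not (0.0 < alpha < 1.0):
        raise DgeError(f"alpha must be in (0, 1), got {alpha}")
    t = tbl.table
    pcol = t["adj_p"] if use_adjusted else t["p"]
    sig = (pcol < alpha) & ~t["filtered"] & pcol.notna()
    status = np.where(sig & (t["log2fc"] > 0), "up",
                      np.where(sig & (t["log2fc"] < 0), "down", "ns"))
    return pd.Series(status, index=t.index, name=f"status_{tbl.timepoint}")
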