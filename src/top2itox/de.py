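"""Counts to moderated per-contrast differential-expression tables.

log2 counts-per-million with pseudo-counts, a mean-log2cpm expression filter,
trimmed-mean-of-M-values normalization, mean-variance precision weights,
gene-wise weighted linear models with empirical-Bayes variance moderation,
and Benjamini-Hochberg adjustment within each contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import CountExperiment
from .simulate import VEHICLE, contrast_pairs, pair_key


def log2_cpm(counts, lib_sizes=None, norm_factors=None):
    """log2((count + 0.5) / (lib * factor + 1) * 1e6), the edgeR convention."""
    is_frame = isinstance(counts, pd.DataFrame)
    vals = counts.to_numpy(dtype=float) if is_frame else np.asarray(counts, float)
    if lib_sizes is None:
        lib_sizes = vals.sum(axis=0)
    lib = np.asarray(lib_sizes, dtype=float)
    if (lib <= 0).any():
        raise ValueError("lib_sizes must be > 0")
    if norm_factors is not None:
        lib = lib * np.asarray(norm_factors, dtype=float)
    out = np.log2((vals + 0.5) / (lib + 1.0) * 1e6)
    if is_frame:
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def filter_expressed(log2cpm: pd.DataFrame, threshold: float = 0.0) -> pd.Index:
    """Genes whose mean log2 cpm across samples is >= ``threshold``.

    The exclusion rule is strict (< threshold removed), so a gene sitting
    exactly on the boundary is retained.
    """
    if log2cpm.shape[0] == 0:
        raise ValueError("empty matrix")
    means = log2cpm.mean(axis=1)
    return log2cpm.index[means >= threshold]


def _quantile_factor(vals: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(vals / lib, p, axis=0)


def tmm_factors(
    counts,
    lib_sizes=None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors (Robinson-Oshlack).

    Reference sample: upper quartile (of count/lib-size) closest to the mean
    upper quartile. Gene-wise log ratios are trimmed 30% by M and 5% by A and
    combined by a precision-weighted mean; factors are rescaled to have unit
    geometric mean (so a pure depth difference yields equal factors).
    """
    vals = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    if vals.shape[1] < 2:
        raise ValueError("need at least two samples")
    if lib_sizes is None:
        lib = vals.sum(axis=0)
    else:
        lib = np.asarray(lib_sizes, dtype=float)
    # drop all-zero genes, as the reference implementation does
    vals = vals[vals.sum(axis=1) > 0]
    f75 = _quantile_factor(vals, lib)
    if np.median(f75) < 1e-20:
        ref = int(np.argmax(np.sqrt(vals).sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(vals.shape[1])
    yr = vals[:, ref]
    nr = lib[ref]
    for j in range(vals.shape[1]):
        if j == ref:
            continue
        y = vals[:, j]
        n = lib[j]
        ok = (y > 0) & (yr > 0)
        if not ok.any():
            warnings.warn(f"sample {j} shares no expressed genes with reference")
            continue
        yo, yro = y[ok], yr[ok]
        m = np.log2((yo / n) / (yro / nr))
        a = 0.5 * (np.log2(yo / n) + np.log2(yro / nr))
        v = (n - yo) / (n * yo) + (nr - yro) / (nr * yro)
        fin = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
        m, a, v = m[fin], a[fin], v[fin]
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            continue
        nn = m.size
        lo_l = np.floor(nn * logratio_trim) + 1
        hi_l = nn + 1 - lo_l
        lo_s = np.floor(nn * sum_trim) + 1
        hi_s = nn + 1 - lo_s
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
        if keep.any():
            f = 2.0 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))
            if np.isfinite(f) and f > 0:
                factors[j] = f
    return factors / np.exp(np.mean(np.log(factors)))


def _check_design(design: np.ndarray) -> None:
    n, p = design.shape
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("design matrix is rank-deficient")
    if n - p <= 0:
        raise ValueError("no residual degrees of freedom")


def _batched_wls(y: np.ndarray, w: np.ndarray, x: np.ndarray):
    """Gene-wise weighted least squares; returns beta, xtwx_inv, s2, df."""
    n, p = x.shape
    xtwx = np.einsum("ji,gj,jk->gik", x, w, x)
    xtwy = np.einsum("ji,gj,gj->gi", x, w, y)
    xtwx_inv = np.linalg.inv(xtwx)
    beta = np.einsum("gik,gk->gi", xtwx_inv, xtwy)
    resid = y - beta @ x.T
    df = n - p
    s2 = np.einsum("gj,gj->g", w * resid, resid) / df
    return beta, xtwx_inv, s2, df


def precision_weights(
    log2cpm,
    design: np.ndarray,
    lib_sizes,
    span: float = 0.5,
) -> np.ndarray:
    """Per-observation inverse-variance weights from the mean-variance trend.

    Gene-wise linear models are fit to the log2 cpm values; a lowess curve of
    sqrt(residual SD) against average log2 count captures the mean-variance
    trend, and each observation's weight is the predicted variance at its
    fitted log-count, inverted.
    """
    y = log2cpm.to_numpy(dtype=float) if isinstance(log2cpm, pd.DataFrame) else np.asarray(log2cpm, float)
    x = np.asarray(design, dtype=float)
    _check_design(x)
    lib = np.asarray(lib_sizes, dtype=float)
    w0 = np.ones_like(y)
    beta, _, s2, _ = _batched_wls(y, w0, x)
    sigma = np.sqrt(s2)
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    ok = np.isfinite(sy)
    lo = lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
    fitted = beta @ x.T
    fitted_logcount = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, lo[:, 0], lo[:, 1])
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-6, None)
    return pred_sqrt_sd ** -4


def _trigamma_inverse(y: float) -> float:
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of gene-wise variances.

    Method of moments on log s^2 (the scaled-F prior fit): returns the prior
    degrees of freedom d0, prior variance s0^2, and posterior variances
    ``(d0 * s0^2 + df * s2) / (d0 + df)``.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.clip(s2, 1e-12, None)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
        post = np.full_like(s2, s0_2)
    return d0, s0_2, post


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


@dataclass
class ModeratedFit:
    """Result of a moderated weighted linear-model fit."""

    tables: dict  # contrast name -> per-gene DataFrame
    d0: float
    df_residual: float
    s0_2: float

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_residual


def moderated_fit(
    log2cpm: pd.DataFrame,
    weights: np.ndarray,
    design: np.ndarray,
    contrasts: dict,
) -> ModeratedFit:
    """Weighted least squares per gene with empirical-Bayes moderated t.

    ``contrasts`` maps a name to a coefficient-combination vector. p-values
    come from a t distribution with d0 + residual df degrees of freedom; BH
    adjustment is applied within each contrast.
    """
    y = log2cpm.to_numpy(dtype=float)
    x = np.asarray(design, dtype=float)
    _check_design(x)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    beta, xtwx_inv, s2, df = _batched_wls(y, w, x)
    d0, s0_2, post_s2 = squeeze_var(s2, df)
    df_total = d0 + df
    avg = log2cpm.mean(axis=1)
    tables = {}
    for name, cvec in contrasts.items():
        c = np.asarray(cvec, dtype=float)
        est = beta @ c
        unscaled = np.sqrt(np.einsum("i,gik,k->g", c, xtwx_inv, c))
        tval = est / (np.sqrt(post_s2) * unscaled)
        if np.isfinite(df_total):
            p = 2.0 * stats.t.sf(np.abs(tval), df_total)
        else:
            p = 2.0 * stats.norm.sf(np.abs(tval))
        tables[name] = pd.DataFrame(
            {
                "log2fc": est,
                "moderated_t": tval,
                "p": p,
                "p_adj": bh_adjust(p),
                "avg_log2cpm": avg.to_numpy(),
            },
            index=log2cpm.index,
        )
    return ModeratedFit(tables=tables, d0=d0, df_residual=df, s0_2=s0_2)


def _pair_design(samples: pd.DataFrame, drug: str, vehicle: str):
    """Intercept + treatment indicator + individual blocking dummies."""
    treat = (samples["treatment"] == drug).astype(float).to_numpy()
    ind = pd.get_dummies(samples["individual"], drop_first=True, dtype=float)
    x = np.column_stack([np.ones(len(samples)), treat, ind.to_numpy()])
    contrast = np.zeros(x.shape[1])
    contrast[1] = 1.0
    return x, contrast


@dataclass
class PairFit:
    """One drug-vs-vehicle contrast at one timepoint."""

    table: pd.DataFrame
    df_total: float
    d0: float


def fit_pair(
    experiment: CountExperiment,
    drug: str,
    time: str,
    vehicle: str = VEHICLE,
    expressed: pd.Index | None = None,
) -> PairFit:
    """The full TMM / precision-weight / moderated-t pipeline for one
    treatment-vehicle pair at one timepoint."""
    ids = experiment.group_samples(drug, time) + experiment.group_samples(vehicle, time)
    if not experiment.group_samples(drug, time):
        raise ValueError(f"no samples for {drug} at {time}")
    if not experiment.group_samples(vehicle, time):
        raise ValueError(f"no vehicle samples at {time}")
    sub = experiment.subset_samples(ids)
    counts = sub.counts if expressed is None else sub.counts.loc[expressed]
    lib = sub.counts.sum(axis=0).to_numpy(dtype=float)  # library size from all genes
    factors = tmm_factors(counts, lib_sizes=lib)
    lcpm = log2_cpm(counts, lib_sizes=lib, norm_factors=factors)
    design, contrast = _pair_design(sub.samples, drug, vehicle)
    w = precision_weights(lcpm, design, lib * factors)
    fit = moderated_fit(lcpm, w, design, {pair_key(drug, time): contrast})
    return PairFit(table=fit.tables[pair_key(drug, time)], df_total=fit.df_total, d0=fit.d0)


def pairwise_de(
    experiment: CountExperiment,
    pairs: list[tuple[str, str]] | None = None,
    vehicle: str = VEHICLE,
    expression_threshold: float = 0.0,
) -> dict:
    """ContrastTables for every (drug, time) pair against the vehicle.

    The expression filter (mean log2 cpm across all samples) defines a common
    gene universe before any pair is fit.
    """
    if pairs is None:
        treatments = [t for t in experiment.samples["treatment"].unique() if t != vehicle]
        times = list(experiment.samples["time"].unique())
        pairs = [(t, tp) for t in treatments for tp in times]
    lcpm_all = log2_cpm(experiment.counts)
    expressed = filter_expressed(lcpm_all, expression_threshold)
    return {
        pr: fit_pair(experiment, pr[0], pr[1], vehicle=vehicle, expressed=expressed)
        for pr in pairs
    }


def response_correlation_matrix(tables: dict):
    """Pearson correlation of log2 fold-change vectors across treatment-time
    groups, with average-linkage clustering on 1 - r.

    Returns (correlation DataFrame, leaf order, linkage matrix).
    """
    names = list(tables.keys())
    keys = [pair_key(*n) if isinstance(n, tuple) else str(n) for n in names]
    frames = {}
    common = None
    for n, k in zip(names, keys):
        t = tables[n].table if hasattr(tables[n], "table") else tables[n]
        frames[k] = t["log2fc"]
        common = t.index if common is None else common.intersection(t.index)
    mat = pd.DataFrame({k: frames[k].loc[common] for k in keys})
    keep = []
    for k in keys:
        if mat[k].std() == 0:
            warnings.warn(f"group {k} has constant log2fc; dropped")
        else:
            keep.append(k)
    mat = mat[keep]
    corr = mat.corr(method="pearson")
    dist = np.clip(1.0 - corr.to_numpy(), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [keep[i] for i in leaves_list(z)]
    return corr, order, z
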