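"""Inter-individual expression variability per treatment-time group.

Per-gene means/variances of log2 cpm across individuals, gene-wise two-sided
F tests of drug vs vehicle variance, a group-level paired shift test on log
variance ratios, and hierarchical clustering of groups by their gene-wise
F-statistic profiles (Spearman correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


@dataclass
class VarianceTable:
    means: pd.DataFrame  # genes x group
    variances: pd.DataFrame  # genes x group
    group_sizes: pd.Series  # group -> n individuals
    flagged_groups: list


def group_mean_variance(log2cpm: pd.DataFrame, samples: pd.DataFrame) -> VarianceTable:
    """Per-gene sample mean and unbiased variance across individuals within
    each treatment-time group. Groups with a single individual are flagged
    (variance undefined)."""
    means, variances, sizes = {}, {}, {}
    flagged = []
    for (trt, tp), grp in samples.groupby(["treatment", "time"], sort=False):
        key = f"{trt}_{tp}"
        ids = grp.index.tolist()
        sub = log2cpm[ids]
        sizes[key] = grp["individual"].nunique()
        means[key] = sub.mean(axis=1)
        if sizes[key] < 2:
            flagged.append(key)
            variances[key] = pd.Series(np.nan, index=log2cpm.index)
        else:
            variances[key] = sub.var(axis=1, ddof=1)
    return VarianceTable(
        means=pd.DataFrame(means),
        variances=pd.DataFrame(variances),
        group_sizes=pd.Series(sizes),
        flagged_groups=flagged,
    )


def variance_test_per_gene(
    drug_values: pd.DataFrame, vehicle_values: pd.DataFrame
) -> pd.DataFrame:
    """Gene-wise variance-ratio F test, drug vs vehicle.

    F = s2_drug / s2_veh with (n_drug - 1, n_veh - 1) degrees of freedom;
    two-sided p = 2 * min(P(F <= f), P(F >= f)), capped at 1. Genes with zero
    vehicle variance are excluded (F undefined); the count is reported in the
    ``excluded`` attribute of the returned frame.
    """
    n1, n2 = drug_values.shape[1], vehicle_values.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least two individuals")
    s1 = drug_values.var(axis=1, ddof=1)
    s2 = vehicle_values.var(axis=1, ddof=1)
    ok = s2 > 0
    f = s1[ok] / s2[ok]
    d1, d2 = n1 - 1, n2 - 1
    cdf = stats.f.cdf(f, d1, d2)
    p = np.minimum(2.0 * np.minimum(cdf, 1.0 - cdf), 1.0)
    out = pd.DataFrame({"F": f, "p": p, "df1": d1, "df2": d2}, index=f.index)
    out.attrs["excluded"] = int((~ok).sum())
    return out


def group_variance_shift_test(
    drug_variances: pd.Series, vehicle_variances: pd.Series
) -> dict:
    """Paired two-sided Wilcoxon signed-rank test on per-gene log variance
    ratios. Returns the p-value, the median log2 ratio and the direction."""
    ratio = np.log2(drug_variances) - np.log2(vehicle_variances)
    ratio = ratio.replace([np.inf, -np.inf], np.nan).dropna()
    nonzero = ratio[ratio != 0]
    if nonzero.empty:
        return {"p": 1.0, "median_log2_ratio": 0.0, "direction": 0, "n": int(len(ratio))}
    stat, p = stats.wilcoxon(nonzero)
    med = float(np.median(ratio))
    return {
        "p": float(p),
        "median_log2_ratio": med,
        "direction": int(np.sign(med)),
        "n": int(len(ratio)),
    }


def variance_profile_clustering(f_matrix: pd.DataFrame):
    """Spearman correlation of gene-wise F-statistic profiles across groups,
    clustered by average linkage on 1 - rho.

    Returns (rho DataFrame, leaf order, linkage matrix)."""
    keep = []
    for col in f_matrix.columns:
        if f_matrix[col].nunique(dropna=True) < 2:
            warnings.warn(f"group {col} has a constant F profile; dropped")
        else:
            keep.append(col)
    mat = f_matrix[keep].dropna()
    rho = mat.corr(method="spearman")
    dist = np.clip(1.0 - rho.to_numpy(), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [keep[i] for i in leaves_list(z)]
    return rho, order, z
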